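"""The job runner: one configured search -> one output folder.

Mirrors the original tool's job form (title, BLAST type, E-value cutoff,
MaxResults) but runs synchronously: parse hits, join them to the
annotation, project, cap, filter, and write the whole bundle —
``<title>_Sorted.tsv`` (all capped results, canonical order),
``<title>_Sorted_Scored.tsv`` (rows surviving the filters), the results
JSON, the interactive ``graph.html``, a static ``graph.svg``,
``table.html`` and a ``run.log`` with the conserved counts.
"""

from __future__ import annotations

import os
import shutil
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

from . import formats, projection, results as results_mod, synth, viz
from .model import PlottedResult, Replicon
from .results import (
    DISPLAY_CAP_DEFAULT,
    RAW_CAP_DEFAULT,
    FilterSpec,
    apply_result_cap,
    filter_table,
)

BLAST_TYPES = ("genes", "proteins", "genomes")


@dataclass
class JobConfig:
    """Everything the job form collects, plus the local paths."""

    job_title: str
    hits_path: Optional[str] = None
    query_fasta: Optional[str] = None
    subject_fasta: Optional[str] = None
    gff_path: Optional[str] = None
    replicons_path: Optional[str] = None  # FASTA or replicon TSV
    blast_type: str = "genes"
    evalue_cutoff: float = synth.EVALUE_CUTOFF_DEFAULT
    max_results: int = synth.MAX_RESULTS_DEFAULT
    display_cap: int = DISPLAY_CAP_DEFAULT
    raw_cap: int = RAW_CAP_DEFAULT
    filters: List[FilterSpec] = field(default_factory=list)
    output_dir: str = "."

    def __post_init__(self) -> None:
        if self.blast_type not in BLAST_TYPES:
            raise ValueError(
                f"blast_type must be one of {BLAST_TYPES}, got "
                f"{self.blast_type!r}"
            )
        if self.display_cap < 1 or self.raw_cap < 1:
            raise ValueError("caps must be >= 1")
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue_cutoff must be > 0")


@dataclass
class JobResult:
    """Run summary: the folder, artifacts and conserved counts."""

    folder: str
    n_parsed: int
    n_resolved: int
    n_unresolved: int
    n_raw_discarded: int
    n_filtered: int
    n_displayed: int
    rows: List[PlottedResult]
    replicons: List[Replicon]


def run_job(config: JobConfig) -> JobResult:
    """Execute one job into ``config.output_dir``; exits clean or removes
    the partial folder."""
    folder = config.output_dir
    created = not os.path.isdir(folder)
    os.makedirs(folder, exist_ok=True)
    try:
        return _run_job_inner(config, folder)
    except Exception:
        if created:
            shutil.rmtree(folder, ignore_errors=True)
        raise


def _run_job_inner(config: JobConfig, folder: str) -> JobResult:
    if config.replicons_path is None:
        raise ValueError("a replicon FASTA or TSV is required")
    for path in filter(None, (config.hits_path, config.gff_path,
                              config.replicons_path, config.query_fasta)):
        if not os.path.exists(path):
            raise FileNotFoundError(f"input file not found: {path}")

    hits_path = config.hits_path
    if hits_path is None:
        # no precomputed hits: run the optional BLAST wrapper
        if config.query_fasta is None or config.subject_fasta is None:
            raise ValueError(
                "either a precomputed hits file or a query+subject FASTA "
                "pair is required"
            )
        program = {"genes": "blastn", "proteins": "blastp",
                   "genomes": "blastn"}[config.blast_type]
        hits_path = os.path.join(folder, "blast_hits.tsv")
        synth.run_blast(
            config.query_fasta, config.subject_fasta, hits_path,
            program=program, evalue_cutoff=config.evalue_cutoff,
            max_results=config.max_results,
        )

    unit = "protein" if config.blast_type == "proteins" else "nucleotide"
    hits = formats.read_blast_tabular(hits_path, unit=unit)
    hits = [h for h in hits if h.evalue <= config.evalue_cutoff]
    n_parsed = len(hits)

    if config.blast_type == "genomes":
        replicons = formats._read_replicon_lengths(config.replicons_path)
        replicons = projection.assign_replicon_indices(replicons)
        rep_by_id = {r.replicon_id: r for r in replicons}
        resolved, unresolved = [], []
        for h in hits:
            (resolved if h.subject_id in rep_by_id else unresolved).append(h)
        scale = projection.ColorScale.from_results(
            [h.bitscore for h in resolved]
        )
        rows = [
            projection.project_hit_genome(h, rep_by_id[h.subject_id], scale)
            for h in resolved
        ]
    else:
        if config.gff_path is None:
            raise ValueError("gene/protein jobs require a GFF3 annotation")
        replicons, features = formats.read_annotation(
            config.gff_path, config.replicons_path
        )
        replicons = projection.assign_replicon_indices(replicons)
        rows, unresolved = projection.project_hits(hits, features, replicons)

    rows, n_raw_discarded = apply_result_cap(rows, config.raw_cap)
    filtered = filter_table(rows, config.filters)
    displayed, n_disp_discarded = apply_result_cap(
        filtered, config.display_cap
    )

    title = config.job_title.replace(" ", "_") or "job"
    job_meta = {
        "title": config.job_title,
        "parameters": {
            "blast_type": config.blast_type,
            "evalue_cutoff": config.evalue_cutoff,
            "max_results": config.max_results,
            "display_cap": config.display_cap,
            "raw_cap": config.raw_cap,
            "filters": [
                {"column": f.column, "mode": f.mode, "needle": f.needle}
                for f in config.filters
            ],
        },
    }
    formats.write_table_tsv(
        rows, os.path.join(folder, f"{title}_Sorted.tsv"), "sorted_raw"
    )
    formats.write_table_tsv(
        rows, os.path.join(folder, f"{title}_Sorted_Scored.tsv"),
        "sorted_scored", filters=config.filters,
    )
    formats.write_results_json(
        rows, os.path.join(folder, f"{title}.json"),
        job=job_meta, replicons=replicons,
    )
    view = viz.ViewSpec(y_range=(1, max(len(replicons), 1)))
    viz.render_interactive(
        displayed, view, os.path.join(folder, "graph.html"),
        replicons=replicons, title=config.job_title,
    )
    viz.render_static(
        displayed, view, os.path.join(folder, "graph.svg"),
        title=config.job_title,
    )
    viz.render_table_html(
        displayed, os.path.join(folder, "table.html"),
        title=config.job_title,
    )
    log_lines = [
        f"job: {config.job_title}",
        f"parsed: {n_parsed}",
        f"resolved: {len(rows) + n_raw_discarded}",
        f"unresolved: {len(unresolved)}",
        f"raw_discarded: {n_raw_discarded}",
        f"filtered: {len(filtered)}",
        f"displayed: {len(displayed)}",
    ]
    with open(os.path.join(folder, "run.log"), "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return JobResult(
        folder=folder,
        n_parsed=n_parsed,
        n_resolved=len(rows) + n_raw_discarded,
        n_unresolved=len(unresolved),
        n_raw_discarded=n_raw_discarded,
        n_filtered=len(filtered),
        n_displayed=len(displayed),
        rows=rows,
        replicons=replicons,
    )
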