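"""Readers and writers for the standard formats around the pipeline.

Reads 12-column BLAST tabular output (``-outfmt 6``; ``-outfmt 7``
comment lines are tolerated), GFF3 annotation via :mod:`gffutils`, and
replicon lengths from either a FASTA file or a 2-4 column TSV
(``replicon_id  length_bp  [organism]  [topology]``).

Writes the tool's own outputs: a results JSON document (job metadata,
replicon catalogue, projected results) and the two spreadsheet-style TSV
tables — ``*_Sorted`` with all (capped) results in canonical significance
order and ``*_Sorted_Scored`` with only the rows surviving the active
filters.
"""

from __future__ import annotations

import json
import os
from typing import Iterable, List, Optional, Sequence, Tuple

import gffutils
from Bio import SeqIO

from .model import BlastHit, GeneFeature, PlottedResult, Replicon
from .results import FilterSpec, canonical_order, filter_table

BLAST_TABULAR_FIELDS = 12

TABLE_COLUMNS = (
    "Query",
    "Subject",
    "Organism",
    "Replicon",
    "RelPosition",
    "BitScore",
    "Evalue",
    "Product",
)

_RESULT_FIELDS = (
    "x", "y", "vector_deg", "seg_offset_deg", "seg_len_deg", "strand",
    "bitscore", "color_value", "evalue", "query_id", "subject_id",
    "organism", "product", "replicon_id", "s_start", "s_end",
)


class FormatError(ValueError):
    """Raised for malformed input files, naming the offending location."""


def read_blast_tabular(path: str, unit: str = "nucleotide") -> List[BlastHit]:
    """Parse a BLAST ``-outfmt 6`` (or 7) file into hits, input order kept.

    ``unit`` declares the coordinate unit of the subject start/end
    columns: ``"nucleotide"`` for blastn-style searches against gene or
    genome databases, ``"protein"`` (residues) for blastp/tblastn
    searches against protein databases.
    """
    hits: List[BlastHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < BLAST_TABULAR_FIELDS:
                raise FormatError(
                    f"{path}: line {lineno}: expected >={BLAST_TABULAR_FIELDS} "
                    f"fields, got {len(fields)}"
                )
            try:
                hits.append(
                    BlastHit(
                        query_id=fields[0],
                        subject_id=fields[1],
                        pct_identity=float(fields[2]),
                        aln_length=int(fields[3]),
                        mismatches=int(fields[4]),
                        gap_opens=int(fields[5]),
                        q_start=int(fields[6]),
                        q_end=int(fields[7]),
                        s_start=int(fields[8]),
                        s_end=int(fields[9]),
                        evalue=float(fields[10]),
                        bitscore=float(fields[11]),
                        unit=unit,
                    )
                )
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: {exc}"
                ) from exc
    return hits


def write_blast_tabular(hits: Sequence[BlastHit], path: str) -> None:
    """Serialize hits back to canonical 12-column tabular lines."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.pct_identity:.2f}",
                        str(h.aln_length),
                        str(h.mismatches),
                        str(h.gap_opens),
                        str(h.q_start),
                        str(h.q_end),
                        str(h.s_start),
                        str(h.s_end),
                        f"{h.evalue:.2e}",
                        f"{h.bitscore:g}",
                    ]
                )
                + "\n"
            )


def _read_replicon_lengths(path: str) -> List[Replicon]:
    """Replicons from a FASTA (sequence lengths) or a replicon TSV."""
    with open(path) as fh:
        head = fh.read(1)
    if head == ">":
        return [
            Replicon(replicon_id=rec.id, length_bp=len(rec.seq))
            for rec in SeqIO.parse(path, "fasta")
        ]
    replicons: List[Replicon] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(
                    f"{path}: line {lineno}: expected replicon_id<TAB>length_bp"
                )
            try:
                length = int(fields[1])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: length_bp not an integer: "
                    f"{fields[1]!r}"
                ) from exc
            replicons.append(
                Replicon(
                    replicon_id=fields[0],
                    length_bp=length,
                    organism=fields[2] if len(fields) > 2 else "",
                    topology=fields[3] if len(fields) > 3 else "circular",
                )
            )
    return replicons


def read_annotation(
    gff_path: str, fasta_or_tsv_path: str
) -> Tuple[List[Replicon], List[GeneFeature]]:
    """Read gene features from GFF3 plus replicon lengths.

    Prefers ``gene`` records; falls back to ``CDS`` when the file has no
    genes (avoids double-counting loci annotated with both).  Features
    annotated with end < start on a circular replicon are treated as
    origin-spanning and normalized to ``end + replicon_length`` with the
    ``wraps_origin`` flag set.
    """
    replicons = _read_replicon_lengths(fasta_or_tsv_path)
    lengths = {r.replicon_id: r.length_bp for r in replicons}
    db = gffutils.create_db(
        gff_path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    featuretypes = set(db.featuretypes())
    wanted = "gene" if "gene" in featuretypes else "CDS"
    features: List[GeneFeature] = []
    seen: set = set()
    for f in db.all_features(featuretype=wanted, order_by=None):
        if f.seqid not in lengths:
            raise FormatError(f"{gff_path}: unknown replicon {f.seqid}")
        length = lengths[f.seqid]
        fid = (f.attributes.get("ID") or f.attributes.get("locus_tag") or [f.id])[0]
        start, end, wraps = f.start, f.end, False
        if end < start:  # origin-spanning annotation on a circular replicon
            end += length
            wraps = True
        if not wraps and end > length:
            raise FormatError(
                f"{gff_path}: feature {fid}: end {end} exceeds length of "
                f"replicon {f.seqid} ({length} bp)"
            )
        if (f.seqid, fid) in seen:
            raise FormatError(
                f"{gff_path}: duplicate feature id {fid} on replicon {f.seqid}"
            )
        seen.add((f.seqid, fid))
        features.append(
            GeneFeature(
                replicon_id=f.seqid,
                feature_id=fid,
                start_bp=start,
                end_bp=end,
                strand="-" if f.strand == "-" else "+",
                locus_tag=(f.attributes.get("locus_tag") or [""])[0],
                product=(f.attributes.get("product") or [""])[0],
                wraps_origin=wraps,
            )
        )
    return replicons, features


def write_results_json(
    results: Sequence[PlottedResult],
    path: str,
    job: Optional[dict] = None,
    replicons: Optional[Sequence[Replicon]] = None,
) -> None:
    """Write the results document (plain-text JSON).

    Schema: ``{"job": {...}, "replicons": [...], "results": [...]}``.
    Floats survive the round trip exactly (serialized at full precision).
    """
    doc = {
        "job": job or {},
        "replicons": [
            {
                "replicon_id": r.replicon_id,
                "organism": r.organism,
                "length_bp": r.length_bp,
                "replicon_index": r.replicon_index,
            }
            for r in (replicons or [])
        ],
        "results": [r.to_dict() for r in results],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=None, separators=(",", ":"))
        fh.write("\n")


def read_results_document(path: str) -> dict:
    """The full results JSON document, validated."""
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON at line {exc.lineno}") from exc
    if "results" not in doc:
        raise FormatError(f"{path}: missing field results")
    for i, rec in enumerate(doc["results"]):
        for key in _RESULT_FIELDS:
            if key not in rec:
                raise FormatError(f"{path}: result {i}: missing field {key}")
    return doc


def read_results_json(path: str) -> List[PlottedResult]:
    """Read back the projected results (round-trip inverse of the writer)."""
    doc = read_results_document(path)
    return [PlottedResult.from_dict(rec) for rec in doc["results"]]


def write_table_tsv(
    results: Sequence[PlottedResult],
    path: str,
    variant: str = "sorted_raw",
    filters: Optional[Iterable[FilterSpec]] = None,
) -> int:
    """Write a spreadsheet-style TSV table; returns the number of data rows.

    ``sorted_raw`` holds all (capped) results in canonical significance
    order; ``sorted_scored`` holds only the rows surviving ``filters``.
    """
    if variant not in ("sorted_raw", "sorted_scored"):
        raise ValueError(f"unknown table variant {variant!r}")
    rows = canonical_order(results)
    if variant == "sorted_scored":
        rows = filter_table(rows, filters or [])
    with open(path, "w") as fh:
        fh.write("\t".join(TABLE_COLUMNS) + "\n")
        for r in rows:
            fh.write(
                "\t".join(
                    [
                        r.query_id,
                        r.subject_id,
                        r.organism,
                        r.replicon_id,
                        f"{r.x:.4f}",
                        f"{r.bitscore:g}",
                        f"{r.evalue:.3g}",
                        r.product,
                    ]
                )
                + "\n"
            )
    return len(rows)
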