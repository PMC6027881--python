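"""Seeded synthetic genomes, annotations and BLAST tabular files.

Stands in for a real genome database: generates multi-organism,
multi-replicon annotations (GFF3 + replicon TSV) and BLAST ``-outfmt 6``
hit files with planted gene clusters — e.g. a four-gene bacteriocin-style
locus hit by queries capA..capD — over a sparse random background, so the
whole pipeline can be exercised without downloads.  All randomness comes
from one seeded generator per operation; identical specs and seeds give
byte-identical files.

An optional wrapper drives a locally installed BLAST+ (``makeblastdb``
plus blastn/blastp/tblastn) when real alignments are wanted.
"""

from __future__ import annotations

import os
import shutil
import subprocess
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .model import BlastHit, GeneFeature, Replicon

MIN_GENE_LEN_BP = 90
CLUSTER_GAP_BP = 25  # intergenic gap inside a planted operon-style locus

# bitscore bands: planted cluster hits are unambiguously more significant
# than background; e-value is a monotone stand-in (the pipeline needs
# ordering, not BLAST statistics)
PLANTED_BITSCORE_RANGE = (200.0, 400.0)
BACKGROUND_BITSCORE_RANGE = (40.0, 80.0)

EVALUE_CUTOFF_DEFAULT = 1e-08
MAX_RESULTS_DEFAULT = 30_000


class BlastNotInstalledError(RuntimeError):
    """BLAST+ binaries are not on PATH (the wrapper is optional)."""


@dataclass(frozen=True)
class GenomeSimSpec:
    """Shape of a synthetic genome set.

    Each organism gets the same replicon layout: ``replicon_lengths[0]``
    is the chromosome, any further entries are plasmids.  Genes are
    placed without overlap, uniformly at random, with lengths around
    ``mean_gene_length_bp``.
    """

    n_organisms: int = 1
    replicon_lengths: Tuple[int, ...] = (1_000_000,)
    topologies: Tuple[str, ...] = ()
    genes_per_replicon: int = 100
    mean_gene_length_bp: int = 900
    seed: int = 0
    organism_names: Tuple[str, ...] = ()
    #: (replicon_id, first gene index (0-based), gene count, role tag):
    #: the products of these genes carry the tag, marking a planted locus.
    cluster_tags: Tuple[Tuple[str, int, int, str], ...] = ()

    def __post_init__(self) -> None:
        if self.n_organisms < 1 or self.genes_per_replicon < 1:
            raise ValueError("counts must be >= 1")
        if not self.replicon_lengths:
            raise ValueError("at least one replicon length required")


@dataclass(frozen=True)
class PlantedCluster:
    """A run of consecutive genes each hit by one query (zipped pairing)."""

    replicon_id: str
    start_gene_index: int
    queries: Tuple[str, ...]


@dataclass(frozen=True)
class HitSimSpec:
    """Shape of a synthetic BLAST result set over a synthetic genome."""

    queries: Tuple[str, ...] = ()
    hit_rate: float = 0.0  # expected background hits per (query, replicon)
    planted_clusters: Tuple[PlantedCluster, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hit_rate < 0:
            raise ValueError("hit_rate must be >= 0")


def _organism_name(spec: GenomeSimSpec, i: int) -> str:
    if spec.organism_names:
        return spec.organism_names[i]
    return f"Synthetica_organism_{i + 1:02d}"


def generate_genome(
    spec: GenomeSimSpec, out_dir: str
) -> Tuple[str, str, List[Replicon], List[GeneFeature]]:
    """Write ``annotation.gff3`` and ``replicons.tsv``; return paths + records.

    Deterministic for a fixed seed: running twice gives byte-identical
    files.  Raises on infeasible packing (total gene length exceeding a
    replicon).
    """
    rng = np.random.default_rng(spec.seed)
    os.makedirs(out_dir, exist_ok=True)
    replicons: List[Replicon] = []
    features: List[GeneFeature] = []
    tag_by_gene: Dict[Tuple[str, int], str] = {}
    for rep_id, start, count, tag in spec.cluster_tags:
        for k in range(count):
            tag_by_gene[(rep_id, start + k)] = f"{tag} protein {k + 1}"
    for i in range(spec.n_organisms):
        org = _organism_name(spec, i)
        for j, L in enumerate(spec.replicon_lengths):
            topo = spec.topologies[j] if j < len(spec.topologies) else "circular"
            rep_id = f"{org}_rep{j + 1}"
            replicons.append(
                Replicon(replicon_id=rep_id, length_bp=L, organism=org,
                         topology=topo)
            )
            n = spec.genes_per_replicon
            lengths = np.maximum(
                MIN_GENE_LEN_BP,
                rng.normal(spec.mean_gene_length_bp,
                           spec.mean_gene_length_bp / 4, n).astype(int),
            )
            total = int(lengths.sum())
            if total > L:
                raise ValueError(
                    f"infeasible packing: {n} genes totalling {total} bp "
                    f"exceed replicon {rep_id} ({L} bp)"
                )
            slack = L - total
            # genes inside a tagged cluster sit operon-style: short fixed
            # intergenic gaps, so the locus stays compact on the 360 axis
            intra = {
                start + k
                for cl_rep, start, count, _ in spec.cluster_tags
                if cl_rep == rep_id
                for k in range(1, count)
            }
            free_slots = [k for k in range(n + 1) if k not in intra]
            slack -= CLUSTER_GAP_BP * len(intra)
            if slack < 0:
                raise ValueError(
                    f"infeasible packing: genes plus cluster gaps exceed "
                    f"replicon {rep_id} ({L} bp)"
                )
            gaps = np.zeros(n + 1, dtype=int)
            gaps[free_slots] = rng.multinomial(
                slack, np.full(len(free_slots), 1.0 / len(free_slots))
            )
            gaps[list(intra)] = CLUSTER_GAP_BP
            pos = 1
            for k in range(n):
                pos += int(gaps[k])
                start_bp = pos
                end_bp = pos + int(lengths[k]) - 1
                pos = end_bp + 1
                strand = "+" if rng.random() < 0.5 else "-"
                product = tag_by_gene.get(
                    (rep_id, k), "hypothetical protein"
                )
                features.append(
                    GeneFeature(
                        replicon_id=rep_id,
                        feature_id=f"{rep_id}_g{k + 1:04d}",
                        start_bp=start_bp,
                        end_bp=end_bp,
                        strand=strand,
                        locus_tag=f"{rep_id}_lt{k + 1:04d}",
                        product=product,
                    )
                )
    gff_path = os.path.join(out_dir, "annotation.gff3")
    tsv_path = os.path.join(out_dir, "replicons.tsv")
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                f"{f.replicon_id}\tblastxy-synth\tgene\t{f.start_bp}\t"
                f"{f.end_bp}\t.\t{f.strand}\t.\t"
                f"ID={f.feature_id};locus_tag={f.locus_tag};"
                f"product={f.product}\n"
            )
    with open(tsv_path, "w") as fh:
        for r in replicons:
            fh.write(
                f"{r.replicon_id}\t{r.length_bp}\t{r.organism}\t{r.topology}\n"
            )
    return gff_path, tsv_path, replicons, features


def _hit_line(
    query: str,
    feature: GeneFeature,
    rng: np.random.Generator,
    bitscore_range: Tuple[float, float],
) -> str:
    """One valid 12-column tabular row against a synthetic gene."""
    sub_len = feature.length_bp
    frac = rng.uniform(0.5, 1.0)
    aln = max(1, int(frac * sub_len))
    s_start = int(rng.integers(1, sub_len - aln + 2))
    s_end = s_start + aln - 1
    pct = rng.uniform(70.0, 100.0)
    mismatches = int(aln * (100.0 - pct) / 100.0)
    bitscore = round(float(rng.uniform(*bitscore_range)), 1)
    evalue = 10.0 ** (-bitscore / 10.0)
    return "\t".join(
        [
            query,
            feature.feature_id,
            f"{pct:.2f}",
            str(aln),
            str(mismatches),
            "0",
            "1",
            str(aln),
            str(s_start),
            str(s_end),
            f"{evalue:.2e}",
            f"{bitscore:g}",
        ]
    )


def simulate_hits(
    features: Sequence[GeneFeature],
    spec: HitSimSpec,
    path: str,
) -> Tuple[str, int, int]:
    """Write an ``-outfmt 6`` file; return ``(path, n_planted, n_background)``.

    Each planted cluster emits exactly one high-bitscore hit per
    (query, consecutive gene) pair, pairing query *i* with the *i*-th
    gene from the cluster start.  Background hits are Poisson-distributed
    per (query, replicon) at ``hit_rate``, on random genes, with low
    bitscores.
    """
    rng = np.random.default_rng(spec.seed)
    by_rep: Dict[str, List[GeneFeature]] = {}
    for f in features:
        by_rep.setdefault(f.replicon_id, []).append(f)
    lines: List[str] = []
    n_planted = 0
    for cl in spec.planted_clusters:
        if cl.replicon_id not in by_rep:
            raise ValueError(f"unknown replicon {cl.replicon_id!r}")
        genes = by_rep[cl.replicon_id]
        if cl.start_gene_index + len(cl.queries) > len(genes):
            raise ValueError(
                f"planted cluster on {cl.replicon_id!r} references genes "
                f"past the last one ({len(genes)} genes present)"
            )
        for i, q in enumerate(cl.queries):
            g = genes[cl.start_gene_index + i]
            lines.append(_hit_line(q, g, rng, PLANTED_BITSCORE_RANGE))
            n_planted += 1
    n_background = 0
    if spec.hit_rate > 0:
        for q in spec.queries:
            for rep_id in sorted(by_rep):
                for _ in range(int(rng.poisson(spec.hit_rate))):
                    g = by_rep[rep_id][int(rng.integers(len(by_rep[rep_id])))]
                    lines.append(
                        _hit_line(q, g, rng, BACKGROUND_BITSCORE_RANGE)
                    )
                    n_background += 1
    with open(path, "w") as fh:
        for line in lines:
            fh.write(line + "\n")
    return path, n_planted, n_background


_DBTYPE = {"blastn": "nucl", "blastp": "prot", "tblastn": "nucl"}


def run_blast(
    query_fasta: str,
    subject_fasta: str,
    out_path: str,
    program: str = "blastn",
    evalue_cutoff: float = EVALUE_CUTOFF_DEFAULT,
    max_results: int = MAX_RESULTS_DEFAULT,
) -> str:
    """Run a local BLAST+ search, writing 12-column tabular output.

    Optional convenience over ``makeblastdb`` + the chosen program with
    ``-outfmt 6``.  Raises :class:`BlastNotInstalledError` when the
    binaries are absent — distinguishable from a BLAST runtime failure,
    which raises :class:`RuntimeError` with the tool's stderr.
    """
    if program not in _DBTYPE:
        raise ValueError(f"unsupported program {program!r}")
    if shutil.which(program) is None or shutil.which("makeblastdb") is None:
        raise BlastNotInstalledError("blast not installed")
    db = out_path + ".db"
    mk = subprocess.run(
        ["makeblastdb", "-in", subject_fasta, "-dbtype", _DBTYPE[program],
         "-out", db],
        capture_output=True, text=True,
    )
    if mk.returncode != 0:
        raise RuntimeError(f"makeblastdb failed: {mk.stderr.strip()}")
    cmd = [
        program, "-query", query_fasta, "-db", db, "-outfmt", "6",
        "-evalue", str(evalue_cutoff), "-max_target_seqs", str(max_results),
        "-out", out_path,
    ]
    res = subprocess.run(cmd, capture_output=True, text=True)
    if res.returncode != 0:
        raise RuntimeError(f"{program} failed: {res.stderr.strip()}")
    return out_path
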