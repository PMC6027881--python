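"""The core coordinate method: circular replicons on a fixed 0-360 axis.

Every replicon — chromosome or plasmid, whatever its size — is drawn as a
straight horizontal line of fixed length 360 (the degrees of a circle), so
a genomic position is mapped by its *relative* position instead of its
nucleotide position.  The y axis counts the replicons in the job, from 1
upward.  Each BLAST result becomes a dot at the strand-aware origin of
the subject gene, a vector whose magnitude is the gene length in degrees
and whose sign is the transcription sense, an alignment sub-segment over
the vector, and a color driven by the BLAST BitScore — dark blue for the
most significant down to yellow for the least.

Degree convention: base ``b`` of a length-``L`` replicon occupies the
half-open interval ``[360(b-1)/L, 360b/L)``, which makes the first base's
start exactly 0, the final base's end exactly 360, and the map
measure-preserving.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .model import (
    FULL_CIRCLE_DEG,
    BlastHit,
    GeneFeature,
    PlottedResult,
    Replicon,
)

#: Color-scale endpoints: dark blue = most significant, yellow = least.
DARK_BLUE = (0, 0, 139)
YELLOW = (255, 255, 0)


def relative_coordinate(
    pos_bp: int, replicon_length_bp: int, boundary: str = "start"
) -> float:
    """Degree coordinate of one base boundary.

    ``boundary="start"`` gives the left edge ``360*(pos-1)/L`` of the
    base's degree interval, ``"end"`` its right edge ``360*pos/L``.
    Positions beyond ``L`` (origin-wrap normalized coordinates) are
    reduced modulo the replicon length first.
    """
    if replicon_length_bp < 1:
        raise ValueError(f"replicon length must be >= 1, got {replicon_length_bp}")
    if pos_bp < 1:
        raise ValueError(f"position must be >= 1, got {pos_bp}")
    if boundary not in ("start", "end"):
        raise ValueError(f"boundary must be 'start' or 'end', got {boundary!r}")
    L = replicon_length_bp
    pos = (pos_bp - 1) % L + 1  # reduce wrap-normalized coordinates
    if boundary == "start":
        return FULL_CIRCLE_DEG * (pos - 1) / L
    return FULL_CIRCLE_DEG * pos / L


def degrees_per_bp(replicon_length_bp: int) -> float:
    return FULL_CIRCLE_DEG / replicon_length_bp


def assign_replicon_indices(replicons: Sequence[Replicon]) -> List[Replicon]:
    """Assign y-axis indices 1..N in the canonical order.

    Order: organism name ascending, then length descending within an
    organism (so a chromosome precedes its plasmids), ties broken by
    replicon_id.  Deterministic for identical input, regardless of the
    order replicons were listed in.
    """
    ids = [r.replicon_id for r in replicons]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValueError(f"duplicate replicon_id(s): {sorted(dupes)}")
    ordered = sorted(
        replicons, key=lambda r: (r.organism, -r.length_bp, r.replicon_id)
    )
    out = []
    for idx, r in enumerate(ordered, start=1):
        out.append(
            Replicon(
                replicon_id=r.replicon_id,
                length_bp=r.length_bp,
                organism=r.organism,
                topology=r.topology,
                replicon_index=idx,
            )
        )
    return out


@dataclass(frozen=True)
class ColorScale:
    """Linear BitScore -> color map over a job's full result set.

    Normalization is computed once over the full (capped) result set —
    not per zoomed view — so colors stay stable while panning.
    """

    min_bitscore: float
    max_bitscore: float
    low_color: Tuple[int, int, int] = YELLOW
    high_color: Tuple[int, int, int] = DARK_BLUE

    def __post_init__(self) -> None:
        if self.min_bitscore > self.max_bitscore:
            raise ValueError("min_bitscore must be <= max_bitscore")

    @classmethod
    def from_results(cls, bitscores: Sequence[float]) -> "ColorScale":
        if not bitscores:
            return cls(0.0, 0.0)
        return cls(min(bitscores), max(bitscores))

    def color_value(self, bitscore: float) -> float:
        if not math.isfinite(bitscore):
            raise ValueError(f"bitscore must be finite, got {bitscore}")
        if self.max_bitscore == self.min_bitscore:
            return 1.0  # degenerate scale: everything is "most significant"
        v = (bitscore - self.min_bitscore) / (self.max_bitscore - self.min_bitscore)
        return min(1.0, max(0.0, v))


def bitscore_to_color(
    bitscore: float, scale: ColorScale
) -> Tuple[float, Tuple[int, int, int]]:
    """Normalized significance in [0,1] plus the interpolated RGB triple."""
    v = scale.color_value(bitscore)
    rgb = tuple(
        round(lo + v * (hi - lo))
        for lo, hi in zip(scale.low_color, scale.high_color)
    )
    return v, rgb


def _subject_length(feature: GeneFeature, unit: str) -> int:
    """Length of the BLAST subject in its own coordinate unit."""
    if unit == "protein":
        # residue count of the encoded protein; codon-level phase
        # bookkeeping is deliberately avoided (invisible at 360-unit
        # resolution)
        return max(1, feature.length_bp // 3)
    return feature.length_bp


def project_hit(
    hit: BlastHit,
    feature: GeneFeature,
    replicon: Replicon,
    scale: ColorScale,
) -> PlottedResult:
    """Project one resolved hit into plot coordinates.

    The dot sits at the strand-aware transcription start of the subject
    gene (lower genomic boundary for ``+`` features, upper for ``-``);
    the vector points in the transcription sense with magnitude
    ``360 * gene_length / replicon_length``.  The aligned region becomes
    a sub-segment of the vector: the subject-coordinate interval
    ``min(s_start, s_end) .. max(s_start, s_end)`` as a fraction of the
    subject length, scaled to the vector magnitude.
    """
    if replicon.replicon_index is None:
        raise ValueError(
            f"replicon {replicon.replicon_id!r} has no index assigned"
        )
    L = replicon.length_bp
    sub_len = _subject_length(feature, hit.unit)
    s_lo, s_hi = min(hit.s_start, hit.s_end), max(hit.s_start, hit.s_end)
    if s_lo < 1 or s_hi > sub_len:
        raise ValueError(
            f"hit {hit.query_id!r} -> {hit.subject_id!r}: subject coordinates "
            f"{hit.s_start}..{hit.s_end} outside subject length {sub_len}"
        )
    vector_mag = FULL_CIRCLE_DEG * feature.length_bp / L
    if feature.strand == "+":
        x = relative_coordinate(feature.start_bp, L, "start")
        vector = vector_mag
    else:
        x = relative_coordinate(feature.end_bp, L, "end")
        vector = -vector_mag
    seg_offset = (s_lo - 1) / sub_len * vector_mag
    seg_len = (s_hi - s_lo + 1) / sub_len * vector_mag
    return PlottedResult(
        x=x,
        y=replicon.replicon_index,
        vector_deg=vector,
        seg_offset_deg=seg_offset,
        seg_len_deg=seg_len,
        strand=feature.strand,
        bitscore=hit.bitscore,
        color_value=scale.color_value(hit.bitscore),
        evalue=hit.evalue,
        query_id=hit.query_id,
        subject_id=hit.subject_id,
        organism=replicon.organism,
        product=feature.product,
        replicon_id=replicon.replicon_id,
        s_start=hit.s_start,
        s_end=hit.s_end,
    )


def project_hit_genome(
    hit: BlastHit, replicon: Replicon, scale: ColorScale
) -> PlottedResult:
    """Project a hit whose subject is a whole replicon (no annotation join).

    Used for genome-database searches: x comes from the lower subject
    coordinate, the vector spans the aligned interval, strand from the
    orientation of ``s_start``/``s_end``, and the alignment segment
    covers the whole vector.
    """
    if replicon.replicon_index is None:
        raise ValueError(
            f"replicon {replicon.replicon_id!r} has no index assigned"
        )
    L = replicon.length_bp
    s_lo, s_hi = min(hit.s_start, hit.s_end), max(hit.s_start, hit.s_end)
    if s_lo < 1 or s_hi > L:
        raise ValueError(
            f"hit {hit.query_id!r}: subject coordinates {hit.s_start}.."
            f"{hit.s_end} outside replicon length {L}"
        )
    strand = "-" if hit.s_end < hit.s_start else "+"
    vector_mag = FULL_CIRCLE_DEG * (s_hi - s_lo + 1) / L
    if strand == "+":
        x = relative_coordinate(s_lo, L, "start")
        vector = vector_mag
    else:
        x = relative_coordinate(s_hi, L, "end")
        vector = -vector_mag
    return PlottedResult(
        x=x,
        y=replicon.replicon_index,
        vector_deg=vector,
        seg_offset_deg=0.0,
        seg_len_deg=vector_mag,
        strand=strand,
        bitscore=hit.bitscore,
        color_value=scale.color_value(hit.bitscore),
        evalue=hit.evalue,
        query_id=hit.query_id,
        subject_id=hit.subject_id,
        organism=replicon.organism,
        product="",
        replicon_id=replicon.replicon_id,
        s_start=hit.s_start,
        s_end=hit.s_end,
    )


def resolve_subject(
    subject_id: str,
    by_feature_id: Dict[str, GeneFeature],
    by_locus_tag: Dict[str, GeneFeature],
) -> Optional[GeneFeature]:
    """Two-stage subject lookup: exact feature ID first, then locus_tag."""
    return by_feature_id.get(subject_id) or by_locus_tag.get(subject_id)


def project_hits(
    hits: Sequence[BlastHit],
    features: Sequence[GeneFeature],
    replicons: Sequence[Replicon],
    scale: Optional[ColorScale] = None,
) -> Tuple[List[PlottedResult], List[BlastHit]]:
    """Project every resolvable hit; return ``(results, unresolved_hits)``.

    Every resolvable hit yields exactly one result; hits whose subject
    matches no feature ID or locus_tag are returned separately (counted,
    never silently dropped).  When no scale is given, one is computed
    from the bitscores of the resolvable hits.
    """
    rep_by_id = {r.replicon_id: r for r in replicons}
    for r in rep_by_id.values():
        if r.replicon_index is None:
            raise ValueError("assign_replicon_indices must run before projection")
    by_fid = {f.feature_id: f for f in features}
    by_tag = {f.locus_tag: f for f in features if f.locus_tag}
    resolved: List[Tuple[BlastHit, GeneFeature]] = []
    unresolved: List[BlastHit] = []
    for h in hits:
        f = resolve_subject(h.subject_id, by_fid, by_tag)
        if f is None:
            unresolved.append(h)
        else:
            resolved.append((h, f))
    if scale is None:
        scale = ColorScale.from_results([h.bitscore for h, _ in resolved])
    out = [
        project_hit(h, f, rep_by_id[f.replicon_id], scale) for h, f in resolved
    ]
    return out, unresolved
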