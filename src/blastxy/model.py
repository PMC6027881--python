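"""Core domain records shared across the package.

A *replicon* is a self-replicating DNA unit (a bacterial/archaeal chromosome
or plasmid).  Each replicon becomes one horizontal track of the plot: its
full length is rescaled to a fixed 360-unit axis (the degrees of a circle)
and its track number is the plot's y value.  Gene annotations and raw BLAST
tabular rows are carried as plain records; ``PlottedResult`` is a BLAST hit
after projection onto that coordinate system.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

#: Fixed length of the linearized replicon axis, in degrees of a circle.
FULL_CIRCLE_DEG = 360.0

TOPOLOGIES = ("circular", "linear")
STRANDS = ("+", "-")
SUBJECT_UNITS = ("nucleotide", "protein")


@dataclass
class Replicon:
    """A chromosome or plasmid with its length and (assigned) y-axis index."""

    replicon_id: str
    length_bp: int
    organism: str = ""
    topology: str = "circular"
    replicon_index: Optional[int] = None

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise ValueError(
                f"replicon {self.replicon_id!r}: length_bp must be >= 1, "
                f"got {self.length_bp}"
            )
        if self.topology not in TOPOLOGIES:
            raise ValueError(
                f"replicon {self.replicon_id!r}: topology must be one of "
                f"{TOPOLOGIES}, got {self.topology!r}"
            )
        if self.replicon_index is not None and self.replicon_index < 1:
            raise ValueError("replicon_index must be >= 1 once assigned")


@dataclass
class GeneFeature:
    """An annotated gene/CDS, 1-based inclusive coordinates.

    Features annotated across the origin of a circular replicon are
    normalized to ``end_bp = annotated_end + replicon_length`` with
    ``wraps_origin=True`` so the ``start_bp <= end_bp`` invariant holds
    while the true length is preserved.
    """

    replicon_id: str
    feature_id: str
    start_bp: int
    end_bp: int
    strand: str
    locus_tag: str = ""
    product: str = ""
    wraps_origin: bool = False

    def __post_init__(self) -> None:
        if self.start_bp < 1:
            raise ValueError(
                f"feature {self.feature_id!r}: start_bp must be >= 1"
            )
        if self.end_bp < self.start_bp:
            raise ValueError(
                f"feature {self.feature_id!r}: end_bp {self.end_bp} < "
                f"start_bp {self.start_bp}"
            )
        if self.strand not in STRANDS:
            raise ValueError(
                f"feature {self.feature_id!r}: strand must be '+' or '-', "
                f"got {self.strand!r}"
            )

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass
class BlastHit:
    """One row of 12-column BLAST tabular output (``-outfmt 6``)."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float
    unit: str = "nucleotide"  # coordinate unit of s_start/s_end

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"hit {self.query_id!r}: evalue must be >= 0")
        if self.aln_length < 1:
            raise ValueError(f"hit {self.query_id!r}: aln_length must be >= 1")
        if self.unit not in SUBJECT_UNITS:
            raise ValueError(f"unit must be one of {SUBJECT_UNITS}")


@dataclass
class PlottedResult:
    """A BLAST hit projected onto the 0-360 x / replicon-index y plane.

    ``x`` is the strand-aware origin of the subject gene in degrees.
    ``vector_deg`` has magnitude proportional to the gene length (in
    degrees) and sign equal to the transcription sense (+ toward
    increasing degrees).  The aligned region is a sub-segment of the
    vector, ``seg_offset_deg`` from the dot and ``seg_len_deg`` long.
    ``color_value`` is the normalized significance in [0, 1]
    (1 = most significant = dark blue; 0 = least = yellow).
    """

    x: float
    y: int
    vector_deg: float
    seg_offset_deg: float
    seg_len_deg: float
    strand: str
    bitscore: float
    color_value: float
    evalue: float
    query_id: str
    subject_id: str
    organism: str
    product: str
    replicon_id: str
    s_start: int
    s_end: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.x <= FULL_CIRCLE_DEG:
            raise ValueError(f"x must be in [0, 360], got {self.x}")
        if self.y < 1:
            raise ValueError(f"y (replicon index) must be >= 1, got {self.y}")
        if self.seg_offset_deg < 0 or self.seg_len_deg < 0:
            raise ValueError("alignment segment must have non-negative extent")
        if self.seg_offset_deg + self.seg_len_deg > abs(self.vector_deg) + 1e-9:
            raise ValueError(
                "alignment segment extends past the end of the gene vector"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PlottedResult":
        return cls(**d)
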