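"""Result-table operations: sorting, "contains" filtering, caps, clustering.

The tool keeps two bounds on result volume: a *raw cap* (default one
million rows) on what is exported at all, and a *display cap* (default
fifty thousand rows) on what is handed to the renderers — more than that
saturates the plot.  When a cap binds, the most significant hits are kept
(bitscore first), matching the significance-centric color semantics.

All operations are pure: input row lists are never mutated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

from .model import PlottedResult

DISPLAY_CAP_DEFAULT = 50_000
RAW_CAP_DEFAULT = 1_000_000
CLUSTER_WINDOW_DEG_DEFAULT = 5.0

#: Table column -> PlottedResult attribute.  Text columns admit "contains"
#: filtering; numeric columns admit numeric sorting.
TEXT_COLUMNS = {
    "Query": "query_id",
    "Subject": "subject_id",
    "Organism": "organism",
    "Product": "product",
    "Replicon": "replicon_id",
}
NUMERIC_COLUMNS = {
    "RelPosition": "x",
    "BitScore": "bitscore",
    "Evalue": "evalue",
    "Y": "y",
}
ALL_COLUMNS = {**TEXT_COLUMNS, **NUMERIC_COLUMNS}


@dataclass(frozen=True)
class FilterSpec:
    """A single "contains" condition on one table column.

    Matching is case-sensitive literal substring — the semantics the
    underscore-suffix query naming convention (``SSI_`` vs ``SSII_``)
    relies on.  Multiple filters compose with AND.
    """

    column: str
    needle: str
    mode: str = "contains"

    def __post_init__(self) -> None:
        if self.column not in TEXT_COLUMNS:
            raise ValueError(
                f"unknown filter column {self.column!r}; "
                f"expected one of {sorted(TEXT_COLUMNS)}"
            )
        if self.mode != "contains":
            raise ValueError(f"unsupported filter mode {self.mode!r}")
        if not self.needle:
            raise ValueError("filter needle must be non-empty")

    def matches(self, row: PlottedResult) -> bool:
        return self.needle in getattr(row, TEXT_COLUMNS[self.column])


@dataclass
class Cluster:
    """A run of results at nearby relative positions on one replicon."""

    replicon_id: str
    members: List[PlottedResult]
    span: Tuple[float, float]

    def __len__(self) -> int:
        return len(self.members)


def filter_table(
    rows: Sequence[PlottedResult], filters: Iterable[FilterSpec]
) -> List[PlottedResult]:
    """Rows surviving every filter (AND composition), original order kept."""
    filters = list(filters)
    return [r for r in rows if all(f.matches(r) for f in filters)]


def sort_table(
    rows: Sequence[PlottedResult], column: str, direction: str = "asc"
) -> List[PlottedResult]:
    """Stable sort on one column; ties keep their prior relative order."""
    if column not in ALL_COLUMNS:
        raise ValueError(
            f"unknown sort column {column!r}; expected one of "
            f"{sorted(ALL_COLUMNS)}"
        )
    if direction not in ("asc", "desc"):
        raise ValueError(f"direction must be 'asc' or 'desc', got {direction!r}")
    attr = ALL_COLUMNS[column]
    return sorted(
        rows, key=lambda r: getattr(r, attr), reverse=(direction == "desc")
    )


def significance_key(row: PlottedResult) -> Tuple:
    """Canonical significance ordering: bitscore desc, evalue asc, y asc, x asc."""
    return (-row.bitscore, row.evalue, row.y, row.x)


def canonical_order(rows: Sequence[PlottedResult]) -> List[PlottedResult]:
    """Rows in canonical significance order (stable on input order)."""
    return sorted(rows, key=significance_key)


def apply_result_cap(
    rows: Sequence[PlottedResult], cap: int
) -> Tuple[List[PlottedResult], int]:
    """Retain at most ``cap`` rows, most significant first.

    Returns ``(retained, n_discarded)``.  If the cap does not bind the
    input is returned unchanged; otherwise exactly the top-``cap`` rows
    under the canonical significance ordering (ties broken by input
    order, since the sort is stable) are returned in that order.
    """
    if cap < 1:
        raise ValueError(f"cap must be >= 1, got {cap}")
    rows = list(rows)
    if len(rows) <= cap:
        return rows, 0
    retained = canonical_order(rows)[:cap]
    return retained, len(rows) - cap


def detect_clusters(
    rows: Sequence[PlottedResult],
    window_deg: float = CLUSTER_WINDOW_DEG_DEFAULT,
) -> List[Cluster]:
    """Single-linkage grouping of results along x, per replicon.

    Within one replicon, rows sorted by x are split into a new cluster
    whenever the gap to the previous x exceeds ``window_deg``.  Clusters
    never span replicons; every row belongs to exactly one cluster.
    Useful for spotting operon-like runs of hits — in the projected plot
    it is easily noticed when two or more results sit close together.
    """
    if not window_deg > 0:
        raise ValueError(f"window_deg must be > 0, got {window_deg}")
    by_replicon: dict = {}
    for r in rows:
        by_replicon.setdefault(r.replicon_id, []).append(r)
    clusters: List[Cluster] = []
    for rep_id in sorted(by_replicon):
        members = sorted(by_replicon[rep_id], key=lambda r: r.x)
        current = [members[0]]
        for r in members[1:]:
            if r.x - current[-1].x > window_deg:
                clusters.append(
                    Cluster(rep_id, current, (current[0].x, current[-1].x))
                )
                current = [r]
            else:
                current.append(r)
        clusters.append(Cluster(rep_id, current, (current[0].x, current[-1].x)))
    return clusters


@dataclass
class ResultTable:
    """Ordered result collection with filter/sort state and the two caps."""

    rows: List[PlottedResult] = field(default_factory=list)
    active_filters: List[FilterSpec] = field(default_factory=list)
    sort_column: Optional[str] = None
    sort_direction: str = "asc"
    display_cap: int = DISPLAY_CAP_DEFAULT
    raw_cap: int = RAW_CAP_DEFAULT

    def __post_init__(self) -> None:
        if self.display_cap < 1 or self.raw_cap < 1:
            raise ValueError("caps must be >= 1")

    def filtered(self) -> List[PlottedResult]:
        view = filter_table(self.rows, self.active_filters)
        if self.sort_column is not None:
            view = sort_table(view, self.sort_column, self.sort_direction)
        return view

    def display_rows(self) -> Tuple[List[PlottedResult], int]:
        """Filtered rows under the display cap: ``(rows, n_discarded)``."""
        return apply_result_cap(self.filtered(), self.display_cap)
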