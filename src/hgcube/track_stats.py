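"""Statistics over tracks and track groups.

These are the quantities that fill data-cube cells: group summaries
(track count, base-pair coverage, average segment length), the
observed-vs-expected coverage ratio under a uniform-across-categories null,
and the pairwise relation statistics between two tracks — overlap,
query-normalized overlap, and the Forbes colocalization coefficient.

Forbes coefficient
------------------
For tracks A and B on a genome of ``G`` bp::

    F = G * |A ∩ B| / (|A| * |B|)

where ``|·|`` is bp coverage. This is observed overlap divided by the
overlap expected if A and B were placed independently on the genome:
``F = 1`` means no association, ``F > 1`` colocalization enrichment,
``F < 1`` depletion. Binned at 1 bp this reduces to the classical 2×2
Forbes association index.

Undefined statistics (e.g. a ratio with a zero denominator) return the
module-level sentinel :data:`NA` (NaN), never 0, so cube aggregation can
skip them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .genome import GenomeDef
from .track_store import IndexedTrack, overlap_bp, overlap_count

NA = float("nan")

STAT_NAMES = ("count", "coverage_bp", "avg_segment_length", "obs_exp_ratio",
              "overlap_bp", "overlap_count", "normalized_overlap", "forbes")

RELATION_STATS = ("overlap_bp", "overlap_count", "normalized_overlap", "forbes")


def is_na(value: float) -> bool:
    return isinstance(value, float) and math.isnan(value)


@dataclass(frozen=True)
class StatResult:
    """A named scalar statistic with its provenance."""

    statistic: str
    value: float
    n_tracks: int = 0
    provenance: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if self.statistic not in STAT_NAMES:
            raise ValueError(f"unknown statistic {self.statistic!r}")
        if self.n_tracks < 0:
            raise ValueError("n_tracks must be >= 0")


# -- group statistics ------------------------------------------------------

def count_stat(group: Sequence[IndexedTrack]) -> int:
    """Total element count over the group (mutation count for point
    tracks)."""
    return sum(t.count_elements() for t in group)


def group_coverage(group: Sequence[IndexedTrack]) -> int:
    """Total bp coverage summed over tracks (each track merged
    individually; tracks are not merged against each other)."""
    return sum(t.coverage_bp() for t in group)


def group_summary(group: Sequence[IndexedTrack]) -> tuple[int, int, float]:
    """(number of tracks, total bp coverage, average segment length).

    The average is mean element length over the whole group (total element
    length over total element count; for segment tracks element length is
    the merged coverage). (0, 0, 0.0) for an empty group, average 0.0 when
    the group holds no elements.
    """
    n = len(group)
    cov = group_coverage(group)
    count = count_stat(group)
    total_len = sum(t.total_element_length() for t in group)
    return n, cov, (total_len / count if count else 0.0)


def obs_exp_coverage(cell_coverage: float,
                     all_coverages: Sequence[float]) -> float:
    """Observed / expected coverage for one cell of a complete partition.

    The null allocates the partition's total coverage uniformly across its
    groups: ``expected = sum(all_coverages) / len(all_coverages)``. Ratios
    over the full partition therefore average to exactly 1. Returns
    :data:`NA` when the expected coverage is 0.
    """
    if not all_coverages:
        return NA
    expected = sum(all_coverages) / len(all_coverages)
    if expected == 0:
        return NA
    return cell_coverage / expected


# -- pairwise relation statistics -----------------------------------------

def normalized_overlap(query: IndexedTrack, reference: IndexedTrack,
                       normalize_by: str = "query") -> float:
    """Overlap as a fraction of one track's coverage.

    Default is query-normalized: the fraction of the query track lying
    inside the reference (for a point query this is points-in-reference
    over total points). ``normalize_by="reference"`` gives the
    reference-normalized variant. :data:`NA` if the denominator track is
    empty.
    """
    if normalize_by not in ("query", "reference"):
        raise ValueError(f"normalize_by must be 'query' or 'reference', got {normalize_by!r}")
    denom_track = query if normalize_by == "query" else reference
    denom = denom_track.coverage_bp()
    if denom == 0:
        return NA
    return overlap_bp(query, reference) / denom


def forbes(a: IndexedTrack, b: IndexedTrack,
           genome: GenomeDef | None = None) -> float:
    """Forbes colocalization coefficient ``G·|A∩B| / (|A|·|B|)``.

    :data:`NA` if either track has zero coverage.
    """
    genome = genome or a.genome
    cov_a, cov_b = a.coverage_bp(), b.coverage_bp()
    if cov_a == 0 or cov_b == 0:
        return NA
    return genome.G * overlap_bp(a, b) / (cov_a * cov_b)


def relation_stat(name: str, a: IndexedTrack, b: IndexedTrack) -> float:
    """Dispatch a pairwise statistic by name (query = ``a``)."""
    if name == "overlap_bp":
        return float(overlap_bp(a, b))
    if name == "overlap_count":
        return float(overlap_count(a, b))
    if name == "normalized_overlap":
        return normalized_overlap(a, b)
    if name == "forbes":
        return forbes(a, b)
    raise ValueError(f"unknown relation statistic {name!r}; "
                     f"choose from {RELATION_STATS}")
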