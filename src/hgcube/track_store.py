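"""Indexed genomic tracks and interval statistics.

BED tracks are held as per-chromosome, sorted numpy interval arrays — an
in-memory index supporting the coverage and overlap queries the rest of the
package is built on. Coordinates are BED-native throughout: 0-based,
half-open ``[start, end)``.

Semantics, chosen to match mutation-counting use:

* **segment tracks** are merged for coverage purposes (bookended intervals
  ``(a,b),(b,c)`` merge into ``(a,c)``); ``count_elements`` counts merged
  intervals;
* **point tracks** (unit-length elements, e.g. somatic mutations) keep
  duplicates — two mutations at one position count twice — and
  ``count_elements`` counts raw elements.

Strand is ignored for interval arithmetic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .genome import GenomeDef, GenomeError

log = logging.getLogger(__name__)

POINTS = "points"
SEGMENTS = "segments"


class BedError(ValueError):
    """Raised for malformed BED input."""


@dataclass(frozen=True)
class Interval:
    """One track element: ``[start, end)`` on ``chrom``; ``name`` optionally
    carries a feature or mutation-type label."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    value: float | None = None


def _merge(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge sorted intervals; bookended intervals coalesce."""
    if len(starts) == 0:
        return starts, ends
    cummax = np.maximum.accumulate(ends)
    new_group = np.concatenate(([True], starts[1:] > cummax[:-1]))
    first = np.flatnonzero(new_group)
    last = np.append(first[1:], len(starts)) - 1
    return starts[first], cummax[last]


class IndexedTrack:
    """Per-chromosome sorted interval arrays with cached merged views."""

    def __init__(self, genome: GenomeDef, track_type: str,
                 data: dict[str, tuple[np.ndarray, np.ndarray, list[str] | None]]):
        if track_type not in (POINTS, SEGMENTS):
            raise ValueError(f"track_type must be {POINTS!r} or {SEGMENTS!r}, got {track_type!r}")
        self.genome = genome
        self.track_type = track_type
        self._data = data
        self._merged_cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    # -- construction ------------------------------------------------------

    @classmethod
    def from_intervals(cls, genome: GenomeDef, intervals: Iterable[Interval],
                       track_type: str = SEGMENTS) -> "IndexedTrack":
        by_chrom: dict[str, list[tuple[int, int, str | None]]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, iv.name))
        data = {}
        for chrom, items in by_chrom.items():
            if chrom not in genome:
                raise GenomeError(f"interval on unknown chromosome {chrom!r}")
            clen = genome.length(chrom)
            for s, e, _ in items:
                if not (0 <= s < e <= clen):
                    raise BedError(f"invalid interval {chrom}:{s}-{e} (chromosome length {clen})")
                if track_type == POINTS and e != s + 1:
                    raise BedError(f"point track element {chrom}:{s}-{e} is not unit-length")
            items.sort(key=lambda t: (t[0], t[1]))
            starts = np.array([t[0] for t in items], dtype=np.int64)
            ends = np.array([t[1] for t in items], dtype=np.int64)
            names = [t[2] for t in items]
            has_names = any(n is not None for n in names)
            data[chrom] = (starts, ends, names if has_names else None)
        return cls(genome, track_type, data)

    @classmethod
    def empty(cls, genome: GenomeDef, track_type: str = SEGMENTS) -> "IndexedTrack":
        return cls(genome, track_type, {})

    # -- accessors ---------------------------------------------------------

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(c for c in self.genome.names if c in self._data)

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        if chrom in self._data:
            s, e, _ = self._data[chrom]
            return s, e
        z = np.empty(0, dtype=np.int64)
        return z, z

    def names(self, chrom: str) -> list[str] | None:
        return self._data.get(chrom, (None, None, None))[2]

    def merged(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        if chrom not in self._merged_cache:
            self._merged_cache[chrom] = _merge(*self.arrays(chrom))
        return self._merged_cache[chrom]

    def intervals(self) -> list[Interval]:
        out = []
        for chrom in self.chroms:
            s, e, _ = self._data[chrom]
            names = self.names(chrom)
            for i in range(len(s)):
                out.append(Interval(chrom, int(s[i]), int(e[i]),
                                    names[i] if names else None))
        return out

    # -- statistics --------------------------------------------------------

    def coverage_bp(self) -> int:
        """Total bp covered (merged sense)."""
        return int(sum((me - ms).sum() for ms, me in
                       (self.merged(c) for c in self.chroms)))

    def count_elements(self) -> int:
        """Raw element count for point tracks, merged-interval count for
        segment tracks."""
        if self.track_type == POINTS:
            return int(sum(len(self.arrays(c)[0]) for c in self.chroms))
        return int(sum(len(self.merged(c)[0]) for c in self.chroms))

    def total_element_length(self) -> int:
        """Sum of element lengths: raw count for point tracks (unit
        elements, duplicates included), merged coverage for segments."""
        if self.track_type == POINTS:
            return self.count_elements()
        return self.coverage_bp()

    def avg_segment_length(self) -> float:
        """Mean element length (exactly 1.0 for any non-empty point
        track); 0.0 for an empty track."""
        n = self.count_elements()
        return self.total_element_length() / n if n else 0.0


def coverage_bp(track: IndexedTrack) -> int:
    return track.coverage_bp()


def count_elements(track: IndexedTrack) -> int:
    return track.count_elements()


def avg_segment_length(track: IndexedTrack) -> float:
    return track.avg_segment_length()


def _check_same_genome(a: IndexedTrack, b: IndexedTrack) -> None:
    if a.genome != b.genome:
        raise GenomeError(
            f"genome mismatch: {a.genome.name!r} vs {b.genome.name!r}")


def overlap_bp(a: IndexedTrack, b: IndexedTrack) -> int:
    """Total bp in the intersection of the two merged interval sets.

    Computed per chromosome via inclusion–exclusion with the merged union:
    ``|A ∩ B| = |A| + |B| − |A ∪ B|``.
    """
    _check_same_genome(a, b)
    total = 0
    for chrom in a.genome.names:
        asx, aex = a.merged(chrom)
        bsx, bex = b.merged(chrom)
        if len(asx) == 0 or len(bsx) == 0:
            continue
        cov_a = int((aex - asx).sum())
        cov_b = int((bex - bsx).sum())
        s = np.concatenate([asx, bsx])
        e = np.concatenate([aex, bex])
        order = np.argsort(s, kind="stable")
        us, ue = _merge(s[order], e[order])
        total += cov_a + cov_b - int((ue - us).sum())
    return total


def overlap_count(points: IndexedTrack, regions: IndexedTrack) -> int:
    """Number of elements of ``points`` whose position falls inside
    ``regions`` (merged sense). Duplicated points count individually."""
    _check_same_genome(points, regions)
    if points.track_type != POINTS:
        raise ValueError("overlap_count requires a point track as first argument")
    total = 0
    for chrom in points.chroms:
        p, _ = points.arrays(chrom)
        rs, re = regions.merged(chrom)
        if len(p) == 0 or len(rs) == 0:
            continue
        idx = np.searchsorted(rs, p, side="right") - 1
        inside = idx >= 0
        inside[inside] &= p[inside] < re[idx[inside]]
        total += int(inside.sum())
    return total


def union(tracks: Sequence[IndexedTrack]) -> IndexedTrack:
    """Interval-wise union of tracks of one type on one genome.

    Point tracks: multiset union (duplicates kept, names preserved).
    Segment tracks: merged interval union (names dropped on merge).
    """
    if not tracks:
        raise ValueError("union of zero tracks")
    genome, ttype = tracks[0].genome, tracks[0].track_type
    for t in tracks[1:]:
        _check_same_genome(tracks[0], t)
        if t.track_type != ttype:
            raise ValueError("cannot union point and segment tracks")
    data = {}
    for chrom in genome.names:
        parts = [(t.arrays(chrom), t.names(chrom)) for t in tracks
                 if len(t.arrays(chrom)[0])]
        if not parts:
            continue
        s = np.concatenate([p[0][0] for p in parts])
        e = np.concatenate([p[0][1] for p in parts])
        names: list[str | None] = []
        for (st, _en), nm in parts:
            names.extend(nm if nm is not None else [None] * len(st))
        order = np.lexsort((e, s))
        s, e = s[order], e[order]
        names = [names[i] for i in order]
        if ttype == SEGMENTS:
            s, e = _merge(s, e)
            names = None
        elif not any(n is not None for n in names):
            names = None
        data[chrom] = (s, e, names)
    return IndexedTrack(genome, ttype, data)


# -- BED I/O ---------------------------------------------------------------

def read_bed(path: str | Path, genome: GenomeDef, track_type: str = SEGMENTS,
             policy: str = "strict") -> IndexedTrack:
    """Read a BED3+ file into an :class:`IndexedTrack`.

    ``policy="strict"`` rejects intervals on chromosomes absent from the
    genome or extending past the chromosome end; ``"lenient"`` drops unknown
    chromosomes (with a logged warning) and clips overlong intervals.
    """
    if policy not in ("strict", "lenient"):
        raise ValueError(f"policy must be 'strict' or 'lenient', got {policy!r}")
    path = Path(path)
    intervals: list[Interval] = []
    dropped = 0
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise BedError(f"{path}:{lineno}: expected at least 3 tab-separated fields")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise BedError(f"{path}:{lineno}: non-integer coordinates") from None
        name = fields[3] if len(fields) > 3 and fields[3] not in (".", "") else None
        if start >= end or start < 0:
            raise BedError(f"{path}:{lineno}: invalid interval {chrom}:{start}-{end}")
        if chrom not in genome:
            if policy == "strict":
                raise BedError(f"{path}:{lineno}: chromosome {chrom!r} not in genome "
                               f"{genome.name!r} (use lenient policy to drop)")
            dropped += 1
            continue
        clen = genome.length(chrom)
        if end > clen:
            if policy == "strict":
                raise BedError(f"{path}:{lineno}: end {end} exceeds length of "
                               f"{chrom} ({clen})")
            end = clen
            if start >= end:
                dropped += 1
                continue
        intervals.append(Interval(chrom, start, end, name))
    if dropped:
        log.warning("%s: dropped %d interval(s) outside genome %s",
                    path, dropped, genome.name)
    return IndexedTrack.from_intervals(genome, intervals, track_type)


def write_bed(track: IndexedTrack, path: str | Path) -> None:
    """Write raw (pre-merge for points, merged for segments) intervals as
    BED3/BED4."""
    with open(path, "w") as fh:
        for chrom in track.chroms:
            if track.track_type == SEGMENTS:
                s, e = track.merged(chrom)
                names = None
            else:
                s, e = track.arrays(chrom)
                names = track.names(chrom)
            for i in range(len(s)):
                if names is not None and names[i] is not None:
                    fh.write(f"{chrom}\t{s[i]}\t{e[i]}\t{names[i]}\n")
                else:
                    fh.write(f"{chrom}\t{s[i]}\t{e[i]}\n")


class TrackLoader:
    """Resolve hGSuite entry URIs to :class:`IndexedTrack`, with caching.

    Track files are looked up relative to ``base_dir``; the suite's declared
    track type decides point vs segment semantics unless overridden.
    """

    def __init__(self, genome: GenomeDef, base_dir: str | Path = ".",
                 track_type: str | None = None, policy: str = "strict"):
        self.genome = genome
        self.base_dir = Path(base_dir)
        self.track_type = track_type
        self.policy = policy
        self._cache: dict[tuple[str, str], IndexedTrack] = {}

    def __call__(self, entry, track_type: str | None = None) -> IndexedTrack:
        ttype = track_type or self.track_type or SEGMENTS
        key = (entry.uri, ttype)
        if key not in self._cache:
            p = Path(entry.uri)
            if not p.is_absolute():
                p = self.base_dir / p
            self._cache[key] = read_bed(p, self.genome, ttype, self.policy)
        return self._cache[key]
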