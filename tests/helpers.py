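"""Shared test utilities: brute-force per-base oracles and random generators.

The oracles deliberately avoid the package's interval arithmetic: every
statistic is recomputed from a per-base boolean array over a small genome,
so agreement is meaningful.
"""

from __future__ import annotations

import numpy as np

from hgcube.genome import GenomeDef
from hgcube.hgsuite_format import GSuiteHeader, HGSuite, TrackEntry
from hgcube.track_store import POINTS, SEGMENTS, IndexedTrack, Interval


# -- per-base oracles ------------------------------------------------------

def base_mask(track: IndexedTrack) -> dict[str, np.ndarray]:
    """Boolean per-base presence array per chromosome (merged sense)."""
    masks = {}
    for chrom, clen in track.genome.chroms:
        m = np.zeros(clen, dtype=bool)
        s, e = track.arrays(chrom)
        for i in range(len(s)):
            m[s[i]:e[i]] = True
        masks[chrom] = m
    return masks


def oracle_coverage(track: IndexedTrack) -> int:
    return int(sum(m.sum() for m in base_mask(track).values()))


def oracle_overlap_bp(a: IndexedTrack, b: IndexedTrack) -> int:
    ma, mb = base_mask(a), base_mask(b)
    return int(sum((ma[c] & mb[c]).sum() for c in ma))


def oracle_overlap_count(points: IndexedTrack, regions: IndexedTrack) -> int:
    mr = base_mask(regions)
    n = 0
    for chrom in points.chroms:
        pos, _ = points.arrays(chrom)
        for p in pos:
            if mr[chrom][p]:
                n += 1
    return n


def oracle_forbes(a, b, genome: GenomeDef) -> float:
    ca, cb = oracle_coverage(a), oracle_coverage(b)
    return genome.G * oracle_overlap_bp(a, b) / (ca * cb)


# -- random inputs ---------------------------------------------------------

def random_segment_track(rng: np.random.Generator, genome: GenomeDef,
                         n: int, max_len: int = 50) -> IndexedTrack:
    ivs = []
    for _ in range(n):
        chrom, clen = genome.chroms[rng.integers(len(genome.chroms))]
        length = int(rng.integers(1, max_len + 1))
        start = int(rng.integers(0, clen - length))
        ivs.append(Interval(chrom, start, start + length))
    return IndexedTrack.from_intervals(genome, ivs, SEGMENTS)


def random_point_track(rng: np.random.Generator, genome: GenomeDef,
                       n: int, names=None) -> IndexedTrack:
    ivs = []
    for i in range(n):
        chrom, clen = genome.chroms[rng.integers(len(genome.chroms))]
        p = int(rng.integers(0, clen))
        ivs.append(Interval(chrom, p, p + 1,
                            names[i % len(names)] if names else None))
    return IndexedTrack.from_intervals(genome, ivs, POINTS)


def random_suite(rng: np.random.Generator) -> HGSuite:
    """A random valid hGSuite: 0–3 hierarchy levels, missing values, and
    extra pragmas — for format round-trip checks."""
    n_cols = int(rng.integers(0, 4))
    columns = tuple(f"col{i}" for i in range(n_cols))
    n_hier = int(rng.integers(0, n_cols + 1))
    hierarchy = tuple(rng.permutation(columns)[:n_hier])
    extra = (("note", "x y z"),) if rng.random() < 0.3 else ()
    header = GSuiteHeader(
        location="local",
        file_format=("primary", "preprocessed")[rng.integers(2)],
        track_type=("points", "segments", "unknown")[rng.integers(3)],
        genome=f"g{rng.integers(3)}",
        hierarchy=hierarchy,
        extra_pragmas=extra,
    )
    n_entries = int(rng.integers(0, 6))
    values = ["WT", "KO", "a b", ".", "v-1"]
    entries = []
    for i in range(n_entries):
        meta = {c: values[rng.integers(len(values))] for c in columns
                if rng.random() < 0.8}
        entries.append(TrackEntry(uri=f"t{i}.bed", title=f"track{i}", metadata=meta))
    return HGSuite(header=header, columns=columns, entries=tuple(entries))
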