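"""The metadata-dimensioned data cube.

A :class:`DataCube` is a dense multidimensional array of statistic values
whose axes are hierarchy metadata columns and whose coordinates are the
category labels of those columns. It is built from one hGSuite (cell =
statistic of the tracks sharing that category combination) or from a pair
of suites (cell = pairwise relation statistic between the two groups), and
then explored with the classic cube operations:

* **slice** — fix one category, dropping the dimension;
* **dice**  — restrict a dimension to a category subset;
* **aggregate** — collapse a dimension with a reducer (mean/sum/min/max/count);
* **pivot / transpose** — render a rank-2 cube as a labelled table.

Category combinations not present in the source suite yield NA cells
(NaN), which aggregation skips by default.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .hgsuite_format import HGSuite, HGSuiteError, TrackEntry
from .track_store import IndexedTrack, union
from . import track_stats
from .track_stats import NA, RELATION_STATS

CUBE_STATS = ("count", "coverage_bp", "avg_segment_length", "obs_exp_ratio")
REDUCERS = ("mean", "sum", "min", "max", "count")


class CubeError(ValueError):
    """Raised for invalid cube construction or queries."""


@dataclass(frozen=True)
class CubeSchema:
    """Ordered dimensions (name, ordered category labels) plus the
    statistic the cells hold."""

    dims: tuple[tuple[str, tuple[str, ...]], ...]
    statistic: str

    def __post_init__(self):
        dims = tuple((str(n), tuple(cats)) for n, cats in self.dims)
        object.__setattr__(self, "dims", dims)
        names = [n for n, _ in dims]
        if len(set(names)) != len(names):
            raise CubeError(f"duplicate dimension names: {names}")
        for n, cats in dims:
            if len(set(cats)) != len(cats):
                raise CubeError(f"duplicate categories in dimension {n!r}")

    @property
    def dim_names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.dims)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(len(cats) for _, cats in self.dims)

    def axis(self, dim: str) -> int:
        try:
            return self.dim_names.index(dim)
        except ValueError:
            raise CubeError(f"unknown dimension {dim!r}; "
                            f"have {list(self.dim_names)}") from None

    def categories(self, dim: str) -> tuple[str, ...]:
        return self.dims[self.axis(dim)][1]


class DataCube:
    """Dense statistic array addressed by one category per dimension."""

    def __init__(self, schema: CubeSchema, values: np.ndarray,
                 provenance: np.ndarray | None = None):
        values = np.asarray(values, dtype=float)
        if values.shape != schema.shape:
            raise CubeError(f"values shape {values.shape} != schema shape {schema.shape}")
        if provenance is None:
            provenance = np.empty(schema.shape, dtype=object)
            for idx in np.ndindex(*schema.shape):
                provenance[idx] = ()
        self.schema = schema
        self.values = values
        self.provenance = provenance

    @property
    def rank(self) -> int:
        return len(self.schema.dims)

    def __getitem__(self, categories: str | tuple[str, ...]) -> float:
        """Look up one cell by its category labels (in dimension order)."""
        if isinstance(categories, str):
            categories = (categories,)
        if len(categories) != self.rank:
            raise CubeError(f"need {self.rank} categories, got {len(categories)}")
        idx = tuple(self._cat_index(dim, cat)
                    for (dim, _), cat in zip(self.schema.dims, categories))
        return float(self.values[idx])

    def cell_provenance(self, categories: tuple[str, ...]) -> tuple[str, ...]:
        idx = tuple(self._cat_index(dim, cat)
                    for (dim, _), cat in zip(self.schema.dims, categories))
        return self.provenance[idx]

    def _cat_index(self, dim: str, category: str) -> int:
        cats = self.schema.categories(dim)
        try:
            return cats.index(category)
        except ValueError:
            raise CubeError(f"unknown category {category!r} in dimension {dim!r}; "
                            f"valid: {list(cats)}") from None


# -- construction ----------------------------------------------------------

def _categories_in_order(suite: HGSuite, column: str,
                         order: Sequence[str] | None = None) -> tuple[str, ...]:
    seen: list[str] = []
    for e in suite.entries:
        v = e.get(column)
        if v not in seen:
            seen.append(v)
    if order is not None:
        missing = set(seen) - set(order)
        if missing:
            raise CubeError(f"order for {column!r} omits categories {sorted(missing)}")
        return tuple(c for c in order if c in seen)
    return tuple(seen)


def _group_entries(suite: HGSuite, dims: Sequence[str]) -> dict[tuple, list[TrackEntry]]:
    groups: dict[tuple, list[TrackEntry]] = {}
    for e in suite.entries:
        key = tuple(e.get(d) for d in dims)
        groups.setdefault(key, []).append(e)
    return groups


def build_cube(suite: HGSuite, statistic: str,
               track_loader: Callable[[TrackEntry], IndexedTrack],
               order: dict[str, Sequence[str]] | None = None) -> DataCube:
    """Build a cube from one hGSuite.

    Dimensions are the suite's hierarchy columns in order; categories appear
    in first-appearance order (overridable per dimension via ``order``).
    Each cell holds ``statistic`` over the tracks of its category
    combination; combinations with no tracks are NA.
    """
    if statistic not in CUBE_STATS:
        raise CubeError(f"unknown cube statistic {statistic!r}; choose from {CUBE_STATS}")
    hierarchy = suite.hierarchy
    if not hierarchy:
        raise CubeError("suite declares no hierarchy; add a '##hierarchy:' "
                        "pragma naming the metadata columns to use as dimensions")
    order = order or {}
    dims = tuple((d, _categories_in_order(suite, d, order.get(d)))
                 for d in hierarchy)
    schema = CubeSchema(dims=dims, statistic=statistic)
    values = np.full(schema.shape, NA)
    provenance = np.empty(schema.shape, dtype=object)
    for idx in np.ndindex(*schema.shape):
        provenance[idx] = ()

    groups = _group_entries(suite, hierarchy)
    cat_index = [{c: i for i, c in enumerate(cats)} for _, cats in dims]
    cell_tracks: dict[tuple, list[IndexedTrack]] = {}
    for key, entries in groups.items():
        idx = tuple(cat_index[a][v] for a, v in enumerate(key))
        cell_tracks[idx] = [track_loader(e) for e in entries]
        provenance[idx] = tuple(e.title for e in entries)

    base = "coverage_bp" if statistic == "obs_exp_ratio" else statistic
    for idx, tracks in cell_tracks.items():
        if base == "count":
            values[idx] = track_stats.count_stat(tracks)
        elif base == "coverage_bp":
            values[idx] = track_stats.group_coverage(tracks)
        elif base == "avg_segment_length":
            _, _, avg = track_stats.group_summary(tracks)
            values[idx] = avg
    if statistic == "obs_exp_ratio":
        observed = [values[idx] for idx in cell_tracks]
        for idx in cell_tracks:
            values[idx] = track_stats.obs_exp_coverage(values[idx], observed)
    return DataCube(schema, values, provenance)


def build_relation_cube(suite_a: HGSuite, suite_b: HGSuite, statistic: str,
                        track_loader_a: Callable[[TrackEntry], IndexedTrack],
                        track_loader_b: Callable[[TrackEntry], IndexedTrack] | None = None,
                        reduce: str = "union",
                        order: dict[str, Sequence[str]] | None = None) -> DataCube:
    """Build a relation cube between two hGSuites.

    Dimensions are A's hierarchy followed by B's; each cell holds the
    pairwise ``statistic`` (overlap_bp, overlap_count, normalized_overlap,
    forbes) between the tracks of the A-cell and the B-cell. Multi-track
    cells are reduced by interval union before the statistic
    (``reduce="union"``) or averaged over all track pairs
    (``reduce="pair_mean"``).
    """
    if statistic not in RELATION_STATS:
        raise CubeError(f"unknown relation statistic {statistic!r}; "
                        f"choose from {RELATION_STATS}")
    if reduce not in ("union", "pair_mean"):
        raise CubeError(f"reduce must be 'union' or 'pair_mean', got {reduce!r}")
    if not suite_a.hierarchy or not suite_b.hierarchy:
        raise CubeError("both suites must declare a hierarchy")
    shared = set(suite_a.hierarchy) & set(suite_b.hierarchy)
    if shared:
        raise CubeError(f"hierarchies share dimension name(s) {sorted(shared)}; "
                        "rename a metadata column first")
    loader_b = track_loader_b or track_loader_a
    order = order or {}
    dims_a = tuple((d, _categories_in_order(suite_a, d, order.get(d)))
                   for d in suite_a.hierarchy)
    dims_b = tuple((d, _categories_in_order(suite_b, d, order.get(d)))
                   for d in suite_b.hierarchy)
    schema = CubeSchema(dims=dims_a + dims_b, statistic=statistic)
    values = np.full(schema.shape, NA)
    provenance = np.empty(schema.shape, dtype=object)
    for idx in np.ndindex(*schema.shape):
        provenance[idx] = ()

    groups_a = _group_entries(suite_a, suite_a.hierarchy)
    groups_b = _group_entries(suite_b, suite_b.hierarchy)
    cat_index = [{c: i for i, c in enumerate(cats)} for _, cats in schema.dims]
    na = len(dims_a)

    tracks_a = {k: [track_loader_a(e) for e in v] for k, v in groups_a.items()}
    tracks_b = {k: [loader_b(e) for e in v] for k, v in groups_b.items()}
    union_a = {k: union(v) for k, v in tracks_a.items()}
    union_b = {k: union(v) for k, v in tracks_b.items()}

    for key_a, ents_a in groups_a.items():
        idx_a = tuple(cat_index[i][v] for i, v in enumerate(key_a))
        for key_b, ents_b in groups_b.items():
            idx_b = tuple(cat_index[na + i][v] for i, v in enumerate(key_b))
            idx = idx_a + idx_b
            if reduce == "union":
                values[idx] = track_stats.relation_stat(
                    statistic, union_a[key_a], union_b[key_b])
            else:
                pair_vals = [track_stats.relation_stat(statistic, ta, tb)
                             for ta in tracks_a[key_a] for tb in tracks_b[key_b]]
                finite = [v for v in pair_vals if not math.isnan(v)]
                values[idx] = (sum(finite) / len(finite)) if finite else NA
            provenance[idx] = tuple(e.title for e in ents_a + ents_b)
    return DataCube(schema, values, provenance)


# -- cube operations -------------------------------------------------------

def slice_cube(cube: DataCube, dim: str, category: str) -> DataCube:
    """Fix one category of ``dim`` and drop the dimension (rank − 1)."""
    axis = cube.schema.axis(dim)
    i = cube._cat_index(dim, category)
    schema = CubeSchema(dims=cube.schema.dims[:axis] + cube.schema.dims[axis + 1:],
                        statistic=cube.schema.statistic)
    return DataCube(schema, np.take(cube.values, i, axis=axis),
                    np.take(cube.provenance, i, axis=axis))


def dice(cube: DataCube, dim: str, categories: Sequence[str]) -> DataCube:
    """Restrict ``dim`` to a subset of categories, keeping the dimension
    (order follows the requested subset)."""
    axis = cube.schema.axis(dim)
    idx = [cube._cat_index(dim, c) for c in categories]
    dims = list(cube.schema.dims)
    dims[axis] = (dim, tuple(categories))
    schema = CubeSchema(dims=tuple(dims), statistic=cube.schema.statistic)
    return DataCube(schema, np.take(cube.values, idx, axis=axis),
                    np.take(cube.provenance, idx, axis=axis))


def _reduce_values(block: np.ndarray, reducer: str) -> float:
    finite = block[~np.isnan(block)]
    if reducer == "count":
        return float(len(finite))
    if len(finite) == 0:
        return NA
    if reducer == "mean":
        return float(finite.mean())
    if reducer == "sum":
        return float(finite.sum())
    if reducer == "min":
        return float(finite.min())
    if reducer == "max":
        return float(finite.max())
    raise CubeError(f"unknown reducer {reducer!r}; choose from {REDUCERS}")


def aggregate(cube: DataCube, dim: str, reducer: str,
              strict_na: bool = False) -> DataCube:
    """Collapse ``dim`` with a reducer (rank − 1).

    NA cells are skipped; the result is NA iff all inputs were NA (for
    ``count`` the result is the number of non-NA inputs, possibly 0). With
    ``strict_na=True`` any NA input makes the result NA.
    """
    if reducer not in REDUCERS:
        raise CubeError(f"unknown reducer {reducer!r}; choose from {REDUCERS}")
    axis = cube.schema.axis(dim)
    schema = CubeSchema(dims=cube.schema.dims[:axis] + cube.schema.dims[axis + 1:],
                        statistic=cube.schema.statistic)
    moved = np.moveaxis(cube.values, axis, -1)
    prov_moved = np.moveaxis(cube.provenance, axis, -1)
    out = np.full(schema.shape, NA)
    prov = np.empty(schema.shape, dtype=object)
    for idx in np.ndindex(*schema.shape):
        block = moved[idx]
        if strict_na and np.isnan(block).any():
            out[idx] = NA
        else:
            out[idx] = _reduce_values(block, reducer)
        merged: tuple[str, ...] = ()
        for p in prov_moved[idx]:
            merged += tuple(t for t in p if t not in merged)
        prov[idx] = merged
    return DataCube(schema, out, prov)


def pivot(cube: DataCube, row_dim: str | None = None,
          col_dim: str | None = None) -> pd.DataFrame:
    """Render a rank-2 cube as a labelled rows × columns table.

    With no arguments the first dimension becomes rows. Higher-rank cubes
    must be sliced or aggregated first.
    """
    if cube.rank != 2:
        raise CubeError(f"pivot needs a rank-2 cube, got rank {cube.rank}; "
                        "slice or aggregate the other dimension(s) first")
    names = cube.schema.dim_names
    if row_dim is None and col_dim is None:
        row_dim, col_dim = names
    elif col_dim is None:
        col_dim = next(n for n in names if n != row_dim)
    elif row_dim is None:
        row_dim = next(n for n in names if n != col_dim)
    if {row_dim, col_dim} != set(names):
        raise CubeError(f"row/col dims must be {list(names)}, got "
                        f"({row_dim!r}, {col_dim!r})")
    values = cube.values if names[0] == row_dim else cube.values.T
    df = pd.DataFrame(values,
                      index=pd.Index(cube.schema.categories(row_dim), name=row_dim),
                      columns=pd.Index(cube.schema.categories(col_dim), name=col_dim))
    return df


def transpose(table: pd.DataFrame) -> pd.DataFrame:
    """Swap rows and columns of a pivoted table."""
    return table.T


def to_table(cube: DataCube, dest, fmt: str = "tsv") -> None:
    """Write a rank ≤ 2 cube as a delimited text table (NA → ``"NA"``).

    Rank-2 cubes pivot to rows × columns; rank-1 cubes become a two-column
    (category, value) table; rank-0 a single labelled value.
    """
    if fmt not in ("tsv", "csv"):
        raise CubeError(f"format must be 'tsv' or 'csv', got {fmt!r}")
    sep = "\t" if fmt == "tsv" else ","
    if cube.rank > 2:
        raise CubeError(f"cannot tabulate a rank-{cube.rank} cube; "
                        "slice or aggregate down to rank 2 first")
    if cube.rank == 2:
        df = pivot(cube)
    elif cube.rank == 1:
        name, cats = cube.schema.dims[0]
        df = pd.DataFrame({cube.schema.statistic: cube.values},
                          index=pd.Index(cats, name=name))
    else:
        df = pd.DataFrame({cube.schema.statistic: [float(cube.values)]},
                          index=pd.Index(["value"], name=""))
    df.to_csv(dest, sep=sep, na_rep="NA")


# -- serialization (for chaining CLI steps) --------------------------------

def save_cube(cube: DataCube, prefix: str | Path) -> None:
    """Persist a cube as ``<prefix>.schema.json`` plus a long-format
    ``<prefix>.values.tsv`` (one row per cell, provenance ';'-joined)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    schema = {"dims": [[n, list(c)] for n, c in cube.schema.dims],
              "statistic": cube.schema.statistic}
    Path(f"{prefix}.schema.json").write_text(json.dumps(schema, indent=1) + "\n")
    with open(f"{prefix}.values.tsv", "w") as fh:
        fh.write("\t".join(cube.schema.dim_names + ("value", "provenance")) + "\n")
        for idx in np.ndindex(*cube.schema.shape):
            cats = [cube.schema.dims[a][1][i] for a, i in enumerate(idx)]
            v = float(cube.values[idx])
            fh.write("\t".join(cats + ["NA" if math.isnan(v) else repr(v),
                                       ";".join(cube.provenance[idx])]) + "\n")


def load_cube(prefix: str | Path) -> DataCube:
    prefix = Path(prefix)
    meta = json.loads(Path(f"{prefix}.schema.json").read_text())
    schema = CubeSchema(dims=tuple((n, tuple(c)) for n, c in meta["dims"]),
                        statistic=meta["statistic"])
    values = np.full(schema.shape, NA)
    provenance = np.empty(schema.shape, dtype=object)
    for idx in np.ndindex(*schema.shape):
        provenance[idx] = ()
    cat_index = [{c: i for i, c in enumerate(cats)} for _, cats in schema.dims]
    with open(f"{prefix}.values.tsv") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        ndim = len(schema.dims)
        if tuple(header[:ndim]) != schema.dim_names:
            raise CubeError("values table does not match schema sidecar")
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            idx = tuple(cat_index[a][fields[a]] for a in range(ndim))
            values[idx] = NA if fields[ndim] == "NA" else float(fields[ndim])
            provenance[idx] = tuple(t for t in fields[ndim + 1].split(";") if t)
    return DataCube(schema, values, provenance)
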