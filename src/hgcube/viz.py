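"""Mutation-profile visual analytics.

Each plotting tool is split into a deterministic **table computation** and a
**rendering step** that consumes only the table, so analyses are testable
and reproducible without comparing pixels:

* :func:`rainfall_table` / :func:`plot_rainfall` — genomic position vs
  distance to the previous mutation; runs of small distances expose
  hypermutated (kataegis-like) regions;
* :func:`frequency_table` / :func:`plot_frequency` — mutations per fixed-
  size bin along chromosomes, with optional overlay feature layers (exons,
  CpG islands, ...);
* :func:`flanking_composition` / :func:`plot_flanking` — base composition
  around each mutation, per mutation type, a first step toward
  mutational-signature contexts;
* :func:`boxplot_summary` / :func:`plot_box` — five-number summaries per
  group;
* :func:`hierarchical_clustering` / :func:`plot_dendrogram` — agglomerative
  clustering of rows with a newick export.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeDef, GenomeError
from .hgsuite_format import HGSuite, HGSuiteError
from .metadata_ops import MutationTypeLabel
from .track_store import POINTS, IndexedTrack

log = logging.getLogger(__name__)

#: Fixed colors per collapsed mutation class (COSMIC-style palette).
MUTATION_COLORS = {
    "C>A": "#2196f3", "C>G": "#212121", "C>T": "#e53935",
    "T>A": "#9e9e9e", "T>C": "#4caf50", "T>G": "#f48fb1",
}


def _normalize_mtype(name: str | None) -> str:
    if name is None:
        return "."
    try:
        return str(MutationTypeLabel.parse(name))
    except ValueError:
        return name


# -- rainfall --------------------------------------------------------------

def rainfall_table(track: IndexedTrack, scope: str = "genome",
                   per_type: bool = False) -> pd.DataFrame:
    """Inter-mutation distance table for rainfall plots.

    One row per mutation, sorted by genome-wide position (chromosomes
    concatenated in genome order for ``scope="genome"``; a single
    chromosome name restricts the view). ``dist`` is the bp distance to
    the previous mutation of any type — or of the same type when
    ``per_type`` — and is NA for the first point of each plotting group.
    """
    if track.track_type != POINTS:
        raise ValueError("rainfall plots require a point (mutation) track")
    offsets = track.genome.offsets()
    if scope != "genome" and scope not in track.genome:
        raise GenomeError(f"unknown chromosome {scope!r}")
    rows = []
    for chrom in track.chroms:
        if scope != "genome" and chrom != scope:
            continue
        pos, _ = track.arrays(chrom)
        names = track.names(chrom)
        off = offsets[chrom] if scope == "genome" else 0
        for i in range(len(pos)):
            mtype = _normalize_mtype(names[i] if names else None)
            rows.append((chrom, int(pos[i]), int(pos[i]) + off, mtype))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "global_pos", "mtype"])
    df = df.sort_values(["global_pos", "chrom", "pos"], kind="stable",
                        ignore_index=True)
    if per_type:
        df["dist"] = df.groupby("mtype")["global_pos"].diff()
    else:
        df["dist"] = df["global_pos"].diff()
    return df[["chrom", "pos", "global_pos", "dist", "mtype"]]


# -- binned frequency ------------------------------------------------------

def frequency_table(track: IndexedTrack, genome: GenomeDef, bin_size: int,
                    overlays: Mapping[str, IndexedTrack] | None = None
                    ) -> pd.DataFrame:
    """Mutations (and overlay features) per fixed-size bin.

    Bins tile each chromosome (``ceil(length / bin_size)`` bins, last bin
    possibly short). The mutation layer counts points per bin; overlay
    layers count elements once per bin they touch, so a segment spanning a
    bin boundary increments both bins.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    overlays = dict(overlays or {})
    frames = []
    for chrom, clen in genome.chroms:
        nbins = -(-clen // bin_size)
        starts = np.arange(nbins, dtype=np.int64) * bin_size
        cols = {"chrom": chrom, "bin_start": starts, "bin_size": bin_size}
        pos, _ = track.arrays(chrom)
        cols["mutations"] = np.bincount(pos // bin_size, minlength=nbins)
        for layer, ov in overlays.items():
            counts = np.zeros(nbins, dtype=np.int64)
            if ov.track_type == POINTS:
                s, _ = ov.arrays(chrom)
                if len(s):
                    counts = np.bincount(s // bin_size, minlength=nbins)
            else:
                s, e = ov.merged(chrom)
                for j in range(len(s)):
                    counts[s[j] // bin_size:(e[j] - 1) // bin_size + 1] += 1
            cols[layer] = counts
        frames.append(pd.DataFrame(cols))
    return pd.concat(frames, ignore_index=True)


# -- flanking-base composition ---------------------------------------------

def flanking_composition(track: IndexedTrack, fasta, k: int = 1) -> pd.DataFrame:
    """Tally reference bases flanking each mutation, per mutation type.

    ``fasta`` is a path to a FASTA of the track's genome (read with
    pyfaidx) or any mapping chromosome → sequence string. For each
    mutation the bases at offsets −k..−1 and +1..+k are counted under the
    mutation's type; positions clipped at chromosome ends are skipped.
    Lowercase bases are uppercased; anything outside ACGT counts as "N".
    """
    if k < 1:
        raise ValueError("flank width k must be >= 1")
    if track.track_type != POINTS:
        raise ValueError("flanking composition requires a point track")
    if isinstance(fasta, (str, Path)):
        from pyfaidx import Fasta
        fa = Fasta(str(fasta), as_raw=True, rebuild=False)
        seqs = {c: fa[c] for c in fa.keys()}
    else:
        seqs = fasta
    for chrom, clen in track.genome.chroms:
        if chrom not in seqs:
            raise GenomeError(f"FASTA lacks chromosome {chrom!r}")
        if len(seqs[chrom]) != clen:
            raise GenomeError(
                f"FASTA/genome length mismatch on {chrom!r}: "
                f"{len(seqs[chrom])} vs {clen}")
    counts: dict[tuple[str, int, str], int] = {}
    for chrom in track.chroms:
        seq = seqs[chrom]
        clen = track.genome.length(chrom)
        pos, _ = track.arrays(chrom)
        names = track.names(chrom)
        for i in range(len(pos)):
            mtype = _normalize_mtype(names[i] if names else None)
            p = int(pos[i])
            for off in list(range(-k, 0)) + list(range(1, k + 1)):
                q = p + off
                if not (0 <= q < clen):
                    continue
                base = str(seq[q]).upper()
                if base not in "ACGT":
                    base = "N"
                key = (mtype, off, base)
                counts[key] = counts.get(key, 0) + 1
    rows = [(m, o, b, c) for (m, o, b), c in sorted(counts.items())]
    return pd.DataFrame(rows, columns=["mtype", "offset", "base", "count"])


# -- box plots -------------------------------------------------------------

def boxplot_summary(data, value: str, group_by: str) -> pd.DataFrame:
    """Five-number summary (min, Q1, median, Q3, max) plus n per group.

    ``data`` is an :class:`HGSuite` (the columns name metadata columns) or
    a DataFrame with ``value`` and ``group_by`` columns. Quantiles use
    linear interpolation. Non-numeric values raise, naming the offender.
    """
    if isinstance(data, HGSuite):
        rows = []
        for e in data.entries:
            raw = e.get(value)
            try:
                v = float(raw)
            except ValueError:
                raise HGSuiteError(
                    f"entry {e.title!r}: non-numeric value {raw!r} in "
                    f"column {value!r}") from None
            rows.append((e.get(group_by), v))
        df = pd.DataFrame(rows, columns=[group_by, value])
    else:
        df = data[[group_by, value]].copy()
        bad = pd.to_numeric(df[value], errors="coerce").isna() & df[value].notna()
        if bad.any():
            raise ValueError(f"non-numeric value in row(s) {list(df.index[bad])}")
        df[value] = pd.to_numeric(df[value])
    out = []
    for group, sub in df.groupby(group_by, sort=True):
        vals = sub[value].to_numpy(dtype=float)
        if len(vals) == 0:
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        out.append((group, vals.min(), q1, med, q3, vals.max(), len(vals)))
    return pd.DataFrame(out, columns=[group_by, "min", "q1", "median",
                                      "q3", "max", "n"]).set_index(group_by)


# -- hierarchical clustering -----------------------------------------------

@dataclass(frozen=True)
class ClusterResult:
    """Agglomerative clustering output: scipy-style linkage matrix, merge
    list ``(i, j, height)``, newick text with branch lengths, and the
    dendrogram leaf order."""

    labels: tuple[str, ...]
    linkage_matrix: np.ndarray
    merges: tuple[tuple[int, int, float], ...]
    newick: str
    leaf_order: tuple[str, ...]


def hierarchical_clustering(matrix: pd.DataFrame,
                            distance: str = "euclidean",
                            linkage: str = "average") -> ClusterResult:
    """Cluster rows of a numeric matrix.

    ``distance`` is ``euclidean`` or ``correlation`` (1 − Pearson r);
    ``linkage`` one of ``average``, ``complete``, ``single``. Rows with
    missing values are dropped with a warning; fewer than 2 usable rows is
    an error. Ties break deterministically by row order (stable pairwise
    distance ordering).
    """
    from scipy.cluster import hierarchy as sch
    from scipy.spatial.distance import pdist

    if distance not in ("euclidean", "correlation"):
        raise ValueError(f"distance must be 'euclidean' or 'correlation', got {distance!r}")
    if linkage not in ("average", "complete", "single"):
        raise ValueError(f"linkage must be average/complete/single, got {linkage!r}")
    clean = matrix.dropna(axis=0)
    if len(clean) < len(matrix):
        log.warning("dropped %d row(s) with missing values",
                    len(matrix) - len(clean))
    if len(clean) < 2:
        raise ValueError("need at least 2 rows without missing values")
    labels = tuple(str(i) for i in clean.index)
    dists = pdist(clean.to_numpy(dtype=float), metric=distance)
    Z = sch.linkage(dists, method=linkage)
    merges = tuple((int(r[0]), int(r[1]), float(r[2])) for r in Z)
    leaf_order = tuple(labels[i] for i in sch.leaves_list(Z))

    tree = sch.to_tree(Z)

    def newick(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = newick(node.left, node.dist)
        right = newick(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    nwk = f"({newick(tree.left, tree.dist)},{newick(tree.right, tree.dist)});"
    return ClusterResult(labels=labels, linkage_matrix=Z, merges=merges,
                         newick=nwk, leaf_order=leaf_order)


# -- rendering -------------------------------------------------------------

def _fig(figsize=(10, 4)):
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    return plt.subplots(figsize=figsize)


def plot_rainfall(table: pd.DataFrame, path: str | Path, title: str = "") -> None:
    """Scatter global position vs log10 inter-mutation distance, colored by
    mutation type (zero distances plotted at a 1 bp pseudo-count)."""
    fig, ax = _fig()
    for mtype, sub in table.groupby("mtype", sort=True):
        d = sub["dist"].to_numpy(dtype=float)
        d = np.where(d <= 0, 1.0, d)
        ax.scatter(sub["global_pos"], np.log10(d), s=6,
                   color=MUTATION_COLORS.get(mtype), label=mtype)
    ax.set_xlabel("genomic position (bp)")
    ax.set_ylabel("log10 distance to previous mutation")
    ax.legend(fontsize=7, markerscale=2)
    if title:
        ax.set_title(title)
    fig.savefig(path, dpi=120)
    import matplotlib.pyplot as plt
    plt.close(fig)


def plot_frequency(table: pd.DataFrame, path: str | Path,
                   chrom: str | None = None) -> None:
    """Line plot of per-bin counts for the mutation layer and overlays."""
    fig, ax = _fig()
    sub = table[table["chrom"] == chrom] if chrom else table
    layers = [c for c in sub.columns if c not in ("chrom", "bin_start", "bin_size")]
    x = sub["bin_start"] + sub["bin_size"] // 2
    for layer in layers:
        ax.plot(x, sub[layer], label=layer, linewidth=1)
    ax.set_xlabel(f"position on {chrom} (bp)" if chrom else "bin start (bp)")
    ax.set_ylabel("count per bin")
    ax.legend(fontsize=7)
    fig.savefig(path, dpi=120)
    import matplotlib.pyplot as plt
    plt.close(fig)


def plot_flanking(table: pd.DataFrame, path: str | Path) -> None:
    """Grouped bars of flanking-base counts per mutation type and offset."""
    fig, ax = _fig((10, 5))
    table = table.copy()
    table["ctx"] = table["offset"].astype(str) + ":" + table["base"]
    wide = table.pivot_table(index="mtype", columns="ctx", values="count",
                             fill_value=0, aggfunc="sum")
    wide.plot.bar(ax=ax, width=0.85)
    ax.set_ylabel("count")
    ax.legend(fontsize=6, ncol=4)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    import matplotlib.pyplot as plt
    plt.close(fig)


def plot_box(summary: pd.DataFrame, path: str | Path, title: str = "") -> None:
    """Draw boxes from a precomputed five-number summary table."""
    fig, ax = _fig((6, 4))
    stats = [{"label": str(g), "whislo": r["min"], "q1": r["q1"],
              "med": r["median"], "q3": r["q3"], "whishi": r["max"],
              "fliers": []} for g, r in summary.iterrows()]
    ax.bxp(stats, showfliers=False)
    ax.set_ylabel("value")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    import matplotlib.pyplot as plt
    plt.close(fig)


def plot_dendrogram(result: ClusterResult, path: str | Path) -> None:
    from scipy.cluster import hierarchy as sch
    fig, ax = _fig((6, 4))
    sch.dendrogram(result.linkage_matrix, labels=list(result.labels), ax=ax,
                   leaf_rotation=90)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    import matplotlib.pyplot as plt
    plt.close(fig)
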