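"""Deterministic synthetic track collections.

Generates toy genomes, point (mutation) and segment (region) BED tracks,
and hGSuite files that structurally mirror the two bundled case studies:

* the **mouse preset** — mutation tracks for four genotypes (wild type, two
  single knockouts of uracil-repair glycosylases, and the double knockout)
  split by mutation type, with genotype-dependent mutation burdens and a
  shared hypermutation hotspot;
* the **cancer preset** — per-patient somatic mutation tracks for three
  tumor types (10 patients each), with a higher burden for skin cancer,
  plus companion region suites (coding/non-coding partition, DNA-repair
  pathways, open-chromatin assays) and a random reference FASTA.

The generative model is intentionally simple: per-track element counts are
Poisson around a category-dependent rate, positions are uniform on the
genome except inside hotspot windows where the intensity is multiplied.
All randomness flows through one ``numpy.random.default_rng(seed)`` stream
(PCG64, integer-seeded), so identical spec + seed reproduce byte-identical
files on any platform.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome import GenomeDef, toy_genome
from .hgsuite_format import GSuiteHeader, HGSuite, TrackEntry, write_hgsuite

ALL_MUTATION_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G",
                      "G>T", "G>C", "G>A", "A>T", "A>G", "A>C")

REPAIR_PATHWAYS = ("MMR", "BER", "NHEJ", "NER", "HR", "POL")

#: Substitution spectrum used when mutation type is not a cube dimension:
#: deamination-driven C>T / G>A dominate, as in real somatic catalogs.
DEFAULT_SPECTRUM = {
    "C>T": 0.25, "G>A": 0.25, "C>A": 0.08, "G>T": 0.08,
    "T>C": 0.07, "A>G": 0.07, "C>G": 0.04, "G>C": 0.04,
    "T>A": 0.03, "A>T": 0.03, "T>G": 0.03, "A>C": 0.03,
}


@dataclass(frozen=True)
class Hotspot:
    """A window where mutation intensity is multiplied."""

    chrom: str
    start: int
    end: int
    multiplier: float


@dataclass(frozen=True)
class FixtureSpec:
    """Conditions for one synthetic point-track suite."""

    dims: tuple[tuple[str, tuple[str, ...]], ...]
    genome: GenomeDef = field(default_factory=toy_genome)
    base_rate: float = 40.0
    multipliers: dict = field(default_factory=dict)  # dim -> {category: factor}
    mtype_dim: str | None = None       # dimension whose category labels the points
    spectrum: dict | None = None       # per-point mutation-type weights otherwise
    hotspots: tuple[Hotspot, ...] = ()
    seed: int = 0
    track_type: str = "points"

    def rate(self, combo: tuple[str, ...]) -> float:
        r = self.base_rate
        for (dim, _), cat in zip(self.dims, combo):
            r *= self.multipliers.get(dim, {}).get(cat, 1.0)
        return r


def _stem(combo: tuple[str, ...]) -> str:
    return "_".join(re.sub(r"[^A-Za-z0-9.+-]", "", c.replace(">", ""))
                    for c in combo)


def _sample_positions(rng: np.random.Generator, genome: GenomeDef,
                      hotspots: tuple[Hotspot, ...], n: int
                      ) -> list[tuple[str, int]]:
    """n positions, uniform with multiplicative hotspot windows.

    Sampling windows: each chromosome contributes background mass equal to
    its length; each hotspot adds ``(multiplier − 1) · window length`` extra
    mass on top, so density inside the window is ``multiplier ×``
    background.
    """
    windows = [(c, 0, l) for c, l in genome.chroms]
    weights = [float(l) for _, l in genome.chroms]
    for h in hotspots:
        if h.chrom not in genome or not (0 <= h.start < h.end <= genome.length(h.chrom)):
            raise ValueError(f"hotspot outside genome: {h}")
        if h.multiplier > 1:
            windows.append((h.chrom, h.start, h.end))
            weights.append((h.multiplier - 1.0) * (h.end - h.start))
    p = np.array(weights) / sum(weights)
    which = rng.choice(len(windows), size=n, p=p)
    out = []
    for w in which:
        chrom, s, e = windows[w]
        out.append((chrom, int(rng.integers(s, e))))
    return out


def generate_point_suite(spec: FixtureSpec, out_dir: str | Path,
                         suite_name: str = "mutations") -> HGSuite:
    """Write one point BED per category combination plus the hGSuite file.

    Counts are Poisson around :meth:`FixtureSpec.rate`; a zero draw still
    produces an (empty) track file so every combination is present. Point
    names carry the mutation type (the ``mtype_dim`` category, or a draw
    from ``spectrum``). Returns the parsed-equivalent suite; the suite file
    is ``<out_dir>/<suite_name>.gsuite``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    dim_names = tuple(d for d, _ in spec.dims)
    entries = []
    for combo in itertools.product(*(cats for _, cats in spec.dims)):
        n = int(rng.poisson(spec.rate(combo)))
        positions = _sample_positions(rng, spec.genome, spec.hotspots, n)
        if spec.mtype_dim is not None:
            mt = combo[dim_names.index(spec.mtype_dim)]
            names = [mt] * n
        elif spec.spectrum:
            labels = list(spec.spectrum)
            w = np.array([spec.spectrum[l] for l in labels], dtype=float)
            names = [labels[i] for i in rng.choice(len(labels), size=n, p=w / w.sum())]
        else:
            names = [None] * n
        order = sorted(range(n), key=lambda i: (spec.genome.names.index(positions[i][0]),
                                                positions[i][1]))
        stem = _stem(combo)
        with open(out_dir / f"{stem}.bed", "w") as fh:
            for i in order:
                chrom, pos = positions[i]
                if names[i] is None:
                    fh.write(f"{chrom}\t{pos}\t{pos + 1}\n")
                else:
                    fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{names[i]}\n")
        entries.append(TrackEntry(uri=f"{stem}.bed", title=stem,
                                  metadata=dict(zip(dim_names, combo))))
    header = GSuiteHeader(track_type=spec.track_type, genome=spec.genome.name,
                          hierarchy=dim_names)
    suite = HGSuite(header=header, columns=dim_names, entries=tuple(entries))
    write_hgsuite(suite, out_dir / f"{suite_name}.gsuite")
    spec.genome.to_chrom_sizes(out_dir / "chrom.sizes")
    return suite


def _tile_segments(rng: np.random.Generator, clen: int,
                   mean_seg: float, mean_gap: float) -> list[tuple[int, int]]:
    """Alternate exponential gaps and segments along one chromosome."""
    segs, pos = [], 0
    while pos < clen:
        pos += int(rng.exponential(mean_gap)) + 1
        if pos >= clen:
            break
        end = min(clen, pos + int(rng.exponential(mean_seg)) + 1)
        segs.append((pos, end))
        pos = end
    return segs


def generate_region_suite(kind: str, genome: GenomeDef, out_dir: str | Path,
                          seed: int = 0) -> HGSuite:
    """Segment suites standing in for annotation collections.

    ``kind="coding"`` — a coding/non-coding pair that exactly partitions
    the genome (coding drawn as exponential blocks covering roughly a
    third, non-coding the complement), hierarchy column ``region``;
    ``kind="pathways"`` — six DNA-repair pathway gene tracks, hierarchy
    column ``pathway``; ``kind="chromatin"`` — DNAseq/ATACseq open-
    chromatin tracks, hierarchy column ``assay``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    def write(stem: str, segs_by_chrom: dict[str, list[tuple[int, int]]]) -> str:
        with open(out_dir / f"{stem}.bed", "w") as fh:
            for chrom in genome.names:
                for s, e in segs_by_chrom.get(chrom, []):
                    fh.write(f"{chrom}\t{s}\t{e}\n")
        return f"{stem}.bed"

    if kind == "coding":
        coding, noncoding = {}, {}
        for chrom, clen in genome.chroms:
            segs = _tile_segments(rng, clen, mean_seg=200, mean_gap=400)
            coding[chrom] = segs
            comp, prev = [], 0
            for s, e in segs:
                if s > prev:
                    comp.append((prev, s))
                prev = e
            if prev < clen:
                comp.append((prev, clen))
            noncoding[chrom] = comp
        column, cats, files = "region", ("coding", "noncoding"), {}
        files["coding"] = write("coding", coding)
        files["noncoding"] = write("noncoding", noncoding)
        name = "regions"
    elif kind == "pathways":
        column, cats, files = "pathway", REPAIR_PATHWAYS, {}
        for pw in REPAIR_PATHWAYS:
            segs = {c: _tile_segments(rng, l, mean_seg=150, mean_gap=1200)
                    for c, l in genome.chroms}
            files[pw] = write(pw, segs)
        name = "pathways"
    elif kind == "chromatin":
        column, cats, files = "assay", ("DNAseq", "ATACseq"), {}
        for assay in cats:
            segs = {c: _tile_segments(rng, l, mean_seg=250, mean_gap=800)
                    for c, l in genome.chroms}
            files[assay] = write(assay, segs)
        name = "chromatin"
    else:
        raise ValueError(f"unknown region-suite kind {kind!r}; "
                         "choose coding/pathways/chromatin")

    entries = tuple(TrackEntry(uri=files[c], title=Path(files[c]).stem,
                               metadata={column: c}) for c in cats)
    header = GSuiteHeader(track_type="segments", genome=genome.name,
                          hierarchy=(column,))
    suite = HGSuite(header=header, columns=(column,), entries=entries)
    write_hgsuite(suite, out_dir / f"{name}.gsuite")
    return suite


def generate_fasta(genome: GenomeDef, seed: int, path: str | Path) -> None:
    """Uniform random ACGT reference of the genome's lengths, 60 bp/line."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    with open(path, "w") as fh:
        for chrom, clen in genome.chroms:
            fh.write(f">{chrom}\n")
            seq = "".join(bases[rng.integers(0, 4, size=clen)])
            for i in range(0, clen, 60):
                fh.write(seq[i:i + 60] + "\n")


# -- presets ---------------------------------------------------------------

MOUSE_GENOTYPES = ("WT", "UNG", "SMUG1", "DKO")
CANCER_TYPES = ("colorectal", "breast", "skin")


def mouse_spec(seed: int = 0, n_mutation_types: int = 4) -> FixtureSpec:
    """4 genotypes × mutation types, one track each.

    Burdens follow the qualitative picture the collection emulates: the UNG
    knockout accumulates the most mutations, the double knockout fewer than
    wild type, and C>T / G>A transitions dominate. A ×8 hotspot window on
    chr2 gives rainfall and frequency plots something to find.
    """
    if n_mutation_types == 4:
        mtypes: tuple[str, ...] = ("C>T", "G>A", "T>C", "C>A")
    elif n_mutation_types == 12:
        mtypes = ALL_MUTATION_TYPES
    else:
        raise ValueError("n_mutation_types must be 4 or 12")
    return FixtureSpec(
        dims=(("genotype", MOUSE_GENOTYPES), ("mutation_type", mtypes)),
        base_rate=40.0,
        multipliers={
            "genotype": {"WT": 1.0, "UNG": 2.2, "SMUG1": 1.0, "DKO": 0.6},
            "mutation_type": {"C>T": 3.0, "G>A": 3.0},
        },
        mtype_dim="mutation_type",
        hotspots=(Hotspot("chr2", 2000, 3000, 8.0),),
        seed=seed,
    )


def cancer_spec(seed: int = 0, patients_per_type: int = 10) -> FixtureSpec:
    """3 cancer types × patients, one mutation track per patient.

    Skin-cancer patients carry the highest burden (UV-driven), mutation
    types are drawn per point from a C>T-heavy spectrum. Patient IDs are
    globally unique (patient001…), so the cancer_type × patientID cube is
    sparse by construction: each patient has one tumor type.
    """
    patients = tuple(f"patient{i + 1:03d}"
                     for i in range(3 * patients_per_type))
    patient_mult = {}
    for i, p in enumerate(patients):
        ctype = CANCER_TYPES[i // patients_per_type]
        patient_mult[p] = {"colorectal": 1.2, "breast": 1.0, "skin": 3.0}[ctype]
    return FixtureSpec(
        dims=(("cancer_type", CANCER_TYPES), ("patientID", patients)),
        base_rate=60.0,
        multipliers={"patientID": patient_mult},
        spectrum=dict(DEFAULT_SPECTRUM),
        seed=seed,
    )


def _cancer_patient_type(patients_per_type: int = 10) -> dict[str, str]:
    return {f"patient{i + 1:03d}": CANCER_TYPES[i // patients_per_type]
            for i in range(3 * patients_per_type)}


def generate_cancer_suite(out_dir: str | Path, seed: int = 0,
                          patients_per_type: int = 10) -> HGSuite:
    """Cancer preset: one track per patient, hierarchy cancer_type,patientID.

    Unlike :func:`generate_point_suite` the category product is not full —
    each patient appears only under their own tumor type, leaving the other
    cube cells NA, as with real cohorts.
    """
    spec = cancer_spec(seed, patients_per_type)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    ptype = _cancer_patient_type(patients_per_type)
    labels = list(spec.spectrum)
    w = np.array([spec.spectrum[l] for l in labels], dtype=float)
    w /= w.sum()
    entries = []
    for patient, ctype in ptype.items():
        rate = spec.base_rate * spec.multipliers["patientID"][patient]
        n = int(rng.poisson(rate))
        positions = _sample_positions(rng, spec.genome, spec.hotspots, n)
        names = [labels[i] for i in rng.choice(len(labels), size=n, p=w)]
        order = sorted(range(n), key=lambda i: (spec.genome.names.index(positions[i][0]),
                                                positions[i][1]))
        stem = f"{ctype}_{patient}"
        with open(out_dir / f"{stem}.bed", "w") as fh:
            for i in order:
                chrom, pos = positions[i]
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{names[i]}\n")
        entries.append(TrackEntry(uri=f"{stem}.bed", title=stem,
                                  metadata={"cancer_type": ctype,
                                            "patientID": patient}))
    header = GSuiteHeader(track_type="points", genome=spec.genome.name,
                          hierarchy=("cancer_type", "patientID"))
    suite = HGSuite(header=header, columns=("cancer_type", "patientID"),
                    entries=tuple(entries))
    write_hgsuite(suite, out_dir / "patients.gsuite")
    spec.genome.to_chrom_sizes(out_dir / "chrom.sizes")
    return suite


def make_preset(preset: str, out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Materialize a full case-study fixture set in ``out_dir``.

    Returns paths keyed by artifact: the mutation suite, region suites,
    chrom.sizes and reference FASTA. Presets: ``mouse`` or ``cancer``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genome = toy_genome()
    paths: dict[str, Path] = {"chrom_sizes": out_dir / "chrom.sizes"}
    if preset == "mouse":
        generate_point_suite(mouse_spec(seed), out_dir)
        paths["mutations"] = out_dir / "mutations.gsuite"
    elif preset == "cancer":
        generate_cancer_suite(out_dir, seed)
        paths["mutations"] = out_dir / "patients.gsuite"
    else:
        raise ValueError(f"unknown preset {preset!r}; choose mouse or cancer")
    generate_region_suite("coding", genome, out_dir, seed=seed + 1)
    generate_region_suite("pathways", genome, out_dir, seed=seed + 2)
    generate_region_suite("chromatin", genome, out_dir, seed=seed + 3)
    paths["regions"] = out_dir / "regions.gsuite"
    paths["pathways"] = out_dir / "pathways.gsuite"
    paths["chromatin"] = out_dir / "chromatin.gsuite"
    fasta = out_dir / "reference.fa"
    generate_fasta(genome, seed + 4, fasta)
    paths["fasta"] = fasta
    return paths
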