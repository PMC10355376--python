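# Methods

## Coordinate model and merge semantics

All interval arithmetic is BED-native: 0-based, half-open `[start, end)`
coordinates on a declared genome (ordered chromosomes with lengths; the
total length `G` enters the expectation-based statistics). Two element
semantics coexist, chosen to match mutation-counting use:

* **segment tracks** (genes, peaks, regions) are merged: overlapping and
  bookended intervals coalesce, so coverage and counts are set-like;
* **point tracks** (mutations) are unit-length and keep duplicates — two
  mutations called at the same position are two events. Coverage is still
  merged (distinct covered bases), but counts and unions are multiset
  operations.

Average segment length is the mean *element* length: exactly 1 for point
tracks, merged coverage over merged-interval count for segments. Strand is
ignored in interval arithmetic; strand only enters when collapsing
complementary mutation types (C>T ≡ G>A on the reverse strand), which maps
the twelve substitutions onto the six pyrimidine-reference classes.

Overlap is computed per chromosome by inclusion–exclusion against the
merged union (`|A∩B| = |A|+|B|−|A∪B|`), and point membership by binary
search into merged region arrays. These paths are validated exactly
against brute-force boolean per-base arrays in the test suite; the toy
genome (3 chromosomes, 10/8/5 kb) is deliberately small enough that the
per-base oracle is cheap to run everywhere.

## Statistics

**Group summary** — number of tracks, summed coverage, mean element
length. Tracks are merged individually, not against each other, so a
group's coverage is additive over its tracks.

**Observed/expected coverage** — for the cells of a cube (a complete
partition of the suite), expected coverage is the partition total divided
by the number of occupied cells: a uniform-across-categories null.
Consequently the ratios average to exactly 1 over the partition, an
identity the tests check to 1e-12. Alternative nulls (proportional to
category size, GC- or mappability-aware) are out of scope.

**Normalized overlap** — overlap divided by *query* coverage by default
(the fraction of the query inside the reference; for point queries this is
points-in-reference / points). Because the natural reading is ambiguous, a
reference-normalized variant is exposed via `normalize_by="reference"`.

**Forbes coefficient** — `F = G·|A∩B| / (|A|·|B|)` in bp. Under
independent placement `E[|A∩B|] = |A|·|B|/G`, so `F` is observed over
expected overlap; binning the genome at 1 bp reduces it to the classical
2×2 Forbes association index. `F` is symmetric and proportional to `G`
for fixed tracks. Calibration is checked by simulation: for independent
uniform point tracks the mean over 200 replicates sits within 3 standard
errors of 1, and a shared 10× hotspot window pushes it well above 1.

**Undefined values** — any statistic with a zero denominator (empty query,
empty partition) returns NaN as an explicit not-available marker, never 0,
so aggregation can skip it.

## The data cube

Dimensions are the suite's hierarchy columns in declared order; categories
appear in first-appearance order (stable and reproducible), overridable
per dimension. Storage is dense; category combinations absent from the
suite (e.g. a patient under the wrong cancer type) are NA cells rather
than errors, since real cohorts rarely fill the category product. The
relation cube concatenates the two suites' hierarchies (dimension names
must be disjoint) and reduces multi-track cells by interval union before
the pairwise statistic; a per-pair-mean variant is available.

Operations: `slice` fixes a category and drops the dimension, `dice`
restricts categories, `aggregate` collapses a dimension with
mean/sum/min/max/count (NA skipped; result NA iff all inputs NA; a
`strict_na` flag propagates instead), `pivot`/`transpose` render rank-2
cubes as labelled tables. Cubes serialize to a JSON schema sidecar plus a
long-format TSV so CLI steps chain. Per-cell provenance (contributing
track titles) is carried through every operation; for a single-suite cube
the provenance sets partition the suite.

The cube is materialized eagerly; at the collection sizes this package
targets (hundreds of tracks, ≤ ~6 dimensions) dense storage is trivial and
lazy evaluation would only complicate provenance.

## Visual analytics

Every plot is a pure table computation plus a renderer that consumes only
the table, so tests assert on tables and outputs are byte-stable.

* **Rainfall** — points sorted by genome-wide position (chromosomes
  concatenated in genome order); distance is to the previous mutation of
  *any* type, the standard rainfall convention, with a `per_type` option
  since figure conventions vary. The y axis renders `log10(dist)` with a
  1 bp pseudo-count for co-located mutations. The first point of each
  plotting scope has NA distance.
* **Binned frequency** — `ceil(length/bin_size)` bins per chromosome;
  mutations counted by position, overlay features counted once per bin
  they touch (a segment spanning a boundary increments both bins). Counts,
  not densities, are reported; per-layer bin sums therefore equal element
  counts, a conservation law the tests rely on. Default bin size is 1 Mb
  for real genomes; the toy fixtures use 100–500 bp.
* **Flanking composition** — reference bases at offsets −k…−1, +1…+k
  around each mutation, tallied per mutation type; k defaults to 1 (a
  single flank suffices for a first look at sequence context; full
  96-context signature extraction is out of scope). Ends are clipped,
  lowercase uppercased, non-ACGT pooled as "N".
* **Box summaries** — min/Q1/median/Q3/max with linear-interpolation
  quantiles, computed per group before rendering.
* **Hierarchical clustering** — scipy agglomerative clustering (euclidean
  or correlation distance; average/complete/single linkage) with a newick
  export whose branch lengths are merge-height differences. Rows with
  missing values are dropped with a warning. Merge heights are checked
  against a brute-force agglomerative oracle on small matrices.
* Mutation-class colors are fixed (COSMIC-style palette) for reproducible
  figures.

## Synthetic data generator

The generator emulates the *structure* of two study designs, not their
numbers (none are published for them): a genotype × mutation-type mouse
comparison (wild type, two uracil-glycosylase knockouts, double knockout)
and a 3 × 10-patient cancer cohort. Element counts are Poisson around a
category-dependent rate (base rate × per-category multipliers); positions
are uniform except in hotspot windows where intensity is multiplied.
Chosen conditions: mouse base rate 40 with UNG ×2.2, DKO ×0.6 and
C>T/G>A ×3 (burden ordering and transition dominance typical of
uracil-repair deficiency), a ×8 hotspot of 1 kb on chr2; cancer base rate
60 with skin ×3 and colorectal ×1.2 (UV-driven skin burden highest).
Region suites (a coding/non-coding pair that exactly partitions the
genome, six DNA-repair-pathway tracks, two open-chromatin tracks) are
drawn as alternating exponential gaps/segments; the reference FASTA is
uniform ACGT.

All randomness flows through one `numpy.random.default_rng(seed)` (PCG64)
stream, giving byte-identical output across platforms for a given seed.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: realistic mutational-signature spectra and
sequence-context dependence, chromatin- or replication-timing-dependent
mutation rates, inter-patient heterogeneity beyond a scalar burden,
chromosome-scale genome sizes, and assembly artifacts. The tests
demonstrate correctness of the computations and calibration of the null
models, not biological conclusions.

## Numerical and design choices

* Missing metadata uses the sentinel `"."` and forms its own category in
  cube dimensions; values are case-sensitive and whitespace-stripped.
* Each track occupies exactly one category per dimension (no overlapping
  groups); overlapping groupings can be expressed by duplicating entries
  under new titles if ever needed.
* Concatenation by metadata only merges tracks that agree on all
  hierarchy columns *above* the target column, so e.g. mutation types are
  collapsed within, never across, genotypes. Entries whose value falls in
  no group pass through unchanged. Merged tracks are materialized as BED
  files with deterministic names in a workspace directory, keeping the
  output suite self-contained.
* Ordered groupings (e.g. dates embedded in titles) are honored lexically;
  no date parsing is attempted.
* Chromosome policy on BED input is strict by default (unknown chromosome
  or overlong interval is an error); lenient mode drops/clips with a
  logged warning.
* Determinism everywhere: stable sorts, first-appearance category order,
  seeded RNG, no global random state; clustering tie-breaks follow scipy's
  deterministic pair ordering.

## Problem sizes

The default test and reproduction runs use the 23 kb toy genome, 16–60
track suites, 200-replicate calibrations and 120-suite round-trip sweeps —
sizes at which every statistic also has an exact per-base oracle. The
implementation is vectorized (numpy interval arrays, binary search) and
has no fixture-scale assumptions; real chrom.sizes files and Mb-scale bins
are supported directly.

## Known limitations

No p-values or permutation tests for colocalization (descriptive
statistics only); no BigBed/BAM/VCF ingestion; no persistent on-disk
index (tracks are re-indexed per run); dense cube storage is not meant
for more than ~6 dimensions; remote URIs in suite files are not fetched.
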