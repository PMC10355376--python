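# hgcube

Hierarchical, metadata-informed analysis of genomic track collections.

Many genomics studies produce dozens to hundreds of *tracks* — sets of
objects (somatic mutations, peaks, genes) with coordinates on a reference
genome — each carrying metadata such as genotype, patient, cancer type, or
mutation type. Per-track statistics are easy; drawing overall conclusions
across the collection is not. `hgcube` organizes a collection as a
**hGSuite** (a tab-separated suite file whose metadata columns carry a
declared hierarchical ordering) and computes statistics into a
**data cube**: a multidimensional array whose axes are the hierarchy's
metadata columns. The cube is then explored with the classic OLAP
operations — slice, dice, pivot, aggregate — so "average mutation count per
cancer type" or "C>T burden in coding regions per patient" is one
operation, not a script.

## What it computes

Per cell (a group of tracks sharing one category per dimension):

* descriptive statistics — element count, base-pair coverage, average
  segment length, and the observed/expected coverage ratio under a
  uniform-across-categories null (ratios over a complete partition average
  to exactly 1);
* relations between two suites — overlap in bp, points-in-regions count,
  query-normalized overlap, and the **Forbes colocalization coefficient**

  ```
  F = G · |A ∩ B| / (|A| · |B|)
  ```

  observed overlap over the overlap expected for independently placed
  tracks on a genome of `G` bp (`F = 1` no association, `F > 1`
  colocalization).

Visual analytics for mutation profiling are included as deterministic
table computations plus rendering: rainfall plots (inter-mutation
distance), binned mutation frequency along chromosomes with feature
overlays, flanking-base composition per mutation type, box summaries, and
hierarchical clustering with newick export. Suite-customization tools
(relabel / filter / title-group / concatenate / strand-collapse mutation
types / combine / add metadata) reshape a collection before cube analysis.

A deterministic fixture generator emulates two case-study structures — a
four-genotype mouse knockout comparison and a three-cancer-type,
30-patient cohort — on a 23 kb toy genome, so the whole stack is testable
offline.

## Worked example

```
hgcube fixtures make --preset mouse --seed 7 --out demo
hgcube cube build demo/mutations.gsuite --stat count \
    --genome demo/chrom.sizes -o demo/cube
hgcube cube export demo/cube -o demo/profile.tsv
cat demo/profile.tsv
```

```
genotype	C>T	G>A	T>C	C>A
WT	124.0	112.0	33.0	44.0
UNG	260.0	256.0	85.0	82.0
SMUG1	113.0	126.0	35.0	40.0
DKO	90.0	63.0	24.0	19.0
```

Each cell is the number of mutations for one genotype × mutation-type
track. The synthetic conditions are visible at a glance: the UNG knockout
carries roughly twice the wild-type burden, the double knockout fewer
mutations than wild type, and C>T/G>A transitions dominate every genotype.
Collapse the strand-equivalent types and aggregate:

```
hgcube meta collapse demo/mutations.gsuite -c mutation_type \
    --genome demo/chrom.sizes --workspace demo/ws -o demo/collapsed.gsuite
hgcube cube agg demo/cube -d mutation_type -r sum -o demo/bygeno
hgcube cube export demo/bygeno -o demo/bygeno.tsv
```

`demo/bygeno.tsv` then holds one total per genotype (`WT 313, UNG 683,
SMUG1 314, DKO 196` for this seed). The same grammar drives the cohort
preset: `hgcube cube relate patients.gsuite regions.gsuite --stat
overlap_count …` builds a cancer-type × patient × region cube, and
`slice`/`agg` reduce it to any 2-D view, exported as TSV.

### Command groups

| group | task |
| --- | --- |
| `hgcube suite build/validate` | create an hGSuite from a BED directory; check one |
| `hgcube meta modify/filter/title-filter/concat/collapse/combine/add` | customize a suite via its metadata |
| `hgcube cube build/relate/slice/dice/agg/export` | build and query data cubes (chained via TSV bundles) |
| `hgcube plot rainfall/freq/flank/box/cluster` | visual analyses (tables + PNG/SVG) |
| `hgcube fixtures make` | synthetic case-study data |

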