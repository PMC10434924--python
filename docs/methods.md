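# Methods

## The analysis in one paragraph

Each individual thrips contributes one 434-nt COI barcode sequence.
Identical sequences collapse into haplotypes; shared haplotypes are named
H1, H2, … in descending frequency and singletons HU⟨k⟩ continue the
numbering. Pairwise distances between haplotypes (substitutions per site)
feed a Neighbor-Joining tree whose two major clades correspond to the
thelytokous and arrhenotokous mitochondrial lineages. A three-primer PCR
assay types the reproductive mode directly: a 451-nt product marks
thelytoky, a 261-nt product arrhenotoky, both at once mark heteroplasmy,
which is then resolved by the haplotype's lineage group. Per-population
diversity is the mean pairwise distance among that sample's sequences;
homogeneity of modes across locations is a chi-square; genetic vs
geographic structure is a Mantel permutation test.

## Sequence handling and QC

- The barcode window is 1-based, start-inclusive, end-exclusive: the
  conventional COI coordinates (341, 775) span exactly 434 nt, which is the
  only convention under which the published fragment length is recovered.
  The bundled panel carries the 434-nt fragment directly (fragment
  coordinates 1–434), so the gene-vs-amplicon ambiguity of the original
  coordinates affects documentation only.
- `-`, `N` and multi-base IUPAC codes are treated as missing for distance
  computation (pairwise deletion) but kept for primer matching, where
  ambiguity codes match their base sets (H = {A,C,T}, …).
- QC discards a record iff it misses more than five nucleotides at the
  beginning or end of the window; up to five are retained and absorbed by
  pairwise deletion downstream. The filter is idempotent and partitions its
  input.
- Haplotype collapsing is string-identity by default (`strict`), because
  consensus sequences are collapsed whole; a `merge` policy (identical at
  all mutually resolved sites, first-compatible-cluster order) exists for
  QC-passed sequences with residual end-missing data. Whether the original
  survey's H-numbering is frequency- or discovery-ordered is not stated
  anywhere; the namer uses frequency order with ties broken by input order,
  which reproduces the published H/HU split sizes.

## Distance models

All distances use pairwise deletion and are undefined (error) when a pair
shares no resolved site.

- `p`: mismatches / compared sites.
- `jc69`: −(3/4)·ln(1 − 4p/3); error at p ≥ 3/4.
- `k2p`: −½·ln(1 − 2P − Q) − ¼·ln(1 − 2Q) with P, Q the transition and
  transversion proportions.
- `mcl`: a composite-likelihood-style correction in the Tamura–Nei form,
  with base frequencies estimated empirically from each pair and separate
  A↔G and C↔T transition terms. The exact internals of the
  composite-likelihood estimator popularised by MEGA are not published at
  implementation granularity; this form shares its ingredients
  (frequency-awareness, separate transition classes) and satisfies the
  contracts that matter at survey scale: it converges to p as p → 0 and
  stays within a few percent of JC69 for p ≤ 0.05. Degenerate compositions
  (a missing purine or pyrimidine class) fall back to JC69.
- Diversity of an n = 1 sample is undefined (error), not 0. Identical
  pairs contribute 0 to means. Between-sample distance averages all
  |A|·|B| cross pairs; for samples given as haplotype counts an exact
  count-weighted computation avoids expanding individuals.

On the bundled panel the three models agree to the third decimal
(0.0228 / 0.0232 / 0.0235), as expected at ≈ 2% divergence. The reported
headline mean uses the p model because it depends only on the published
variable-site profile; the corrections additionally touch the base
composition of the reconstructed invariant background (below).

## Neighbor-Joining, rooting, groups

The joining loop is standard Saitou–Nei Q-minimisation. Ties in Q are
broken by the lowest (row, column) pair in the current matrix order, so
trees are bit-reproducible for a fixed label order. Negative branch
lengths are clamped to 0 by default (flag to retain; the additive-tree
recovery tests retain raw values). NJ is consistent: on distances that are
exactly additive on a tree it reproduces that tree's topology and branch
lengths to 1e-9, property-tested over random trees with n ≤ 12 and
cross-checked bipartition-for-bipartition against an independent NJ
implementation.

Rooting bisects the outgroup's pendant edge (midpoint rooting as a
fallback when no outgroup is given). Group assignment is anchored: each
lineage group is seeded with haplotypes of known identity and grows to the
largest rooted clade containing all of its anchors and none of any other
group's; leaves caught in no clade stay ungrouped. Anchoring is explicit
rather than automatic 2-clustering because lineage identity ultimately
comes from externally characterised reference individuals.

A caveat the bundled panel exposes: the published lineage annotation is
not monophyletic on a distance tree built from the panel alone. A small
cluster of thelytokous-fragment haplotypes (H6/H7/H34/H35 and relatives)
sits 4–6 substitutions from the arrhenotokous core but 12 from H1, and NJ
places it — and the unassignable haplotype HU58 — on the group-2 side.
The original grouping relied on a larger tree including externally
annotated accessions that are not part of the panel. Tests therefore
assert the recoverable structure (a pure group-1 clade, all group-2
haplotypes together, correct outgroup split), while mode resolution and
the heteroplasmy tallies use the panel's published group labels.

## In-silico reproductive-mode PCR

Primer matching is an exhaustive ambiguity-aware sliding-window scan with
a mismatch budget (default 0 for the mode-specific primers: specificity is
the assay's point). Amplicon length follows the gel convention — from the
forward primer's 5′ end through the reverse primer's 5′ end inclusive, so
both footprints count — which reproduces the published 451/261 product
sizes. Observed lengths can be snapped to the canonical pair within a
configurable gel-resolution tolerance (exact by default in tests).

Call logic: {451} → thelytokous; {261} → arrhenotokous; {451, 261} →
heteroplasmic, resolved thelytokous for group 1 and arrhenotokous for
group 2 (undetermined if ungrouped); {} → undetermined. Heteroplasmy is a
property of an individual's mitochondrial population, so an individual is
modelled as a *set* of mitotype templates and typed from the union of
amplified lengths.

## Geostatistics

- Great-circle distances use the haversine formula with mean Earth radius
  6371.0088 km; differences from ellipsoidal or GIS-software distances are
  far below between-site distances at survey scale. Repeat samplings of
  one site sit at distance 0.
- The Mantel statistic is the Pearson correlation over upper-triangle
  off-diagonal entries; the null jointly permutes rows and columns of the
  second matrix; p uses the add-one rule so ties count as exceedances and
  p ≥ 1/(permutations + 1). Two-sided on |r| by default, with a one-sided
  `greater` option because some population-genetics software reports that;
  the original survey does not state which it used. Calibration: empirical
  type-I error 0.05 ± 0.04 over 200 null simulations; power ≥ 90% against
  the generator's isolation-by-distance setting.
- Mode homogeneity is a Pearson chi-square on the 2 × L resolved-mode
  count table (no continuity correction, df = L − 1); individuals with
  undetermined mode are excluded, zero-total locations dropped with a
  warning.
- Detection probability is 1 − (1 − f)ⁿ; its inverse gives the smallest n
  reaching a target confidence (29 for f = 0.1 at 95%, which is why
  33-per-site designs are standard).

## The bundled reference panel

The panel file encodes the published variable-site table of 58 haplotypes:
52 polymorphic positions, per-haplotype frequency, fragment pattern, and
lineage group. Full 434-nt sequences are reconstructed by substituting the
listed states into a seeded AT-rich (70%) invariant background; since
haplotypes differ only at listed positions, every pairwise distance is
independent of the background seed (tested). Counts are the published
frequencies resolved against the 545 sequenced individuals; they sum to
exactly 545 and frequencies are renormalised from them.

Two transcription reconciliations, applied because the printed table
disagrees with its own text totals: fragment entries printed "461" are a
typo for the 451-nt thelytokous product, and for the one affected
singleton haplotype the pattern must read "261 & 451" for the published
tallies (20 thelytokous-only / 11 arrhenotokous-only / 26 both / 1 none,
with 23 heteroplasmic haplotypes in group 2) to hold.

Only two per-location compositions appear in the survey's main text (one
population fixed for H1, one with a single one-step mutant of H1); the
remaining compositions live in supplementary material and are deliberately
not bundled, so population-level statistics that need them (the published
2 × 14 chi-square and the survey-wide Mantel) are out of the desk-scale
reproduction.

## The generator

`SimConfig` defaults mirror the survey design: 14 sites at the bundled
coordinates, 33 individuals per site with one 16-individual sample, two
lineage cores differing at 13 sites over 434 (the distance between the two
published lineage cores), Poisson private mutations at rate 0.003 per site
per individual (expected pairwise divergence 2μ(1−μ) + ⅔μ² ≈ 0.006,
matching the middle of the published per-site diversity range), AT-rich
(70%) composition as in insect mtDNA, and per-site mode compositions with
every third site purely thelytokous (5 of 14, interleaved so composition
carries no spatial gradient under the panmictic setting) and the rest
hosting both lineages in sympatry (60/25/15 thelytokous/arrhenotokous/
heteroplasmic). Heteroplasmic individuals carry a group-2 barcode with
probability 0.8, reflecting the strong group-2 skew of observed
heteroplasmy. Mode-assay templates embed the barcode and a 451-nt assay
region: the exact primer sites with the published product geometry
(arrhenotoky site at offset 190 → 261-nt tail product) and, on the
thelytokous mitotype, a T insertion at fragment position 212 that shifts
the arrhenotoky primer site out of register — so a pure thelytokous
template can never yield the 261-nt band (asserted up to 2 mismatches).
The isolation-by-distance setting places sites on an equatorial transect
(~556 km spacing) and drifts the local core by ~3 substitutions per
1000 km, making between-population distance increase monotonically with
geographic separation.

What the generator does *not* emulate: coalescent genealogies (mutations
are star-like around the cores), recombination between heteroplasmic
mitotypes, sequencing error, within-individual mitotype frequency, or
seasonal turnover. Passing recovery tests therefore show the pipeline is
correct under clean lineage structure, not that it is robust to messy real
chromatograms.

## Problem sizes in the checks

The test suite runs the additive-tree recovery over 100 random trees
(n ≤ 12), distance-oracle equivalence over 50 random alignments, Mantel
calibration over 200 null simulations (n = 12, 99 permutations) and power
over 100 isolation-by-distance surveys (8 sites × 10 individuals),
mode-typing recovery over 500 simulated individuals, and diversity
recovery over 50 single-site populations of 33 — sizes chosen so each
check is statistically informative while the whole suite stays fast enough
to run on every change.

## Species assignment

Nearest-reference assignment with the barcode gap as thresholds:
conspecific at distance ≤ 0.05, heterospecific at ≥ 0.15, a flagged gap
zone between. The original survey used BLAST homology without a numeric
cutoff; the defaults encode its observed gap (within-species < 5%,
between-species ≈ 20%) and are configurable. Ties are broken by panel
order with a warning.
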