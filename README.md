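# thripspop

Population genetics of onion thrips (*Thrips tabaci*) from COI DNA barcodes.

*Thrips tabaci* is the major insect pest of onion worldwide. Within the
species, two mitochondrial lineages correspond to the two reproductive
modes — thelytokous (asexual, female-only parthenogenesis) and
arrhenotokous (males from unfertilized eggs) — and some individuals are
heteroplasmic, carrying COI copies from both lineages. Surveys genotype
individual thrips by sequencing a 434-nt fragment of the mitochondrial
Cytochrome Oxidase subunit I (COI) gene, collapse identical fragments into
haplotypes, and ask: how is diversity distributed within and between
populations, which reproductive mode lives where, and does genetic distance
track geographic distance?

`thripspop` implements that full analysis as a tested, reusable pipeline:

- **seqio** — FASTA/metadata I/O, ambiguity-aware primer trimming, the
  434-nt barcode window, and the end-missing QC rule (records missing more
  than five nucleotides at either end are discarded).
- **haplotypes** — collapsing identical sequences into haplotypes with
  H/HU frequency-ranked naming, and the dot-notation variable-site table.
- **distances** — pairwise distances (p, Jukes–Cantor, Kimura 2-parameter,
  and a composite-likelihood-style correction with empirical base
  frequencies), all with pairwise deletion of missing data; Nei-style
  diversity *within* a sample (mean distance over all sequence pairs, in
  base substitutions per site) and distance *between* samples (mean over
  all cross pairs).
- **nj** — Saitou–Nei Neighbor-Joining with deterministic tie-breaking,
  outgroup rooting, and anchored assignment of haplotypes to lineage groups.
- **modes** — in-silico PCR with the published three-primer assay (TCOC +
  TCOR amplify 451 nt from thelytokous templates, TCOS + TCOR amplify
  261 nt from arrhenotokous ones, heteroplasmic individuals show both), and
  phylogenetic resolution of heteroplasmic calls.
- **geostats** — haversine great-circle distances, a Mantel permutation
  test of genetic vs geographic distance, chi-square homogeneity of
  reproductive modes across locations, and sampling-design calculators
  (P(detect) = 1 − (1 − f)ⁿ).
- **species** — barcode-gap species assignment (within-species COI
  divergence < 5%, between-species ≈ 20%).
- **reference** — a bundled published panel of 58 *T. tabaci* haplotypes
  (52 variable sites over 434 nt, frequencies among 545 individuals,
  fragment patterns, lineage groups) plus the 14 survey sites, so every
  stage is testable without downloads.
- **simulate** — a seeded generator of synthetic geo-referenced surveys
  with the same structure (two lineages 13 substitutions apart, sparse
  private mutations, per-site mode compositions, heteroplasmic template
  sets, optional isolation by distance).
- **pipeline / cli** — the end-to-end run and per-stage subcommands.

## Worked example

Rebuild the bundled reference panel and summarise it:

```sh
$ thripspop fixture --outdir results/panel
{"p": 0.02275293350171831, "jc69": 0.023230891587107904, "mcl": 0.02349584565247234}
```

or, from the numbered analysis drivers:

```sh
$ python analysis/01_reference_panel.py
58-haplotype panel rebuilt -> results/reference_panel
polymorphic sites: 52 / 434
mean pairwise haplotype distance (p): 0.0228
mean pairwise haplotype distance (jc69): 0.0232
mean pairwise haplotype distance (mcl): 0.0235
per-location diversity: {'Tulancingo de Bravo': '0.00e+00', 'Huron': '1.40e-04'}
fragment tallies: {'thelytokous_only': 20, 'arrhenotokous_only': 11, 'both': 26, 'none': 1}
heteroplasmy % by group: {'group1': 13, 'group2': 68, 'ungrouped': 0}
```

Reading this: the 58 haplotypes vary at 52 of the 434 barcode positions and
differ on average by ≈ 0.023 substitutions per site (about 2.3% — well
below the ≈ 20% between-species barcode gap). One population is fixed for
the most common haplotype H1 (diversity exactly 0); another carries a
single one-step mutant of H1, giving mean diversity 1.4 × 10⁻⁴. Of the 58
haplotypes, 20 amplify only the thelytokous 451-nt fragment, 11 only the
arrhenotokous 261-nt fragment, 26 amplify both (heteroplasmic) and one
does not amplify; heteroplasmy is far more common in the arrhenotokous
lineage (68%) than in the thelytokous one (13%).

A synthetic end-to-end run:

```sh
$ python analysis/02_simulated_survey.py
simulated 445 individuals at 14 sites (315 true haplotypes)
haplotypes found: 315; polymorphic sites: 316; mean haplotype distance: 0.0197
heteroplasmy % by group: {'group1': 3, 'group2': 23}
mode homogeneity: X2(13, N=445) = 84.64, p = 1.46e-12
Mantel genetic~geographic: r = -0.069, p = 0.631 (999 permutations)  [panmictic generator: no spatial signal expected]
```

The chi-square rejects an even distribution of reproductive modes across
sites (some simulated sites are purely thelytokous), while the Mantel test
correctly finds no genetic–geographic correlation under the panmictic
generator; `analysis/03_geography_and_sampling.py` shows the same test
detecting the isolation-by-distance setting (r ≈ 0.99, p ≈ 0.001) and its
type-I error sitting at the nominal 5%.

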