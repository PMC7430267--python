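# mitoibd

A toolkit for comparative mitochondrial phylogeography of low-vagility
terrestrial vertebrates — built around the analysis design used for the
southern California slender salamanders (*Batrachoseps major* and
*B. nigriventris*, cytochrome *b*): descriptive sequence summaries over
defined mitochondrial clades, isolation-by-distance (IBD) comparison
across taxa, and a haplotype-matching screen that detects introduced
populations from anomalous genetic/geographic contrasts.

It is for phylogeographers who have (1) an aligned single-locus
mitochondrial matrix, (2) a sample table with population labels, clade
assignments and coordinates, and who want reproducible, scriptable
versions of the standard analyses instead of spreadsheet arithmetic.

## What it computes

**Genetic distances.** Pairwise Kimura two-parameter (K80) distances
with pairwise deletion of gapped/ambiguous sites,

d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q),

where P and Q are the transition (A↔G, C↔T) and transversion
proportions; the uncorrected p-distance (P + Q) is available for
near-identity comparisons. Cells outside the K80 domain are masked, not
zeroed. Distances from a faster locus (e.g. *nd4*) can be divided by a
relative-rate factor (default 1.41) to put them on the cyt *b* scale.

**Alignment summaries.** Variable and parsimony-informative site
counts, haplotype collapsing by exact sequence identity (an
ambiguity-tolerant mode exists behind a flag), and between-clade
divergence tables (mean ± sample SD of the between-clade pairwise
distances).

**Isolation by distance.** Population-level genetic and great-circle
(haversine, R = 6371.0088 km) geographic distance matrices; a one-tailed
Mantel permutation test (default 9,999 permutations); an OLS fit of
genetic on geographic distance over the matrix upper triangles; and 95%
percentile confidence intervals from an independent-population-pair
bootstrap (default 1,000 replicates — each replicate shuffles the
populations, forms ⌊n/2⌋ disjoint pairs and refits the line on those
independent points). Taxa are compared by closed-interval CI overlap.

**Introduction screen.** A sample is flagged as a candidate
introduction when its minimum genetic distance to any sample from
another population is ≤ 0.01 substitutions/site (p-distance) *and* the
geographically nearest of those matches is ≥ 100 km away — far beyond
the spans that mitochondrial haplotypes occupy naturally in these
salamanders.

**Synthetic data.** A generator that plants known IBD structure
(expected divergence = a + b·km along a transect), nested clade splits,
and introduced samples, so every estimator can be tested against ground
truth. See `docs/methods.md` for the model and its limitations.

The package bundles the published voucher/locality tables for the two
focal datasets (`mitoibd.datasets`); the corresponding cyt *b*
alignments are not redistributable and, when available to you, go under
`data/external/` (see `data/external/README.md`).

## Worked example

Simulate 20 populations along a 300 km transect with a true slope of
2 × 10⁻⁴ substitutions/site per km and one planted introduction, then
recover both:

```sh
$ mitoibd simulate --out-dir demo --seed 11 --n-pops 20 --plant-introduction
$ mitoibd ibd --alignment demo/alignment.fasta --metadata demo/samples.tsv \
    --drop-populations intro1 --permutations 9999 --bootstrap 1000 \
    --seed 1 --out demo/ibd.tsv
$ cat demo/ibd.tsv
# mitoibd 0.1.0 model=k80 permutations=9999 bootstrap=1000 seed=1 rate_factor=1.0
label	n_populations	mantel_r	mantel_p	slope	slope_ci_low	slope_ci_high	intercept	intercept_ci_low	intercept_ci_high
taxon	20	0.9779	0.0001	2.523151e-04	2.159204e-04	2.842515e-04	-1.958536e-04	-3.504675e-03	4.291178e-03
```

The Mantel correlation (0.98, p = 1e-4) confirms the planted IBD
signal, and the fitted slope 2.52 × 10⁻⁴ per km sits near the
generating 2 × 10⁻⁴, with the bootstrap CI (2.16–2.84 × 10⁻⁴)
describing pair-level uncertainty.

```sh
$ mitoibd screen --alignment demo/alignment.fasta --metadata demo/samples.tsv \
    --out demo/screen.tsv
wrote demo/screen.tsv; flagged: ['intro1']
```

The screen flags exactly the planted sample: its haplotype is identical
to populations p01–p02 yet sits hundreds of km away, while every other
sample's closest haplotype match is a nearby population.

The same subcommands run on real data, e.g. clade-divergence summaries
(`mitoibd summarize --subset-clades 1,2,3,4,5,6,7,8 ...`) or the screen
on the bundled *B. major* table plus your copy of the alignment.

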