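# Methods

This note documents the statistical models implemented in `mitoibd`,
the defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the package's known
limitations. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Genetic distances

Pairwise distances are computed per sequence pair under **pairwise
deletion**: a site contributes only if both sequences carry an
unambiguous A/C/G/T there (gaps, `?`, `N` and partial-ambiguity codes
are excluded from all counts for that pair). From the counted sites,
P = transitions / compared and Q = transversions / compared give

- **K80**: d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q)
- **p-distance**: d = P + Q

When 1 − 2P − Q ≤ 0 or 1 − 2Q ≤ 0 (or no sites are comparable) the K80
distance is undefined; such cells are **masked (NaN), never zeroed**,
and every summary that consumes a matrix skips masked cells and reports
the skip count. The p-distance is the default for the introduction
screen (near-identity comparisons, where correction is irrelevant);
K80 is the default everywhere else.

Cross-locus standardization divides a faster locus's distances by a
relative-rate factor; the bundled constant 1.41 converts *nd4*
distances onto the cyt *b* scale. Division (not multiplication) is the
implemented direction: the factor expresses how much faster the other
locus evolves.

## Geographic distances

Great-circle (haversine) distances on a sphere of mean radius
6371.0088 km (IUGG mean Earth radius). The choice of a spherical model
over an ellipsoid is deliberate: it is reproducible from the formula
alone, and the difference to geodesic distances (< 0.5%) is far below
the noise in any genetic–geographic regression. Published "ca." road- or
map-derived distances can differ from haversine values by a few km;
comparisons against printed values should carry a corresponding
tolerance.

## Site classification and haplotypes

A site is **variable** iff ≥ 2 distinct unambiguous nucleotides occur
among its non-missing characters, and **parsimony-informative** iff ≥ 2
of those states each occur in ≥ 2 sequences. Gaps and ambiguity codes
neither create nor suppress variability (the standard convention for
parsimony-informative counts). Columns with no unambiguous character at
all are classified `all-missing`.

Haplotypes are collapsed by **exact string identity** over all columns
after upper-casing; ambiguity codes count as distinct characters. This
is the simplest reproducible rule and the default. An
ambiguity-tolerant mode (`ambiguity_tolerant=True`) instead merges a
sample into the first haplotype whose representative is site-wise
IUPAC-compatible; it exists for sensitivity analysis, because partially
sequenced samples can otherwise inflate haplotype counts. Haplotype
numbering follows first occurrence, making outputs deterministic under
a fixed input order.

## Clade divergence summaries

For two disjoint clades the summary is the mean and **sample** standard
deviation (ddof = 1) of all defined between-clade pairwise distances,
with the number of pairs and of skipped (masked) cells reported. The
all-pairs table over k clades additionally reports the minimum of the
pair means, which is the natural "shallowest split" statistic for a set
of subclades.

## Isolation by distance

Analyses operate on **population-level** matrices: the genetic entry
for two populations is the mean of the defined inter-individual
distances between them, and the geographic entry is the great-circle
distance between the (member-averaged) population coordinates. The
population, not the individual, is the sampling unit of the design
being emulated.

- **Mantel test**: Pearson correlation r of the n(n−1)/2 upper-triangle
  entries; the null distribution is generated by jointly permuting the
  rows and columns of one matrix. The p-value is one-tailed (upper)
  with the add-one correction, p = (1 + #{r_perm ≥ r_obs}) / (B + 1);
  9,999 permutations by default. Matrices must be fully defined and
  have nonzero triangle variance, otherwise the test raises.
- **OLS fit**: ordinary least squares of genetic on geographic distance
  over the upper-triangle points, intercept included. Units:
  substitutions/site per km (slope) and substitutions/site (intercept).
- **Independent-pair bootstrap** (default B = 1,000): each replicate
  uniformly shuffles the population order, forms ⌊n/2⌋ disjoint
  consecutive pairs, takes each pair's (geographic, genetic) distances
  as one point and fits the OLS line; CIs are the 2.5th/97.5th
  percentiles of the replicate estimates. Replicates with constant
  geographic values or fewer than two usable points are redrawn, with a
  capped number of rounds and a warning. Percentile (not BCa) intervals
  are used — the simplest interval consistent with reporting quantiles
  of replicate fits. The "shuffle + consecutive pairing" construction
  is one concrete random perfect matching; alternative pairing schemes
  would plug in at the same point.
- **Taxon comparison**: slope and intercept CIs are compared as
  *closed* intervals — intervals sharing exactly one endpoint count as
  overlapping.

Seeding: a single integer seed is split (`numpy.random.SeedSequence`)
into independent streams for the Mantel permutations and the bootstrap,
so a full fit is reproducible from one seed.

## The introduction screen

The screen operationalizes the narrative diagnosis "an (almost)
identical haplotype at an impossible distance" as a two-threshold rule.
For each focal sample, the reference set is every sample from a
*different* population (population-mates share provenance and cannot
vouch for their own population; without this, two co-collected
individuals of an introduced population would alibi each other at 0 km).
The focal sample is flagged iff

1. its minimum genetic distance to the reference set is
   ≤ `genetic_threshold` (default 0.01 substitutions/site, p-distance —
   the "< 1%" level used to attach a sample to a source clade), and
2. the geographically nearest of the samples at that minimum distance
   lies ≥ `geographic_threshold` km away (default 100 km, several times
   the largest haplotype spans observed in these salamanders, which are
   a few tens of km).

The rule is monotone: raising the genetic threshold or lowering the
geographic threshold can only add flags, because the match set is the
argmin and does not depend on either threshold.

Genetic evidence alone is symmetric: if a haplotype occurs at exactly
two mutually distant localities and nowhere else, both ends satisfy the
rule and both are reported. In practice the source side has local
haplotype sharing (neighboring localities carrying the same or a
near-identical haplotype), which suppresses its flag; resolving a truly
isolated symmetric pair requires range knowledge, and restricting the
screen to candidate samples is exposed as a filter (`--focal`).
Reference samples of debated status (e.g. island populations) can be
excluded from the reference set without being screened
(`exclude_reference`).

Each report row also carries a haplotype-span statistic: the maximum
great-circle distance between localities sharing the focal sample's
exact haplotype, the quantity against which "anomalous distance" is
judged.

## Synthetic data generator

The generator produces datasets whose expected pairwise divergence
follows E[d] = a + b·km, so estimator output can be compared to known
truth.

**Geography.** Populations are placed uniformly at random along a
one-dimensional south–north transect (default 300 km — the spatial
scale of the southern California sampling), encoded as real
coordinates so the geographic machinery is exercised end to end.

**Genealogy.** Two constructions:

- `transect-path` (default): sequences evolve along the transect path;
  the segment between adjacent populations contributes b·Δkm expected
  substitutions/site, multiplied by mean-one log-normal noise
  (log-sd = `noise`, default 0.1), and each tip carries a private a/2
  branch. Because distances on a line are additive, **every** pair
  satisfies E[d] = a + b·geo exactly, which makes slope-recovery tests
  sharp. An optional deep split inserts an extra expected divergence
  into one inter-population segment, creating two clades whose
  between-clade divergence exceeds the IBD expectation by exactly that
  amount.
- `upgma`: an ultrametric tree from average-linkage clustering of the
  geographic distance matrix, node heights scaled so clusters merging
  at geographic distance h diverge by a + b·h, with log-normal noise
  and heights forced non-decreasing toward the root. This matches the
  intuition "IBD looks like distance-structured clustering", but the
  linear expectation holds per *cluster pair*, not per population pair;
  measured on 30-population transects the within-cluster spread of
  geographic distances attenuates the OLS slope to ≈ 0.63 of the
  nominal value. It is therefore not the default for parameter-recovery
  work and is retained for generating nested, ultrametric clade
  structure.

**Sequence evolution.** Kimura two-parameter model with
transition/transversion ratio κ (default 4, a typical vertebrate
mitochondrial value; sequence length default 784 sites to mirror the
target marker). Branch substitution probabilities use the closed-form
K80 solution with the rate matrix scaled so branch lengths are expected
substitutions per site — branch lengths are exact in expectation, with
no discretization. The root sequence is uniform over A/C/G/T.

**Planted introductions.** The source population's haplotype is copied
to a distant locality (default 200 km beyond the transect end) and, by
default, also shared with the population adjacent to the source —
emulating the local haplotype sharing that real source regions show and
that lets the screen distinguish the source side from the introduced
side. Ground truth (slope, intercept, κ, clade labels, introduced ids,
the shared-neighbor label, branch lengths, newick topology) is
serialized as JSON next to every dataset; identical seeds give
byte-identical outputs.

**What the generator does not emulate**, and hence what passing
recovery tests do not demonstrate about real data: coalescent
within-population variation (population members are exact haplotype
copies), recombination and selection (absent, as appropriate for
mtDNA), indels, sequencing error and partial sequences, non-linear or
anisotropic geography (real sampling is 2-D), and multiple independent
loci. Divergence noise is log-normal and multiplicative per branch,
which is a convenience choice, not a fitted model.

## Numerical and interface choices

- Distance matrices are validated on construction (symmetry, zero
  diagonal, non-negativity) and carry their units; undefined cells are
  NaN and serialize as the sentinel `NA` (documented in the CSV header
  comment).
- Haplotype/alignment characters are upper-cased on read and RNA `U`
  maps to `T`; NEXUS reading accepts interleaved and non-interleaved
  simple DATA blocks (via Biopython), NEXUS writing emits a plain
  non-interleaved block.
- Sample tables auto-detect comma/tab delimiters, require decimal
  degrees, and reject out-of-range coordinates naming the offending
  rows. Pairing an alignment with a table that lacks some of its ids
  fails loudly.
- Sample exclusions (e.g. the low-quality population 17 of the bundled
  *B. major* table) are applied through a documented drop-list, not by
  editing fixtures.
- Ties in the neighbor ranking are broken by sample id, making reports
  deterministic.

## Known limitations

- **Bootstrap CIs are conditional on the realized genealogy.** With a
  single non-recombining locus, all pairwise distances in a dataset
  share one realized genealogy and one realized substitution history;
  the dataset-level slope therefore fluctuates coherently (relative
  sd ≈ 1/√(total transect divergence × sites), ~15% at the default
  depth and 784 sites) in a way that no resampling of population pairs
  can detect. The independent-pair bootstrap correctly handles the
  non-independence of matrix *entries* (it is conservative when noise
  is tip- or pair-level), but its CIs under-cover the *generative*
  slope in simulations — and, by the same logic, describe
  uncertainty-given-the-genealogy, not across evolutionary replicates,
  when applied to real single-locus data. Cross-taxon comparisons are
  less affected because each taxon contributes its own independent
  genealogy.
- The Mantel permutation p is approximate for very small n (exact
  enumeration is feasible at n ≤ 7 and is used as a test oracle, not an
  execution path).
- The screen is a flagging heuristic, not an assignment method: it
  neither models haplotype frequencies nor computes likelihoods, and a
  genuinely isolated natural relict with a far-flung identical
  haplotype would be flagged.
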