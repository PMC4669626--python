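# Methods

`nannopop` analyses haploid biallelic SNP genotypes of moss female shoots and
their epiphytic dwarf males, sampled in a population > colony > host-shoot
hierarchy. This note documents the statistical procedures, the model behind
the synthetic-data generator, the numerical conventions, and the known
limitations.

## The data model

The unit of observation is a haploid multilocus genotype: one 0/1 call per
locus with a small fraction of missing calls. Metadata bind each sample to a
category (female shoot or dwarf male), a population, a colony, planar
coordinates in metres, and — for dwarf males — the female host shoot they
grow on. Colonies are nested in populations; dwarf males inherit their
host's coordinates because they sit on its stem. Sporophyte (diploid) rows
in input tables are skipped: every analysis here is haploid.

All distances between genotypes use *pairwise deletion*: a pair is compared
only at loci called in both samples. With ~1 % missing data this changes
little, but two conventions follow from it:

* the **proportion** distance (mismatches / comparable loci) need not obey
  the triangle inequality; `triangle_violations` reports, never enforces;
* for AMOVA the mismatch **count** is rescaled by `L / comparable` so pairs
  with missing calls sit on the same scale as complete pairs.

## Clone (haplotype) assignment

Two samples share a haplotype when they mismatch at zero jointly called
loci. Missing data make this relation non-transitive, so clones are defined
as connected components of the zero-mismatch graph (single linkage) — the
most inclusive deterministic completion. Clone labels are the
lexicographically smallest member id, which makes the partition invariant to
input order. Without missing data the relation is a true equivalence and
the clone count equals exact row deduplication (tested against that oracle).
A pair with *no* jointly called locus matches vacuously and is linked; at
realistic missingness this cannot occur.

## Genetic diversity

Per-locus diversity is Nei's unbiased estimator
`uh = n/(n-1) * (1 - sum rho_i^2)` with allele frequencies `rho_i` over the
`n` non-missing calls; the group value averages loci, monomorphic loci
contributing zero. `%P` is the percentage of polymorphic loci over the full
panel (monomorphic loci stay in the denominator, so `%P` is comparable
across groups).

Shoots within a colony are clonal replicates and dwarf males share a host,
so individuals within colonies are not independent. Population-level
diversity therefore draws one individual of the focal category per colony,
uniformly and independently across 1000 permutations, and reports the mean
and SD of the per-draw estimates. `%P` is averaged per draw (not pooled
across draws) — consistent with reporting a permutation mean. The
permutation mean converges to the exhaustive-enumeration expectation
(tested by enumeration on small instances).

## Differentiation: AMOVA PhiPT

PhiPT partitions squared pairwise distances into among- and within-group
molecular variance; it is the F_ST analogue usable for haploid/binary data.
For 0/1 haplotypes the per-locus difference is 0 or 1, so the allele
mismatch count *is* the squared Euclidean distance and enters the sums of
squares unsquared. With N individuals in G groups:

    SS_total  = sum_{i<j} d2_ij / N
    SS_within = sum_g sum_{i<j in g} d2_ij / n_g
    sigma2_W  = SS_within / (N - G)
    sigma2_A  = (SS_among/(G-1) - sigma2_W) / n0,
                n0 = (N - sum n_g^2 / N)/(G - 1)
    PhiPT     = sigma2_A / (sigma2_A + sigma2_W)

PhiPT is not truncated at zero — negative estimates are informative (they
occur when within-group distances exceed between-group distances). If total
variance is zero PhiPT is defined as 0 with p = 1. Significance permutes
individuals among groups; all permutation tests in the package use the
`(exceedances + 1) / (permutations + 1)` convention, so 999 permutations
give a minimum attainable p of 0.001.

Two usage patterns mirror the sampling design:

* **between colonies within a population** — all individuals of one
  category, groups = colonies;
* **between populations** — five one-individual-per-colony subsamples per
  category (disjoint when the colony pools permit; pools are shuffled once
  and consumed in order, refilled with replacement only when exhausted),
  PhiPT per subsample, mean ± SD, and a Welch t-test comparing the
  dwarf-male and female subsample sets.

Because the estimator is df-corrected, it is only asymptotically invariant
to duplicating every individual: duplication shifts PhiPT by an O(G/N) term
(≈ +0.04 at N = 30, < 0.02 at N = 120). Similarly, the subsample mean
tracks the full-data PhiPT for dwarf males but *not* for females — clonal
pseudo-replication inflates the full-data female value, which is precisely
the artefact the subsampling scheme exists to remove.

## Spatial structure: Loiselle kinship and Mantel tests

The pairwise kinship F_ij is a haploid adaptation of the Loiselle
allele-frequency-covariance estimator, with the small-sample bias correction
`sum_l sum_a pbar(1-pbar)/(n_l - 1)` added to the numerator and multilocus
ratio-of-sums weighting (sums over loci before dividing). Sums run over
both alleles of each biallelic locus — this doubles numerator and
denominator and is retained for fidelity to the published estimator — and
over loci called in both pair members. Reference frequencies come from the
analysis group itself (the whole category for pooled analyses, the
population for within-population analyses). Loci with fewer than two
non-missing reference calls are excluded; a pair whose comparable loci are
all monomorphic in the reference is undefined (NaN).

The Mantel test correlates the off-diagonal upper triangles of two square
matrices and permutes rows and columns of one matrix jointly. All three
tails (upper, lower, two-sided) are reported, because "kinship declines
with distance" is a directional hypothesis (lower tail) while a generic
association test is two-sided; the caller picks the tail that matches the
question.

## Ordination

Principal coordinates analysis squares the (optionally `1/sqrt(n-1)`
standardized) distances, double-centres (`-1/2 J D^2 J`) and
eigendecomposes. Axes with non-positive eigenvalues are dropped and
excluded from the variance-explained denominator — the usual convention for
possibly non-Euclidean input. On Euclidean-embeddable input the coordinates
reproduce the distances to 1e-9 (tested), and variance proportions match an
independent ordination library.

## Dwarf-male relatedness and origin

For each dwarf male, three proportion distances are computed: `gd_host` to
its own host shoot; `gd_col`, the mean over the colony's other sampled
females (the four satellites in the standard design); and `gd_pop`, the
mean over the population's sampled females *outside the focal colony*.
Excluding the whole focal colony from `gd_pop` keeps the colony and
population contrasts on disjoint female sets and avoids double-counting —
a deliberate resolution of an ambiguity in how "the rest of the population"
can be read.

The paired contrasts (host vs colony; colony vs population) are tested with
a sign-flip permutation test on the per-male differences: the statistic is
the mean difference, the null flips each difference's sign independently,
and p is two-sided with the `(b+1)/(m+1)` convention; fewer than five pairs
triggers exact enumeration of all sign patterns. The test assumes the
paired differences are independent across flip units and symmetric under
the null. Dwarf males sharing a host are *not* independent, so a
colony-stratified variant (whole colonies flip together) is provided and is
the conservative choice for confirmatory use; the per-male flip is the more
powerful default and its p-values should be read accordingly. Calibration
is verified under a null that satisfies the assumption by construction
(independently swapping the two values within each male); no independent-
flip test can be calibrated against generator nulls that leave cross-male
correlation in place.

`assign_origin` names each dwarf male's genetically nearest sampled female
and classifies her location (host / own colony / own population / other
population). A spore carries alleles of both parents, so the call
identifies a relative of *either* parent — under outbreeding it recovers
"the location of a parent", not specifically the mother; against generator
truth it agrees with a parent's location for ≥ 97 % of unambiguous calls.
Ties resolve toward the most local category, then the lowest sample id.
Calls whose margin over the best female of any other category is at most
`margin_threshold` (default one locus, 1/L — one genotyping error could
flip them) are flagged ambiguous.

## The synthetic-data generator

The generator emulates the field design so every estimator can be validated
by parameter recovery:

* **Allele frequencies.** Ancestral frequencies per locus are uniform on
  (0.1, 0.9) (SNP panels are ascertained for intermediate frequencies);
  population frequencies follow the Balding–Nichols island model,
  Beta-distributed with mean p and variance p(1-p)F. The default F = 0.3
  matches the between-population differentiation scale of the system
  studied.
* **Layout.** Populations sit on a 5 km grid (regional scale); colonies
  within a population on a 30 m grid (typical nearest-colony spacing);
  each colony is sampled as a centre shoot plus four satellites 50 cm away.
* **Females.** Each colony draws five distinct founder haplotypes (loci
  independent Bernoulli at the population frequency) and assigns each of
  its five sampled shoots to a founder lineage with dominance weights
  (0.72, 0.07, 0.07, 0.07, 0.07). These give the dominant clone an expected
  3.6 of 5 shoots and ≈ 2.2 expected distinct clones per colony — the
  clonal structure reported for such colonies. The analytic expectation
  `sum_k (1 - (1-w_k)^S)` is exposed as `expected_clones_per_colony`.
* **Dwarf males.** Ten spores land on each centre shoot. Each spore's
  mother is the host (p = 0.6), a satellite shoot of the colony (0.25), a
  shoot of another colony in the population (0.10), or a shoot of another
  population (0.05); the weights are a modelling choice representing
  strongly local spore dispersal, not a measured quantity. The father is
  the mother's own clone with probability 0.3 (identical parent-offspring
  haplotypes are regularly observed in this system), otherwise the
  haplotype of a random sampled shoot of the mother's population — large
  free-living males are essentially absent, so the effective pollen pool is
  the population's haplotype pool. Loci are unlinked (transcriptome SNPs
  with no map): each locus inherits the maternal or paternal allele with
  probability 1/2.
* **Missingness.** Calls are deleted independently at rate 0.011.
* With `isolation_by_distance` on, the mother colony for
  within-population non-local origins is chosen with an `exp(-d/30 m)`
  kernel instead of uniformly.

Everything is deterministic under a seed. The generator returns the hidden
truth (clone ids, origin categories, parent ids, frequency tables) for
recovery tests.

What the generator does **not** emulate: multi-generation demography,
colony extinction/recolonisation, selection, genotyping error (missingness
is the only data pathology), linkage, and unequal female fecundity. Tests
passing on these simulations therefore validate the estimators under the
stated sampling model, not the full complexity of field data.

## Problem sizes used in the test and acceptance runs

Simulation-backed checks use: the study-design preset (315 samples × 68
loci) for pipeline-level checks; 20 demes × 20 haploids × 1000 loci × 10
replicates for differentiation recovery (chosen so the Monte-Carlo SE of
the mean PhiPT is ≈ 0.001, far below the ±0.05 acceptance band); and 500
replicates with 199 permutations each for null-calibration checks (the
binomial 99 % band around a 5 % rejection rate is then ±2.5 points).

## Known limitations

* Single-linkage clone assignment can chain distinct haplotypes through
  intermediate samples with missing calls; at ~1 % missingness chained
  merges are rare, but clone counts at high missingness should be read as
  lower bounds on distinctness.
* PhiPT inherits AMOVA's sensitivity to unequal group sizes through `n0`;
  the one-per-colony subsampling equalises sizes by design.
* The per-male sign-flip test overstates evidence when dwarf males on one
  host are strongly correlated; use the colony-stratified variant when that
  matters.
* The Mantel test's known low power / inflated error under strong spatial
  autocorrelation of both matrices applies here as everywhere; within-
  population tests on few colonies are mainly descriptive.
* `welch_t` delegates to `scipy.stats.ttest_ind(equal_var=False)`;
  PCoA, Mantel and kinship are implemented in-package because the required
  conventions (standardization, tail reporting, haploid two-allele sums
  with pairwise deletion) differ from library defaults, with library and
  brute-force oracles used in the tests instead.
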