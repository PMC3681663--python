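# Methods

## Scope and model

The package quantifies trans-ethnic replicability of case-control GWAS
associations. A *replication attempt* is the evaluation, in a later
independent study, of a SNP previously discovered at genome-wide
significance; it is *successful* when the same risk allele reaches
*P* < α (default α = 0.05). Three mechanisms are modeled explicitly:

1. **Statistical power.** Replication samples differ in size and
   allele frequency, so the expected number of successes under full
   causal sharing is Σᵢ powerᵢ, not *n*. The ratio of observed
   successes to this sum is the *effective replicability rate*; under
   a mixture in which a fraction π_share of associations is truly
   shared, its expectation is π_share + (1 − π_share)·(α/2)/mean(power),
   so it estimates π_share up to a small null-leakage term.
2. **Publication bias.** Treated by bounding, not modeling: if all *k*
   observed successes were same-direction type I errors, the implied
   attempt pool is k/(α·p_dir) with p_dir = ½; an exact (Garwood)
   Poisson interval on *k*, scaled by 1/(α·p_dir), gives the CI. A
   complementary lower bound divides *k* by gathered plus
   maximum-conceivable unreported attempts.
3. **LD divergence.** For a window of 50 SNPs, each population's LD is
   summarized by the matrix of signed r² values (sign(r)·r², r the
   Pearson correlation of phased haplotype alleles); the varLD-style
   raw score is the L1 distance between the two matrices' descending
   eigenvalue vectors. Raw scores are compared between groups of
   regions and against permutation nulls; no genome-wide
   standardization is applied (group comparisons and empirical
   p-values don't need it).

## Power calculation

One-stage allelic two-proportion z-test on allele counts (2 per
individual). Control risk-allele frequency equals the population
frequency (low-prevalence approximation); case frequency follows the
log-additive model. Power counts only same-direction significance,
Φ(|ncp| − z₁₋α/₂), because the success criterion requires the same risk
allele; at ψ = 1 this equals α/2 by continuity. An `any`-direction
variant adds the opposite tail. The analytic value agrees with a
200,000-replicate Monte-Carlo of pooled-variance chi-square tests to
within 0.01 across ψ ∈ {1.1, 1.3, 1.5} × RAF ∈ {0.1, 0.3, 0.5} ×
n ∈ {500, 2000, 10000} (asserted in the test suite). Two-stage designs
are not modeled: replication results are taken from single GWAS-stage
reports.

## Null conventions

The headline expected-null count is n·α (any direction); the success
criterion (same allele AND *P* < α) implies n·α/2. Both are exposed
(`expected_null_count(..., convention=)`); the default reproduces the
headline arithmetic and is conservative for the binomial test. The
synthetic generator's non-shared associations have true OR = 1 in the
replication population — nulls, not population-specific alternative
causal variants.

## Curation rules

Thresholds 5×10⁻⁷ (genotyped) / 5×10⁻⁸ (imputed discovery), strict
inequality. MHC exclusion uses a configurable window, default
chr6:25–35 Mb (coordinates are 1-based inclusive; the region is named,
not specified, in the source conventions, so the window is a config
value). 200-kb pruning chains SNPs transitively (single linkage) at
< 200,000 bp on the same chromosome within a disease and keeps the
minimum-p SNP per chain (ties: smaller position, then SNP id).
Filtering is idempotent and matches a brute-force union-find oracle in
the tests. Attempt selection modes (`largest_per_snp`,
`most_powered_per_snp`, `most_powered_per_region`) break ties by larger
total sample size, then lexicographic study id, so subsets are
deterministic.

## Synthetic replication database

The generator emulates the statistical structure of a curated
multi-disease database; defaults: 28 diseases × 5 associations, 1–3
East Asian-like attempts each, |log OR| ~ |N(0.182, 0.12)| (centered
near OR 1.2, the typical common-variant effect), discovery MAF ~
U(0.05, 0.5), replication RAF = MAF + N(0, 0.05) clipped to
(0.02, 0.98), replication sample sizes U(300, 3000) per arm (giving a
mean power near 0.6, i.e. attempts that are informative but not
saturated), discovery study sizes straddling the 10,000-individual
small/large split. Per association a Bernoulli(π_share) flag decides
whether its effect exists in the replication population (default
π_share = 0.8). The replication z-score is drawn as N(ncp, 1) with ncp
taken from the *same* formula as the analytic power (so simulated and
analytic power agree by construction, making the power oracle
testable); the reported log OR is z·SE_Woolf, whose mean matches the
true log OR to first order. Two-sided p-values derive from the same z.
Winner's curse is off by default (discovery ORs are treated as coming
from replication stages); a flag resamples the discovery OR conditional
on discovery significance for robustness experiments. What the
generator does **not** emulate: heterogeneity of true effects across
populations, LD-dependent tagging differences, correlated attempts of
the same SNP, study-level quality covariates. Passing tests therefore
demonstrate correctness of the estimators under the stated sampling
model, not robustness to those real-data features.

## Synthetic haplotype panels

A base pool of 1000 haplotypes over ≥650 SNPs is built as Li–Stephens
style mosaics of 16 founder haplotypes (founder allele frequencies
uniform on (maf_floor, 1 − maf_floor), default floor 0.05; per-gap
template-switch probability 0.03 gives LD decaying over tens of SNPs).
Two independent copies drift by g generations of whole-haplotype
Wright–Fisher resampling at 2N haplotypes; defaults g = 80, N = 500
give expected per-SNP F = 1 − (1 − 1/(2N))ᵍ ≈ 0.077, matching typical
European/East-Asian divergence. Panels of 60 diploids per population
are sampled without replacement when possible. Because drift resamples
whole haplotypes, SNPs within a region are strongly correlated: the
F_ST check averages per-region estimates over 40 independent regions
and tests against a 4·SE interval rather than treating SNPs as
independent. Known limitation: at extreme drift (g approaching 2N)
most SNPs fix, windows become monomorphic and LD statistics
degenerate — "strong divergence" experiments use g ≈ 300, N = 500
where polymorphism survives. There is no mutation, recombination
during drift, or demography; the generator produces allele-frequency
and LD divergence, not coalescent realism. A targeted variant applies
extra drift generations to a designated SNP block only, creating
locally elevated divergence over genome-typical flanks.

## LD scan numerics

Monomorphic SNPs get zero off-diagonal correlation entries (diagonal
1), keeping matrices symmetric with trace = window size; per-window
monomorphic SNPs are reported. Missing genotypes use masked-array
correlations; an all-missing SNP is an error. Eigenvalues are paired
by descending rank. Windows are centered (center − 25 to center + 24);
the full ±300-SNP, step-5 scan gives 121 windows and needs 325 SNPs on
each side of the focal SNP (650 total); scans near panel edges are
truncated with a warning. Permutation p-values relabel diploid
individuals (both haplotypes together), preserving sample sizes, and
use the add-one estimator (1 + #{perm ≥ obs})/(n_perm + 1). The
MAF-matched background sampler matches each focal MAF within ±0.02
(folded), widening once to a configurable tolerance with a warning
before erroring.

## Statistical machinery

Binomial tests are exact (scipy); heterogeneity across diseases uses a
chi-square homogeneity test with a 10,000-resample permutation p-value
whenever an expected cell is below 5. Spearman p-values: exact
enumeration of rank permutations for n ≤ 7, t-approximation above
(full enumeration at n = 10 costs 3.6M correlations and buys nothing at
that sample size). OLS fits an intercept; the slope and its SE are
reported. Mann-Whitney tests are two-sided with scipy's exact method
for small samples. Display rounding is half-up, with raw values always
emitted alongside.

## Test and acceptance problem sizes

Simulation-based checks use sizes chosen to make Monte-Carlo error
small relative to the asserted tolerances while keeping the whole
suite under a minute: ≥2000 attempts per π_share setting for the
recovery slope (tolerance ±0.1); 200 exchangeable regions × 199
permutations for the uniformity KS check (the discrete p-grid
1/200 … 1 is fine at that resolution); 12 regions per group × 121
windows for the targeted-drift offset comparison; 100 random 50×50
matrices for the eigen-oracle agreement at 10⁻⁸. The acceptance script
generates one 650-SNP region pair and counts the 121 scan windows.

## Open choices made here

* Fig-style OR/MAF profiles use sliding windows of width 0.3 and step
  0.05 with a ≥20-attempt floor; width/step are parameters because the
  "bin" vs "window with step" conventions in the field are ambiguous.
* The Poisson CI on the implied attempt pool is Garwood-exact by
  default (a normal approximation is available); for k = 103 and
  α·p_dir = 0.025 it gives 3363–4997. Published analyses of this kind
  have printed slightly narrower intervals whose exact parametrization
  is not recoverable; the difference is documented rather than chased.
* The log-OR distribution across loci is a stand-in (log-normal
  magnitude); nothing downstream depends on its exact shape, and it is
  exposed in `DbSimConfig`.
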