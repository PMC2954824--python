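# Methods

## The adaptive-cluster test

The unit of analysis is the multi-site genotype: the dosage vector of an
individual over the rare (MAF ≤ 1%) sites of a gene region.  The sample risk
of pattern i, R̂ᵢ = (nᵢᴬ/nᵢ)/(Nᴬ/N), estimates P(affected | Gᵢ)/P(affected);
conceptually it follows a two-component mixture (non-causal vs causal
patterns) of which only the non-causal component is known under the null.
Rather than classifying patterns, KBAC weights each by the null cumulative
probability of its observed case count — the "area under" the known
component up to the observed sample risk.  Because nᵢᴬ is a strictly
monotone function of R̂ᵢ given (nᵢ, N, Nᴬ), weighting by the CDF of the case
count and of the sample risk coincide; the exact algebraic form chosen for
R̂ᵢ therefore does not affect the weights, only their interpretation.

Three kernels give the null CDF: hypergeometric (exact, conditional on both
margins; the default), marginal binomial, and a normal approximation.  The
normal kernel uses a half-integer continuity correction,
Φ((nᵢᴬ + ½ − nᵢp)/√(nᵢp(1−p))), p = Nᴬ/N: without the correction the gap to
the discrete inclusive CDF at the distribution's centre is half a
probability mass (~0.03 at nᵢ = 200), which would defeat the purpose of a
drop-in asymptotic kernel.  The statistic S = Σ wᵢ(nᵢᴬ/Nᴬ − nᵢᵁ/Nᵁ) omits
the wild-type pattern: any constant weight assigned to it cancels in the
score function, and the squared form S² serves two-sided testing.

Significance is empirical.  Permutation shuffles case labels; since the
pattern partition of individuals is fixed, this is executed exactly at the
tally level as a multivariate-hypergeometric redraw of case counts over
pattern classes (wild-type included).  The Monte Carlo approximation redraws
nᵢᴬ* ~ Binomial(nᵢ, Nᴬ/N) independently across patterns — adequate because
rare patterns are nearly independent given their totals.  In both schemes
the weights are recomputed inside every iteration (via a precomputed lookup
table over all possible case counts, which is a recomputation, not a
freeze); freezing the observed weights would inflate type I error because
the weighting is phenotype-dependent.  Empirical p-values use the add-one
convention p = (1 + #{S* ≥ S_obs})/(B + 1), counting ties inclusively, so
p ∈ (0,1] and the test is exact-conservative.

Power under a specified alternative can also be computed without data: given
pattern frequencies in cases and controls, pattern totals are drawn
multinomially, a conditional null quantile is estimated from binomial
redraws at the null case fraction, alternative redraws use the conditional
case probability πᵢ = NᴬpᵢA/(NᴬpᵢA + NᵁpᵢU), and the unconditional power
averages the conditional rejection rates.

## Covariate adjustment

Confounders (age, sex, ancestry eigenvectors, or common-variant dosages)
enter through a logistic null model fit by maximum likelihood; the score for
the kernel-weight variable, U = Σ(yⱼ − p̂ⱼ)xⱼ, is assessed by permuting
phenotype labels and refitting the null model each time, keeping the
adaptive weights and the null fit internally consistent within every
permuted dataset (a Freedman–Lane scheme is noted as an alternative but not
shipped).  With an empty covariate set, p̂ⱼ is the constant case fraction
and U = (NᴬNᵁ/N)·S exactly — the module's correctness oracle, tested to
1e−10.  The permutation p-value is one-sided (case enrichment), matching the
one-sided S.

## Comparator tests

CMC here is the rare-variant collapsing form benchmarked against KBAC:
carrier indicator (any rare dosage > 0) × Pearson 1-df χ² with analytic p
and no continuity correction.  The full CMC with Hotelling's T² for mixed
common/rare groups is intentionally out of scope; common variants are
handled as covariates instead.  WSS follows Madsen–Browning: per-site weight
1/√(N q(1−q)) with q = (mᵁ+1)/(2Nᵁ+2) the smoothed control frequency,
per-individual weighted mutation score, statistic = sum of case ranks,
two-sided permutation p about the exact permutation mean Nᴬ(N+1)/2; weights
are recomputed per permutation.  Since non-carriers score exactly zero under
every weighting, ranking is performed over carriers only with the zero block
contributing its average tied rank — an exact rewriting used for speed.  RVE
counts carriers of case-exclusive variants among cases versus carriers of
control-exclusive variants among controls (a variant seen in both classes
contributes to neither), takes the two-sided Fisher exact p as statistic,
and obtains significance from label permutations with exclusivity
re-determined per permutation — the conservative reading of an
under-specified design, locked by tests.

## Genetic data generation

Haplotype pools come from an individual-based infinite-sites Wright–Fisher
simulation of a 1500-bp coding locus without recombination: Poisson mutation
influx 2NμL per generation at fresh sites; selection coefficients from a
gamma DFE acting on diploid viability (fitness 1, 1−hs, 1−s; h = 0.5
additive by default); fitness-proportional multinomial reproduction;
fixed/lost sites pruned.  Viability selection with multinomial resampling
was chosen over fertility selection; the difference affects only
higher-order moments.  All simulated sites are treated as non-synonymous
(the analyses use only NS variants); a configurable neutral fraction exists
for sensitivity checks.

The shipped demography/DFE configuration is a literature-inspired
placeholder in the spirit of published human NS-mutation estimates: a
two-epoch African-American-like expansion (ancestral diploid size 7778 →
25636, 6809 generations), gamma DFE on −s with shape 0.184 and mean 0.043,
and μ = 1.8×10⁻⁸ per bp per generation; a bottleneck European-like
configuration is also shipped.  These are config inputs, not hard-coded
claims, and can be replaced wholesale.

Desk-scale runs rescale by c: sizes and durations ÷ c, μ and s × c,
preserving θ, Ns and drift time; s is clamped at 0.95 after rescaling
(mutations that strong essentially never segregate regardless).  We verified
the aggregate rare-site frequency of the pools is stable across c ∈
{50, 25, 10}; the studies use c = 10 (pool of 2Nc ≈ 5128 haplotypes).  The
known cost of rescaling is truncation of the ultra-rare tail below
1/(2Nc) ≈ 2×10⁻⁴: sample site counts and exclusive-site counts are mildly
reduced relative to a full-scale run, which depresses the methods that feed
on very rare variation (WSS's frequency weighting, RVE's exclusivity) more
than the others.  A direct SFS-driven generator (per-site Binomial(2, f)
dosages in linkage equilibrium) bypasses population genetics when a site
frequency spectrum is supplied.

## Phenotype models

Disease status follows a linear log-odds model: log-odds = log(b) + Σ causal
alleles' log OR, with baseline odds b = 0.01 by default (the studied
populations' prevalence is not pinned down; b is a config field, and the
carrier-based quantities below are insensitive to it).  Fixed effects use
OR = 3 per causal allele; 50% of rare sites are causal by default (nearest
integer, ties up).  Variable effects map MAF to OR inversely.  The default
map is log-log-linear, OR(f) = clamp(2·(0.01/f)^¼, 2, 20): it spans the
stated 2–20 range across MAF 10⁻²–10⁻⁶ and keeps the bulk of
sample-detectable variants (MAF ~ 10⁻³–10⁻²) at ORs 2–4.  A reciprocal map
OR(f) = clamp(0.02/f, 2, 20) is available as a config option but not
default: because f·OR is then constant, every causal site contributes equal
case-carrier mass, inflating the case:control carrier ratio to ~5–7 and
saturating power — inconsistent with the moderate carrier enrichment and
with most detected variants having ORs in 2–4.

Interactions: in the within-gene model a causal rare allele acts (OR 3) only
in cis with the minor allele of one randomly chosen common (MAF > 20%) site,
using the true simulated phase; in the between-gene model two independent
pools form unlinked genes, causal gene-1 alleles always act (OR 4) and
causal gene-2 alleles act (OR 2) only in individuals with no causal gene-1
allele.  Ascertainment draws individuals (pairs of pool haplotypes, with
replacement) and assigns status by a Bernoulli draw until exactly Nᴬ cases
and Nᵁ controls accrue; a draw cap guards pathological configurations.

Misclassification acts only on the analyst's view: phenotypes always derive
from the full causal set, after which the analysis matrix keeps
(1 − exclude_fraction) of causal sites and include_fraction of non-causal
sites (uniform random subsets, nearest-integer rounding).  Rarity and
causality are population-level (pool) properties in the simulation studies;
the analysis matrix is pruned to sites polymorphic in the sample but not
re-filtered by sample MAF (the sample-MAF filter exists for real-data
analysis, where population frequencies are unknown).

## Study conditions and problem sizes

Power and summary studies use 30 pools, 300 replicates × 1000 permutations
per scenario cell, 1000/1000 samples (within-gene) and α = 0.01 — the
package's desk-scale defaults; the full-scale design (100 pools, 2000
replicates × 5000 permutations) is available through the same config fields.
α = 0.01 was fixed by back-calculation: a two-proportion normal
approximation applied to the generated carrier frequencies under the
fixed-effects model reproduces the collapsing test's empirical power at
α = 0.01 and not at 0.05.  The type-I study uses 2000 null replicates at
400/400 with B = M = 1000.

## What the generator does and does not emulate

It emulates: a purifying-selection-shaped rare SFS for a short NS locus
under expansion demography; case-control sampling with ascertainment to
fixed quotas; analyst-side variant misclassification; cis-acting and
between-locus epistasis.  It does not emulate: recombination or gene
conversion within the locus; sequencing/genotyping error; sample-level
missingness; population structure within a pool (structure is handled only
through covariates); quantitative-trait genetics beyond quartile
dichotomization.  Passing tests on these simulations therefore demonstrate
statistical correctness and the relative behaviour of the methods under the
stated generative models, not performance on any particular real dataset.

## Numerical and design notes

* Kernel CDFs go through scipy's log-space implementations; enumeration
  oracles agree to 1e−12 across (nᵢ ≤ 50, N ≤ 200).
* Pattern order is lexicographic on the dosage vector, making tallies and
  statistics invariant to individual and site order.
* Empirical p-values count ties inclusively.  At desk scale the sample
  often holds only a few polymorphic rare sites, so the permutation null is
  markedly discrete: null p-values have an atom floor near 0.07 and the
  empirical size at 0.05 is conservative (~0.025–0.045 depending on the pool
  set) while permutation and Monte Carlo p-values remain concordant
  (Spearman ρ ≈ 0.998).  Mid-p corrections would smooth the distribution at
  the cost of exactness and are not used.
* All randomness flows from numpy `SeedSequence` spawning: a master seed
  reproduces pools, replicates and resamples byte-identically.
* Degenerate inputs: an all-common or monomorphic region yields an empty
  rare matrix and p = 1 with a warning; one-class phenotypes raise;
  separation in the null logistic fit raises with a diagnostic.

## Known limitations

Desk-scale rescaling truncates the ultra-rare tail, reducing sample site
counts relative to a full-scale run; the carrier-frequency *ratios* are
unaffected but exclusivity-driven quantities (RVE power, exclusive-site
counts) run low, and the weighted-sum test loses part of its edge over plain
collapsing.  The carrier-status odds ratio implied by a per-allele OR of 3
is exactly 3, so generated case:control carrier ratios sit near 2.9;
published tables from comparable designs sometimes print lower ratios,
which cannot arise from this model family at any prevalence.  The
between-gene model assumes exactly two loci; the quartile design assumes a
continuous trait with few boundary ties.
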