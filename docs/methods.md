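# Methods

## Demographic and sampling model

The inference targets a single coetaneous cohort founded by one zygote pool,
with no immigration or recruitment after the first sample.  Genotype counts
`(y11, y12, y22)` at each biallelic locus and time step are modelled as
independent multinomial draws: the two-step process of founding a cohort of
size `N` from the pool and then sampling `n` individuals from the cohort is
equivalent to one multinomial draw of `n` from the pool, and this remains a
good approximation after mortality whenever `N >> n`.  Exhaustive sampling
(`n = N`) violates the independence assumption; it is supported as a
reference mode and the evaluation tools quantify how the methods behave
there (tests become conservative, estimation error shrinks).

Sample sizes may differ across loci at the same time step (per-locus missing
data); all computations are per locus.  Allele 1 is whichever allele the
input lists first; minor allele frequency is computed from the total pooled
sample, and loci that are monomorphic in the pool or fall at or below the MAF
threshold (default 0.05) are excluded from scans because the standardized
change is degenerate or uninformative there.

## Neutrality tests

The change statistic between consecutive samples is
`Δ = (f_t − f_{t−1})² / (z − z²)` with `z` the mean of the two allele
frequencies.  When both samples are fixed for the same allele (`z ∈ {0, 1}`)
Δ is defined as 0: the numerator vanishes faster than the denominator in the
limit, and "no change" is the right semantics for fixed outcomes.

The null distribution of Δ is induced by two independent multinomial draws
from the pool frequencies, estimated from the total pooled sample across
*all* time steps with 1/3 pseudo-counts per genotype class
(`p̂ = (y + 1/3)/(n + 1)`), which encodes the assumption that all three
genotypes exist in the cohort even if undetected.  The pooled estimate is
used for every period of a multi-period scan, since the null hypothesis is
that every sample comes from one common pool.

The quasi-exact p-value is the inclusive tail `Pr(Δ ≥ Δ_obs)`.  Rather than
the quadruple sum over genotype-count pairs (O(n⁴), prohibitive beyond a few
hundred), the implementation first computes the exact probability vector of
the allele count `a = 2·y11 + y12` for each sample size — Δ depends on an
outcome only through `a` — and then scans allele-count pairs, an exact
O(n²) reordering.  The enumeration runs over the full outcome space
including zero counts (probabilities must sum to 1).  Multinomial
probabilities are computed in log space via log-gamma and exponentiated per
row, so sample sizes in the thousands are overflow-safe.  A guard refuses
samples above 2,000 (configurable) and points to the Monte Carlo test.  The
tie comparison `Δ ≥ Δ_obs` is evaluated with a relative guard of 1e−12 so
that the observed outcome itself is always counted; distinct Δ values on the
grid are separated by far more than this at any feasible n.

The Monte Carlo test simulates B pairs of draws (default B = 10,000) and
reports the plain proportion with `Δ_sim ≥ Δ_obs`.  The proportion can be 0;
an `add_one` flag switches to `(k+1)/(B+1)` for a guaranteed-positive
p-value, and the multi-locus scan uses that variant so that ranked
multiple-testing output never contains exact zeros.

Scans test every consecutive period of every retained locus and apply
Benjamini–Hochberg across all locus-by-period tests as one family by
default.  The family structure of FDR control across periods is a genuine
design choice; a `per_period` option corrects each period separately.
`method="auto"` uses the quasi-exact test up to n = 500 per sample and Monte
Carlo above, matching the cost crossover of the enumeration.

## Bayesian selection-coefficient estimation

Genotype relative fitnesses in period t are `(1+2s_t, 1+2h·s_t, 1)`;
post-selection expected frequencies are `p·w/w̄`.  The likelihood multiplies
the multinomial probabilities of all samples, with expected frequencies
computed sequentially from `p0` through `s_1..s_t`.  Priors: flat Dirichlet
(α = 1) on `p0`; uniform `(−0.5, 10⁶)` on each `s_t` (the lower bound keeps
fitness positive; the huge upper bound is harmless after transformation);
uniform `(0, 1)` on `h`, or `h` fixed (0.5 reproduces codominant designs).

The sampler is Metropolis-within-Gibbs with Gaussian random-walk proposals
on unconstrained coordinates, with the prior densities carried through the
corresponding Jacobians:

- `p0` via additive log-ratio coordinates `(log p11/p22, log p12/p22)`;
- each `s_t` via `log(s_t + 0.5)`;
- `h` via `logit(h)` (block skipped when fixed).

Step sizes adapt every 50 iterations during burn-in toward ~30% acceptance
(multiplicative updates clipped to e^±0.5) and are frozen afterwards, so the
retained draws come from a fixed-kernel Markov chain.  Chains are
bit-reproducible given a seed; per-chain seeds derive from a
`numpy.random.SeedSequence`.  Library defaults are 60,000 iterations, 10,000
burn-in, thinning 10, one chain; a multi-chain mode jitters starting points
and reports split-R̂ per period.  The simulation harness and the acceptance
script use 6,000 iterations / 1,500 burn-in / thinning 3 per replicate:
with two temporal samples the posterior is low-dimensional and unimodal,
mixing is fast (acceptance ~0.3 after adaptation), and these lengths already
give Monte Carlo error well below the sampling noise being measured; the
defaults remain the conservative choice for single-locus analyses.

Point estimates are the posterior median and mean; intervals are equal-tailed
at 95% by default (highest-posterior-density intervals are available behind
a flag).  "Significant" means the interval excludes 0.

## Cohort simulator

Each replicate founds a cohort of `N` genotypes multinomially from
Hardy–Weinberg proportions at the scenario's MAF (an explicit zygote-pool
override is accepted), records the `t = 0` sample, and then alternates
selection episodes and sampling.  Survival is individual and stochastic:
a genotype-g individual survives an episode with probability `w_g / w_max`.
This scaling makes survival purely *relative* — under neutrality everyone
survives — which reproduces two boundary behaviors that anchor the design:
exhaustive samples of a neutral cohort are literally identical (Δ = 0, zero
type-I error), and under selection the realized frequency change converges
to the deterministic selection map as N grows.  An optional
`baseline_survival` multiplier adds genotype-independent mortality for
sensitivity analyses.

Samples are drawn without replacement from the currently alive individuals
(multivariate hypergeometric), so the multinomial approximation of the
inference model is itself under test.  A replicate whose survivor pool is
smaller than the requested sample is flagged and excluded, never silently
resampled (resampling would condition on survival and bias the study);
flags propagate into the replicate tables and metric reports.  Per-replicate
RNG streams spawn deterministically from the scenario's master seed.

## Evaluation metrics

From a replicate table: bias and RMSE of both the posterior-mean and
posterior-median point estimates around the true `s`; noncoverage rate (NCR)
of the credible intervals against the true `s`; rejection rate of the
neutrality test at α (type-I error when `s = 0`, power otherwise); and the
Bayesian rejection rate (interval excludes 0).  Grid runs evaluate a list of
scenarios, key results by `(N, n, maf, s)` and keep going past per-scenario
failures.

The bundled tests and the acceptance script run the reference designs at
500 replicates per test cell and 200 replicates for MCMC scenarios, with
binomial allowances set accordingly; the full-scale study design uses 1,000
replicates per cell and is a parameter away (`SimulationScenario.replicates`).

## Known limitations

- Single-locus marginal inference: estimated coefficients average over
  genomic backgrounds; linked or epistatic selection is not modelled, and
  polygenic selection spread over many small-effect loci will mostly evade
  per-locus tests.
- Weak selection (|s| ~ 0.01) is statistically indistinguishable from
  sampling noise at realistic sample sizes; the power of both methods sits
  at the false-positive level there.
- The multinomial sampling assumption degrades when samples are a large
  fraction of a small cohort; the exhaustive mode documents, but does not
  fix, that regime.
- The simulator draws a closed cohort with synchronous episodes; emergence
  phenology, immigration, spatially biased sampling and genotyping error are
  outside its scope, so passing tests say nothing about those failure modes
  in field data.
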