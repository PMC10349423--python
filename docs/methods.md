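# Methods

## The deconvolution model

A plasma cfDNA sample is modelled as a three-component mixture. On panel
block *j* the probability that a CpG read is methylated is

    β_j = α β_j^(T) + γ β_j^(N) + (1 − α − γ) β_j^(0),

with α the ctDNA fraction, γ the fraction of cfDNA shed by tumor-adjacent
normal tissue, β^(T)/β^(N) the patient's measured tissue levels, and
β_j^(0) the latent healthy-background level, given a per-block
Beta(p_j, q_j) prior. Methylated counts are binomial given β_j, so the
block marginal likelihood is the binomial pmf integrated over the
background prior; at α = γ = 0 it collapses to the classical
beta-binomial. The sample log-likelihood sums the block marginals over
the patient's panel, treating blocks as independent — reasonable for
blocks that are genomically well separated, optimistic for any that are
not.

Assumptions worth keeping in mind: tissue levels β^(T), β^(N) are taken
as known constants (deep tissue sequencing), the background prior is
taken as transferable from healthy donors to patients, and the same
(α, γ) applies to every block of a sample.

The mixture substitutes the background variable directly, i.e. the
integral runs over β^(0) with its own density (equivalently, the
change-of-variables Jacobian 1/(1 − α − γ) is included). This makes every
block marginal a true probability — the pmf over M sums to 1 for any
(α, γ), which the test suite asserts.

## Estimation and the MRD score

(α̂, γ̂) maximizes the log-likelihood on the simplex
{α ≥ 0, γ ≥ 0, α + γ ≤ 1 − 1e−6}, by multi-start SLSQP with analytic
gradients from a 3×3 start grid over {0, 1e−3, 1e−2} × {0, 0.05, 0.2};
the likelihood can be flat or weakly bimodal in γ when β^(N) is close to
the background mean, and the multi-start plus the γ-profiled null fit
(α = 0) guard against a start-dependent answer. The reported full
log-likelihood is never allowed below the null profile.

The timMRD score is the Wald statistic α̂² / var(α̂), with var(α̂) the
(α, α) entry of the inverse observed information. The Hessian is taken by
central differences of the analytic gradient (step 1e−4, shrunk to stay
inside the feasible region); when the information matrix is not positive
definite the score falls back to the profile-likelihood curvature in α.
An MLE exactly at the α = 0 boundary scores 0 by convention.

Calls use the χ²₁ quantile at the 98th percentile, 5.412, with a strict
inequality: score > 5.412 is MRD-high. Because α sits on the boundary of
the parameter space under H₀, the null law of the score is a ½χ²₀ + ½χ²₁
mixture rather than χ²₁; the χ²₁ threshold is therefore conservative
(empirically ≤ 1% false-high at the nominal 2% level), which the
calibration test documents rather than corrects.

## Quadrature

The background integral is evaluated with a Gauss–Jacobi rule whose
weight function *is* the Beta(p, q) density. After mapping to (0, 1) the
remaining integrand is the binomial pmf — a polynomial of degree N in
β^(0) — so the order-K rule is exact (up to rounding) whenever
N ≤ 2K − 1; the default K = 128 covers depths to 255 and stays accurate
far beyond. This also handles shape parameters below 1, whose endpoint
singularities defeat generic rules at tight tolerances.

Nodes and weights come from Golub–Welsch on the Jacobi recurrence,
normalized so the weights are squared first-eigenvector components
summing to 1. Working with the normalized measure avoids the
2^(p+q−1) total-mass factor that overflows textbook Jacobi weight
formulas once the concentration p + q reaches a few hundred — a regime
real low-background panels occupy. One consequence: far-tail weights
underflow to zero, flooring log-pmf accuracy at roughly −70 log-units;
this only affects events with probability below ~1e−30 and is irrelevant
for data that can actually occur under the model. Accumulation is
log-sum-exp throughout.

## Background prior

Per block, Beta(p_j, q_j) is fitted to healthy-donor ratios M/N
(depth ≥ min_depth, default 10) by the method of moments: with clipped
sample mean m̄ and unbiased variance v, concentration c = m̄(1 − m̄)/v − 1,
p = m̄c, q = (1 − m̄)c. Ratios at exactly 0 or 1 are clipped to
[1e−4, 1 − 1e−4]. Degenerate blocks (v ≤ 1e−8 or c ≤ 0, or fewer than two
covered samples) fall back to a pseudocount fit at concentration 100 with
ε = 0.5, centred on the block (or panel-pooled) mean, so every block
keeps a proper prior. Moments were preferred over beta MLE because they
are closed-form, deterministic, and adequate for a prior; note they
absorb binomial sampling noise into the prior variance, which widens the
prior at low healthy-cohort depth and makes scores conservative rather
than anticonservative.

## Marker selection

Cohort-level DMB discovery is a paired Wilcoxon signed-rank test per
block on tumor − adjacent-normal levels with Benjamini–Hochberg
correction across blocks, an effect floor on the mean paired difference
(default 0.1), and hypermethylation as the default direction. The
patient-specific panel keeps blocks with tumor level ≥ prior mean + 0.2
and ≥ adjacent-normal + 0.1, prior concentration ≥ 10, ranked by
tumor-over-prior margin, truncated at 5,000 blocks. Ties break by block
id so selection is fully deterministic. These concrete thresholds are a
reconstruction: they preserve the tumor-informed logic (markers must
stand clear of both the patient's normal tissue and the population
background) while remaining configurable.

## Synthetic cohorts

The generator produces data exactly as the likelihood assumes — per block
background draw, mixture, overdispersed depth (negative-binomial, mean
200, size 10, mirroring variable cfDNA input), binomial counts — so
simulator and scorer share one generative contract, which a
self-consistency test checks. Defaults: 1,000 blocks, 50 planted
tumor-hypermethylated blocks at tissue level 0.6–0.9, background shapes
p ∈ (0.5, 2), q ∈ (30, 100) (prior means ≈ 0.5–6%).

Two deliberate regimes:

* the **default panel** (concentration ~30–100) is where parameter
  recovery, calibration, and the main dilution curve are run; its limit
  of detection sits near α ≈ 1e−3 at depth 200 because the background
  *prior* variance, not sequencing depth, bounds the per-block Fisher
  information;
* the **deep panel** (p ∈ (0.3, 1), q ∈ (500, 2000), depth 5,000)
  emulates the tight, low-background behaviour of a production assay,
  where fractions of 2e−4 and below become detectable. The
  limit-of-detection checks use this regime.

Longitudinal cohorts: baseline α log-uniform on (0.002, 0.05); cured
patients clear to α = 0 after surgery; relapsing patients (30%) decay
with a 7-day time constant, then regrow exponentially with a 90-day time
constant toward a relapse-day α log-uniform on (0.03, 0.15), relapse days
uniform on (270, 630). Sampling follows the pre-surgery / day-3 /
day-36 / quarterly-follow-up schedule. The mutation readout (maxAF) is a
noisy attenuated transform of α — attenuation 0.15, log-normal noise
sd 1.2, reporting floor 0.001 — calibrated so the mutation assay's
horizon sensitivity lands near the ~45% reported for tumor-informed
mutation MRD while methylation reaches ~90%: the generator encodes the
empirical observation that methylation signal precedes mutation
detectability at low burden. The generator does **not** model
clonal hematopoiesis, batch effects, bisulfite conversion failure,
fragment-length biology, or panel dropout beyond depth overdispersion —
so passing tests demonstrate correctness of the inference machinery under
its own assumptions, not robustness to real-world artifacts.

## Surveillance evaluation

Lead time is relapse_day minus the day of the earliest positive
postoperative sample (patients never positive before relapse are excluded
from averages). Horizon confusion evaluates each relapsed patient at the
last sample at or before relapse_day − horizon (default 120 days) and
each non-relapsed patient at their last follow-up sample — a simple,
deterministic stand-in for per-timepoint matching. ROC curves sweep the
score threshold over all observed horizon scores with trapezoidal AUC
(checked against the Mann–Whitney identity). The Plasma B/C survival
grouping takes the worse of the two samples when both exist. Fisher exact
tests, Wilcoxon tests, and BH correction are delegated to scipy;
Kaplan–Meier/Cox modelling is out of scope — `export_survival_table`
emits (patient_id, dfs_days, event, group) for standard survival tooling.

## Problem sizes

Studies run at desk scale, chosen once: parameter recovery at m = 500
blocks, depth 200, 100 replicates per α; null calibration at m = 300,
500 replicates; dilution curve at m = 1,000, 25 replicates per fraction;
optimizer-vs-grid checks on 30-block panels (the grid oracle is
exhaustive and only tractable for small m); surveillance on 200 patients
with 400-block panels (~100 selected DMBs) at depth 150. At these sizes
the operating characteristics (bias within a few percent, null rate ≤ 1%,
power curves) are stable across seeds.

## Known limitations

* Tissue levels are treated as noise-free; very low tumor purity would
  bias β^(T) toward β^(N) and α̂ upward correspondingly.
* The χ²₁ threshold is conservative under the boundary null (documented
  above); no chi-bar-square correction is applied, matching the
  published calling rule.
* The Wald variance uses a finite-difference observed information; for
  α̂ within ~1e−4 of the boundary the step shrinks and the score becomes
  noisier — the profile-curvature fallback covers indefinite cases.
* Block independence is assumed; correlated neighbouring blocks would
  inflate scores.
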