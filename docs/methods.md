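# Methods

## Model

One simulated *set* is 30 sachets; the first 10 form the stage-1 sample.
For a sachet with target count n:

1. **Miscounts.** Each of the n intended tablets independently suffers a
   miscount with probability p; a miscount is an overfill (+1 tablet)
   with probability f (default 0.5, per the equal over/underfill
   assumption) or an underfill (−1). The realized count is
   c = n + Σ Eᵢ·Dᵢ, floored at zero (only reachable at n = 1). A single
   Bernoulli opportunity is attached to each *intended* tablet — the
   dosing mechanism's n feed events — so one sachet can accumulate
   several ±1 errors but each tablet at most one; error opportunities do
   not grow with realized count.
2. **Contents.** Each realized tablet's relative content is
   W·P with W ~ N(1, σ_w), P ~ N(1, σ_p) independent (*separate* mode) or
   a single N(1, σ_c) draw (*composite* mode). Negative draws are floored
   at zero with a warning; at the modeled RSDs (≤15%) this is a ≥6.7σ
   event with no practical effect.
3. **Assay.** assay = 100·(Σ contents)/n %LC; batch means are centred at
   100% of target, so results are independent of absolute dose.

The set is judged by the harmonized USP <905> CU procedure
(`sachetcu.usp905`): AV = |M − x̄| + k·s with the sample SD (n−1
denominator), k = 2.4 (n = 10) / 2.0 (n = 30), M the mean clamped to
[98.5, 101.5] %LC, pass iff AV ≤ 15, and — during stage 2 only — every
unit within the closed interval (1 ± 0.25)·M. The AV formula and clamp
band are pinned by the individual-limit extremes 73.875–123.125 and
76.125–126.875 (= (1 ± 0.25)·98.5 and (1 ± 0.25)·101.5). Ties at
AV = 15 pass; both tie conventions are measure-zero under continuous
noise and matter only in the zero-RSD arithmetic (a 3-of-4 fill at
exactly 75.0 %LC passes the individual check when M = 100 but fails when
M < 98.6). Stage-1 failure probability is defined as P(AV₁ > 15) — the
stage-2 trigger rate — and stage-2 failure as overall batch-release
failure, which makes stage-2 ≤ stage-1 structural. The weight-variation
pathway and the T > 101.5 labeling variants of the compendial text are
out of scope; the CU branch subsumes weight variation as the
σ_p → 0 limit.

## Parameters and defaults

| parameter | meaning | default / range |
|---|---|---|
| σ_w, σ_p | bulk tablet weight and potency RSD (fractions) | 0–0.10 modeled |
| σ_c | composite RSD = √(σ_w²+σ_p²) | 0–0.15 modeled |
| n | target tablets per sachet | 1–10 modeled |
| p | per-tablet miscount probability | 0–0.10 modeled |
| f | overfill fraction of miscounts | 0.5 (exposed; real processes may be asymmetric) |
| n_sets | simulated sets per scenario | 1e6 (matches the 1e-6 = 0.0001% reporting floor); 1e5 per grid cell |

Grid defaults: counts 1–10, composite RSD 0–15% in 1-point steps, error
probabilities {0, 1e-6, 1e-5, 1e-4, 1e-3, 1e-2, 1e-1} (the decade-spaced
rows of the study's contour figures; the exact lattice of those figures
is not printed, so every axis is overridable).

## Estimation and uncertainty

Failure probabilities are failure frequencies over n_sets independent
sets. Intervals are Wilson 95% score intervals (well behaved near zero).
Zero observed failures are flagged `below_floor` and should be read as
"< 1/n_sets", mirroring the study's white-space convention. Mean
acceptance values are reported three ways (stage 1; stage 2 over all
sets; stage 2 over sets that entered stage 2) since the study does not
say which its AV panels show; conclusions drawn here (AV insensitivity
to p) hold for all three.

Sampling detail: in composite mode the sum of c iid N(1, σ_c) contents
is exactly N(c, √c·σ_c), so `simulate_assay_sets(method="collapsed")`
draws one normal per sachet instead of one per tablet — identical in
distribution up to the negligible non-negativity floor — and is the
default for composite mode (a distribution-equality test backs this).
Per-tablet sampling (`method="tablet"`) is the default for separate mode
and available everywhere.

Reproducibility: one user seed expands into named substreams (SHA-256 of
the cell label folded into a `SeedSequence`), one per scenario or grid
cell, so sweep results are bit-reproducible and independent of
evaluation order.

Solvers certify against the Wilson upper bound, not the point estimate;
`solve_max_error_prob` evaluates its p lattice under common random
numbers (shared per-sachet uniforms mapped through the inverse binomial
CDF, which is monotone in p, plus shared content normals), so its
estimates are paired.

## Independent oracles

* `stage1_fail_closed_form`: with p = 0 the per-sachet assay is
  N(100, 100·σ_c/√n), the stage-1 sample SD satisfies
  9s²/σ_s² ~ χ²₉ independently of the mean, and
  P(AV₁ > L1) = E_m[ P(χ²₉ > 9((L1 − g(m))/(2.4σ_s))²) ] with
  g(m) the distance of the mean outside the clamp band, integrated
  numerically over the mean's normal law. This is exact for the
  composite model. The pure chi-square tail (`include_mean_term=False`)
  is also provided; it is accurate only when the mean rarely leaves the
  band — at σ_c ≈ 7%, n = 1 the mean term raises the rate from 0.634 to
  0.691, which simulation confirms.
* `zero_rsd_oracle`: with zero tablet variability the assay is exactly
  100·c/n, so the judgment depends only on the 30 realized counts; an
  independent scalar re-coding of the decision flow chart cross-checks
  the vectorized estimator, and the realized-count law itself is checked
  against exact enumeration of the (error, direction) outcomes in the
  tests.

## What the generator does and does not emulate

The generator reproduces the study conditions: normally distributed
content, batch means on target, independent per-tablet Bernoulli
miscounts with an even direction split. It does not model broken or
chipped tablets, log-normal or uniform content distributions, temporally
clustered errors, weight-dependent error rates, off-target batch means,
or multi-drug combination sachets. Passing tests therefore demonstrate
correctness of the stated model, not of any particular real filling
line, whose error mechanism may be asymmetric or correlated.

## Agreement with the published values

The package's own cross-checks close: simulation matches the exact
closed form at p = 0 (< 1 SE at 4e5 sets), the count-only oracle at
σ = 0, and the enumeration law of realized counts; the study's internal
calibration points also reproduce — mean AV₁ ≈ 5.8% at n = 4,
σ_c = 5% (stated as ~6%), stage-2 failure < 1e-6 for the error-free
10-count row at all modeled RSDs, and ≈2% failure at n = 4, σ_c = 5%,
p = 0.1% (stated order 1%).

The published *headline maxima*, however, are reproduced only in part.
The grid-wide maximum (~97.6%) matches within a few percent, and the
fill-count solver returns exactly the published answer (counts 5–10).
Elsewhere this implementation's values differ by factors of 1.5–6 in
*both* directions within the same mechanistic regime (e.g. the
counts 5–10 maxima at 5%/5% RSD come out ~1.5× lower than printed at
p ≤ 0.1% but ~2× higher at p = 1%, and the variance-dominated
single-count cells come out ~3.6× higher). No coherent variant of the
stated model that we could construct — per-sachet instead of per-tablet
error opportunities, direction asymmetry, realized-count opportunity
basis, alternative stage-2 conditioning, global variance rescaling —
moves all cells toward the printed values simultaneously, and the
rescaling that fixes the single-count cells contradicts the
mean-AV calibration above. The related published transition claims land
close but short here: the count-4→5 failure drop at σ_c = 2%, p = 1% is
~5-fold (described as up to 10-fold), and the mean-AV shift between
p = 0 and p = 0.1% at n = 4, σ_c = 5% is 0.6 points. The acceptance
checks encode the printed values unchanged and are left failing where
they disagree; the computed numbers are reported as-is.

## Numerical choices

Chunked simulation (2.5e5 sets per chunk) bounds memory; per-tablet
sampling caps draw blocks at 2e7 tablets. The closed form integrates on
a ±8σ grid of 8001 points (trapezoid; error far below MC resolution).
Counts are exact integers; assays exact rationals at σ = 0, so the
boundary conventions above are deterministic there. Stage-1-only
judgments (10 values) return a STAGE2_REQUIRED outcome rather than a
batch verdict.
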