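# Methods

## The audit model

Each record is one 1:1 two-arm randomized trial with a single continuous
primary outcome, summarized at its pre-specified (or last) follow-up
time-point. Trials with three or more arms, or without per-arm means, are
outside the data model. The audit derives, per trial:

1. **Weighted mean and pooled SD.** The weighted mean is the sample-size
   weighted average of the arm means. The pooled SD is
   √[((n₁−1)s₁² + (n₂−1)s₂²)/(n₁+n₂−2)]. When an arm reports SE instead of
   SD, SD = SE·√n. When it reports a CI of its mean, the implied SE is the
   half-width over the interval quantile: the normal quantile when the
   degrees of freedom exceed 60, otherwise Student-t (df = n−1 for an arm
   CI; df = n₁+n₂−2 when converting a CI of the mean difference via
   SE_diff = SD·√(1/n₁+1/n₂)). Both divisors are exposed
   (`use_t ∈ {auto, never}`); `auto` is the default. Recovery precedence is
   least-derived first: per-arm SD > reported total SD (accepted as the
   pooled SD directly, tagged `TOTAL_SD`) > SE > CI; the most derived path
   used anywhere is recorded as the audit tag.

2. **Percent-of-best-score normalization.** For a bounded scale with
   declared worst and best scores (direction encoded purely by their
   ordering), mean_pct = 100·(mean − worst)/(best − worst) and
   sd_pct = 100·SD/|best − worst|. Both are invariant under affine re-coding
   of the instrument and under reflecting its direction; these invariances
   are property-tested. Native means outside the scale fail loudly
   (`OUT_OF_RANGE`) beyond a tolerance of 10⁻⁶ of the span — extraction
   mistakes should not be silently clipped.

3. **Ceiling crossover.** A trial is flagged when mean_pct + k·sd_pct
   strictly exceeds 100 (k = 1 by default, configurable; the exact-100
   boundary is deliberately *not* flagged — "over" is read strictly). The
   companion quantity `tail_beyond_ceiling` is the exact normal upper-tail
   mass above 100 for N(mean_pct, sd_pct): ≈ 0.159 when mean + SD sits
   exactly at the ceiling — the "about 16 %" rule of thumb. A mirror-image
   floor check exists but is off in the default pipeline. The flag is a
   normal-approximation heuristic on summary statistics, not an estimate of
   the true censored distribution.

4. **Effect-size ratio.** d_obs = |mean₁ − mean₂|/SD_pooled,
   d_est = |MD_est|/SD_est (or a directly reported standardized effect,
   flagged in provenance), ratio = d_obs/d_est. Magnitudes only: direction
   of benefit is not tracked. A trial missing any ingredient is counted
   ineligible rather than erroring, so the eligibility chain
   (total → power calculation usable → summaries recoverable →
   scale-normalizable → ratio-eligible) is non-increasing and fully
   reported in the run manifest.

## Binning and rendering conventions

The published-style labels leave several boundaries open; one convention is
fixed and used everywhere:

* Follow-up (coarse): not applicable, <3 months, 3–6, 6–12, >12 months;
  half-open on the right with 1 month = 30.4375 days and 1 year = 365.25
  days (so 365 days is *within* 12 months, 730 days is beyond). A finer
  nine-category view (≤1 d, 1 d–1 w, 1 w–1 m, 1–3 m, 3 m–1 y, 1–3 y,
  3–10 y, >10 y, plus not-applicable) is available; the 1–3 month bin is
  included so the bins partition the whole axis.
* Weighted-mean percent: ≤60; (60, 75]; (75, 85]; (85, 90); 90 exactly
  falls in the ≥90 bin.
* Ratio: [0, 0.5), [0.5, 1.0), [1.0, 1.5), ≥1.5 (1.0 belongs to 1.0–1.5).
* Percent cells: nearest integer, half away from zero (half-even is
  available as an option); values below 1 % render with one decimal
  ("0.4 %"). The weighted-mean table uses row-wise cell percents with a
  grand-total margin column; the ratio table uses column-wise percents and
  a median (IQR) line per follow-up column, quartiles by linear
  interpolation between order statistics.

## The synthetic registry

The generator emulates the statistical structure the audit presumes, not
any particular set of published trials:

* **Outcome model.** Per patient, outcome = N(latent mean, σ) *censored*
  (clipped, not truncated) at the scale bounds — clipping creates the
  boundary point-mass that defines a ceiling effect. σ is drawn per trial
  as 12–25 % of the scale span (non-PROM outcomes are unbounded with
  native-unit σ in 8–25).
* **Recovery curve.** The latent control mean sits at position
  p(t) = b∞ − (b∞ − b₀)e^(−t/τ) of the worst→best range, with per-trial
  b₀ ~ 0.45 ± 0.10, b∞ ~ 0.92 ± 0.04, τ = 120 days: means approach the
  ceiling as follow-up lengthens. Follow-up is drawn over the coarse bins
  with weights (0.05, 0.22, 0.16, 0.16, 0.41) for PROM trials and
  (0.24, 0.30, 0.16, 0.15, 0.15) otherwise, uniform within bin.
* **Effect and its inflation.** The latent between-arm effect is
  |N(0.25, 0.12)|·σ (floor 0.02σ), directed toward the best score. The
  power calculation's MD_est is the latent effect times a lognormal factor
  with median 2.4 (log-sd 0.5) — a tuning default chosen so the simulated
  overall median observed/estimated ratio lands in the ~0.4 regime, not an
  empirical estimate; SD_est equals the true σ and is present in 60 % of
  trials.
* **Reporting realism.** 76/264 of records lose all variability statistics
  (exercising the ineligibility tallies); the rest present per-arm SDs
  (70 %), SEs (12 %), per-arm 95 % CIs (10 %) or a total SD only (8 %).
  Rationale codes and distribution-presentation codes are drawn from
  multinomials proportional to the frequencies a ~264-trial registry of
  this kind exhibits; the "mean/median only" code is exclusive, the others
  set-valued. Sample sizes are log-uniform in [20, 200] per arm —
  typical of the field, not prescribed.
* **Determinism.** One master seed spawns an independent child stream per
  trial (`numpy` SeedSequence), so registries are byte-reproducible and
  stable under any parallel re-ordering of trial generation.
* **Oracle channel.** Each record carries a latent-truth twin: latent
  means, true standardized effect, inflation factor, per-arm ceiling mass,
  and the censored population's exact moments (closed-form clipped-normal
  mean/SD) with the crossover flag they imply. Truths are written to a
  separate CSV and never enter the public registry.

What passing tests on this substrate show — and what they do not: the
pipeline's algebra, conventions, eligibility plumbing and the qualitative
censoring mechanism are verified end-to-end against independent oracles
(raw-data pooling, brute-force tallies, closed-form censored moments,
null/no-attenuation simulations). They do not certify the generator's
marginal rates as estimates of any real literature: real trial registries
have correlated missingness, non-normal outcomes, heterogeneous variance
between arms and instrument-specific ceiling behaviour that the generator
deliberately omits.

## Problem sizes and numerical choices

The default registry is 264 trials; oracle and recovery tests use 500–2,000
trials, and the attenuation sweep runs 500 replicates per grid point on a
5-point grid with 60 patients per arm — sizes at which binomial/Monte-Carlo
error bars are tight enough for 3-sigma assertions while the whole suite
stays fast. Crossover-fraction recovery is asserted within three binomial
standard errors of the truth-channel fraction; trials whose population
mean + SD sits within sampling noise of exactly 100 % can flip flag either
way, which is symmetric and absorbed by that band. Degenerate inputs are
defined explicitly rather than left to float behaviour: zero-width CIs give
SD 0; sd_pct = 0 makes the ceiling tail 0/0.5/1 below/at/above the ceiling;
pooled SD requires n₁+n₂ ≥ 3; a scale with best = worst is rejected at
validation.

## Known limitations

* The ceiling assessment never models the truncated/censored likelihood;
  it is the normal heuristic on summaries, by design.
* SD recovery from p-values or median/IQR (Wan/Hozo-type estimators) is
  out of scope.
* Only 1:1 two-arm parallel designs are represented; crossover and
  multi-arm trials are excluded at validation.
* The ratio analysis treats MD_est and SD_est as exact; uncertainty in the
  power-calculation inputs themselves is not propagated.
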