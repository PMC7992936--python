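# powergap

Audit pipeline for the gap between what two-arm randomized trials are
*powered* to detect and what they actually *observe* — aimed at
meta-researchers studying trial design in fields (orthopaedics above all)
where the primary outcome is a bounded patient-reported outcome measure
(PROM).

Sample-size calculations rest on an assumed mean difference MD_est and SD
estimate. Two things routinely go wrong: the MD_est is poorly justified and
inflated, so the observed standardized effect falls short of the one powered
for; and on a bounded scale the sample mean drifts toward the best score as
follow-up lengthens, piling observations at the ceiling and masking
between-group differences. `powergap` quantifies both from trial-level
extraction records, and ships a seeded synthetic-registry generator (with a
latent-truth oracle channel) so the whole pipeline is testable without any
external data.

## What it computes

Given per-arm summaries (n, mean, and SD, SE or CI), scale bounds, the power
calculation and follow-up time for each trial:

* **Pooled variability** — SD recovered from SE (SD = SE·√n) or from a CI
  (half-width over the z or small-sample t quantile), then pooled:
  SD_pooled = √[((n₁−1)s₁² + (n₂−1)s₂²)/(n₁+n₂−2)]; the n-weighted mean
  across arms.
* **Ceiling diagnostics** — the weighted mean and SD_pooled re-expressed as
  percent of the best attainable score (100 % = ceiling, direction-aware); a
  *crossover flag* when mean + k·SD > 100 % (k = 1 by default; under
  normality ≈ 16 % of patients would then sit beyond the ceiling), plus the
  exact normal-tail fraction.
* **Effect-size attenuation** — observed d = |mean₁ − mean₂| / SD_pooled
  against estimated d = |MD_est| / SD_est, and their ratio; a ratio below 1
  means the trial observed less than it was powered for.
* **Report tables** — rationale taxonomy for MD_est, distribution-reporting
  taxonomy, weighted-mean × follow-up and ratio × follow-up
  cross-tabulations with count (percent) cells and median (IQR) lines.

## Worked example

```sh
python analysis/01_generate_registry.py   # 264 synthetic trials
python analysis/02_audit_registry.py      # full audit + report tables
python analysis/03_attenuation_sweep.py   # censoring attenuation sweep
```

The audit step prints the eligibility chain and headline findings:

```
264 records (0 rejected rows)
  usable power calculation : 155
  recoverable summaries    : 182
  scale-normalizable       : 110
  ratio-eligible           : 105
ceiling crossover (mean + 1 SD > 100 %): 44/110 (40 %)
median observed/estimated effect-size ratio: 0.43 over 105 trials
  Follow-up between 3 and 6 months: 0.76
  Follow-up between 6 and 12 months: 0.36
  Follow-up over 12 months: 0.39
  Follow-up time not applicable: 0.39
  Follow-up under 3 months: 0.62
```

Reading: of 264 generated trials, 182 printed recoverable variability; 110
of those carry a bounded PROM scale and in 40 % of these the weighted mean
plus one pooled SD crosses the ceiling — a plausible ceiling effect. Among
the 105 trials where both effect sizes are computable, the median
observed-to-estimated ratio is 0.43: the typical trial observed less than
half the standardized effect it was powered for, and the shortfall grows
with follow-up as means approach the ceiling. The attenuation sweep isolates
the mechanism: with the latent effect pinned at 0.5 SD, the mean observed d
drops about 17 % as the latent mean moves from mid-scale to 95 % of the
range.

The same pipeline runs on any registry CSV in the documented schema
(see `powergap/registry_io.py`):

```sh
powergap generate -o out/           # synthetic registry + truths + manifest
powergap audit -i out/registry.csv -o out/audit/
```

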