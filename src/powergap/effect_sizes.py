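"""Observed vs estimated standardized effect sizes and their ratio.

The observed effect size is the standardized mean difference actually seen
in the trial, d_obs = |mean_a − mean_b| / SD_pooled. The estimated effect
size is the one the trial was powered for, d_est = |MD_est| / SD_est from
the sample-size calculation. Their ratio is the attenuation statistic: a
ratio below 1 means the trial observed a smaller standardized effect than
it assumed when choosing its sample size.

Both effect sizes are taken as absolute magnitudes — direction of benefit
is not tracked.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .records import ArmSummary, PowerCalculation, TrialRecord
from .variability import PooledSummary, pooled_summary

__all__ = [
    "EffectSizePair",
    "observed_effect_size",
    "estimated_effect_size",
    "effect_size_ratio",
    "effect_size_pair",
]


@dataclass(frozen=True)
class EffectSizePair:
    d_obs: float
    d_est: float
    ratio: float
    # True when the power calculation reported a standardized effect size
    # directly (accepted as d_est without division)
    est_was_standardized: bool = False


def observed_effect_size(arm_a: ArmSummary, arm_b: ArmSummary, sd_pooled: float) -> float:
    """|mean_a − mean_b| / SD_pooled."""
    md = abs(arm_a.mean - arm_b.mean)
    if sd_pooled <= 0:
        if md == 0:
            return 0.0
        raise ValueError("observed effect size undefined: SD_pooled = 0 with MD != 0")
    return md / sd_pooled


def estimated_effect_size(power: PowerCalculation) -> Optional[float]:
    """|MD_est| / SD_est, or the reported standardized effect directly.

    Returns None when the power calculation does not permit a standardized
    effect size (no SD assumption) — the trial is then ineligible for the
    ratio analysis, not an error.
    """
    if power.md_est is None:
        return None
    if power.standardized:
        return abs(power.md_est)
    if power.sd_est is None or power.sd_est <= 0:
        return None
    return abs(power.md_est) / power.sd_est


def effect_size_ratio(d_obs: float, d_est: float) -> float:
    """d_obs / d_est (requires d_est > 0)."""
    if d_est <= 0:
        raise ValueError(f"d_est must be > 0, got {d_est}")
    return d_obs / d_est


def effect_size_pair(
    record: TrialRecord, pooled: Optional[PooledSummary] = None
) -> Optional[EffectSizePair]:
    """Full per-trial comparison, or None when any ingredient is missing."""
    if record.power is None:
        return None
    d_est = estimated_effect_size(record.power)
    if d_est is None or d_est == 0:
        return None
    if pooled is None:
        flags = record.flags
        if flags is not None and not flags.has_outcome_summaries:
            return None
        try:
            pooled = pooled_summary(record)
        except ValueError:
            return None
    if pooled.sd_pooled <= 0:
        return None
    d_obs = observed_effect_size(record.arm_a, record.arm_b, pooled.sd_pooled)
    return EffectSizePair(
        d_obs, d_est, effect_size_ratio(d_obs, d_est), record.power.standardized
    )
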