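"""Variability algebra: recover SDs from SE or CI and pool across arms.

The conversions follow the standard meta-analytic identities (Cochrane
Handbook ch. 6): SD = SE·√n for one arm; for a confidence interval the
implied standard error is the half-width divided by the normal (or, in small
samples, Student-t) quantile, and an interval around the *mean difference*
converts through SE_diff = SD·√(1/n_a + 1/n_b).

Pooling uses the two-sample pooled SD

    SD_pooled = sqrt( ((n_a−1)·s_a² + (n_b−1)·s_b²) / (n_a + n_b − 2) )

and the weighted mean weights arm means by arm sample size.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from scipy import stats

from .records import ArmSummary, ConfidenceInterval, TrialRecord

__all__ = [
    "SdSource",
    "PooledSummary",
    "sd_from_se",
    "sd_from_ci",
    "arm_sd_from_ci",
    "resolve_arm_sd",
    "pooled_sd",
    "weighted_mean",
    "pooled_summary",
]

# above this many degrees of freedom the t quantile is indistinguishable
# from z at reporting precision; use the large-sample divisor
_Z_DF_THRESHOLD = 60


class SdSource(str, enum.Enum):
    BOTH_SD = "BOTH_SD"
    TOTAL_SD = "TOTAL_SD"
    FROM_SE = "FROM_SE"
    FROM_CI = "FROM_CI"


@dataclass(frozen=True)
class PooledSummary:
    """n-weighted mean and pooled SD of a two-arm trial, with the recovery
    path recorded for audit."""

    weighted_mean: float
    sd_pooled: float
    n_total: int
    source: SdSource


def _quantile(level: float, df: int, use_t: str = "auto") -> float:
    """Two-sided interval quantile: z for large df, t otherwise."""
    if use_t == "never" or (use_t == "auto" and df > _Z_DF_THRESHOLD):
        return stats.norm.ppf(0.5 + level / 2.0)
    return stats.t.ppf(0.5 + level / 2.0, df)


def sd_from_se(se: float, n: int) -> float:
    """SD = SE·√n."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if se < 0:
        raise ValueError(f"se must be >= 0, got {se}")
    return se * math.sqrt(n)


def sd_from_ci(
    lower: float,
    upper: float,
    n_a: int,
    n_b: int,
    level: float = 0.95,
    use_t: str = "auto",
) -> float:
    """Recover the pooled SD from a CI of the *mean difference*.

    SE_diff = (upper − lower) / (2·q); SD = SE_diff / √(1/n_a + 1/n_b),
    with q the z quantile for large samples and the t quantile with
    df = n_a + n_b − 2 otherwise.
    """
    if lower > upper:
        raise ValueError("CI lower > upper")
    if not (0.0 < level < 1.0):
        raise ValueError(f"level must be in (0,1), got {level}")
    if n_a < 1 or n_b < 1:
        raise ValueError("arm sizes must be >= 1")
    q = _quantile(level, n_a + n_b - 2, use_t)
    se_diff = (upper - lower) / (2.0 * q)
    return se_diff / math.sqrt(1.0 / n_a + 1.0 / n_b)


def arm_sd_from_ci(ci: ConfidenceInterval, n: int, use_t: str = "auto") -> float:
    """Recover one arm's SD from a CI of that arm's *mean*:
    SE = half-width / q (df = n − 1), then SD = SE·√n."""
    if n < 2:
        raise ValueError("arm CI recovery needs n >= 2")
    q = _quantile(ci.level, n - 1, use_t)
    return sd_from_se(ci.width / (2.0 * q), n)


def resolve_arm_sd(arm: ArmSummary, use_t: str = "auto") -> tuple[float, SdSource]:
    """Pick the least-derived variability statistic: SD > SE > CI."""
    if arm.sd is not None:
        return arm.sd, SdSource.BOTH_SD
    if arm.se is not None:
        return sd_from_se(arm.se, arm.n), SdSource.FROM_SE
    if arm.ci is not None:
        return arm_sd_from_ci(arm.ci, arm.n, use_t), SdSource.FROM_CI
    raise ValueError("arm has no variability statistic")


def pooled_sd(s_a: float, s_b: float, n_a: int, n_b: int) -> float:
    if n_a + n_b < 3:
        raise ValueError("pooled SD undefined for n_a + n_b < 3")
    df = n_a + n_b - 2
    return math.sqrt(((n_a - 1) * s_a**2 + (n_b - 1) * s_b**2) / df)


def weighted_mean(mean_a: float, mean_b: float, n_a: int, n_b: int) -> float:
    if n_a < 1 or n_b < 1:
        raise ValueError("arm sizes must be >= 1")
    return (n_a * mean_a + n_b * mean_b) / (n_a + n_b)


def pooled_summary(record: TrialRecord, use_t: str = "auto") -> PooledSummary:
    """Weighted mean + pooled SD for a trial, by recovery precedence:
    per-arm SD > reported total SD > per-arm SE > per-arm CI."""
    a, b = record.arm_a, record.arm_b
    wmean = weighted_mean(a.mean, b.mean, a.n, b.n)
    n_total = a.n + b.n

    if a.sd is not None and b.sd is not None:
        return PooledSummary(
            wmean, pooled_sd(a.sd, b.sd, a.n, b.n), n_total, SdSource.BOTH_SD
        )
    if record.total_sd is not None:
        return PooledSummary(wmean, record.total_sd, n_total, SdSource.TOTAL_SD)

    s_a, src_a = resolve_arm_sd(a, use_t)
    s_b, src_b = resolve_arm_sd(b, use_t)
    # most-derived path taken anywhere determines the audit tag
    if SdSource.FROM_CI in (src_a, src_b):
        source = SdSource.FROM_CI
    elif SdSource.FROM_SE in (src_a, src_b):
        source = SdSource.FROM_SE
    else:
        source = SdSource.BOTH_SD
    return PooledSummary(wmean, pooled_sd(s_a, s_b, a.n, b.n), n_total, source)
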