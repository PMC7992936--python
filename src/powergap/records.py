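"""Trial-record data model and validation.

One :class:`TrialRecord` holds what a reader can extract from a published
two-arm randomized trial report: per-arm sample sizes, outcome means with
whatever variability statistic the article printed (SD, SE or a confidence
interval), the bounds and direction of the outcome scale when the outcome is
a bounded instrument, the mean-difference and SD assumptions of the a-priori
power calculation, the follow-up time of the analysed endpoint, and two
post-hoc taxonomies: the rationale given for the power-calculation mean
difference, and how the article presented the distribution of outcome scores.

Validation never alters values; it attaches eligibility flags (does the
record support pooled-SD recovery, scale normalization, ratio analysis) or
rejects the record with a machine-readable reason code.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = [
    "PromScale",
    "ConfidenceInterval",
    "ArmSummary",
    "PowerCalculation",
    "RationaleCode",
    "DistributionCode",
    "TrialRecord",
    "EligibilityFlags",
    "RecordRejection",
    "RejectionReason",
    "validate_record",
]


class RejectionReason(str, enum.Enum):
    """Machine-readable reasons a raw record is refused outright."""

    NONPOSITIVE_N = "NONPOSITIVE_N"
    MISSING_N = "MISSING_N"
    MISSING_MEAN = "MISSING_MEAN"
    NEGATIVE_SD = "NEGATIVE_SD"
    NEGATIVE_SE = "NEGATIVE_SE"
    BAD_CI = "BAD_CI"
    DEGENERATE_SCALE = "DEGENERATE_SCALE"
    NEGATIVE_FOLLOWUP = "NEGATIVE_FOLLOWUP"
    ZERO_MD_EST = "ZERO_MD_EST"
    NONPOSITIVE_SD_EST = "NONPOSITIVE_SD_EST"


@dataclass(frozen=True)
class PromScale:
    """A bounded outcome scale with an explicit best-score direction.

    Direction is encoded purely by ordering: ``best_score`` may lie below
    ``worst_score`` (a 0-10 pain scale has best = 0, worst = 10).
    """

    worst_score: float
    best_score: float
    is_prom: bool = True

    @property
    def span(self) -> float:
        return abs(self.best_score - self.worst_score)

    @property
    def lo(self) -> float:
        return min(self.worst_score, self.best_score)

    @property
    def hi(self) -> float:
        return max(self.worst_score, self.best_score)

    def is_degenerate(self) -> bool:
        return self.best_score == self.worst_score


@dataclass(frozen=True)
class ConfidenceInterval:
    lower: float
    upper: float
    level: float = 0.95

    @property
    def width(self) -> float:
        return self.upper - self.lower


@dataclass(frozen=True)
class ArmSummary:
    """Per-arm n, mean and at most one *needed* variability statistic.

    Articles occasionally print more than one of SD / SE / CI; all are kept
    and the variability module resolves them by precedence (least-derived
    first) rather than rejecting redundancy.
    """

    n: Optional[int] = None
    mean: Optional[float] = None
    sd: Optional[float] = None
    se: Optional[float] = None
    ci: Optional[ConfidenceInterval] = None

    def has_variability(self) -> bool:
        return self.sd is not None or self.se is not None or self.ci is not None


class RationaleCode(str, enum.Enum):
    """Taxonomy of justifications given for the power-calculation MD estimate."""

    NONE = "NONE"
    MCID_MDC_PASS = "MCID_MDC_PASS"
    PROM_VALIDATION = "PROM_VALIDATION"
    STD_EFFECT_SIZE = "STD_EFFECT_SIZE"
    SYSTEMATIC_REVIEW = "SYSTEMATIC_REVIEW"
    RCTS = "RCTS"
    OBSERVATIONAL = "OBSERVATIONAL"
    PILOT = "PILOT"
    CASE_SERIES = "CASE_SERIES"
    CLINICAL_RELEVANCE = "CLINICAL_RELEVANCE"
    PROPORTIONAL = "PROPORTIONAL"


class DistributionCode(str, enum.Enum):
    """How an article presented the distribution of primary-outcome scores.

    ``MEAN_MEDIAN_ONLY`` is mutually exclusive with every other code; the
    remaining codes are set-valued (an article can show both box plots and
    outlier counts).
    """

    MEAN_MEDIAN_ONLY = "MEAN_MEDIAN_ONLY"
    CATEGORIES = "CATEGORIES"
    BOX_PLOTS = "BOX_PLOTS"
    PATIENT_LEVEL_CHANGE = "PATIENT_LEVEL_CHANGE"
    N_AT_CEILING_FLOOR = "N_AT_CEILING_FLOOR"
    N_OUTLIERS = "N_OUTLIERS"
    N_RESPONDERS = "N_RESPONDERS"
    N_GAINED_MIC_MDC = "N_GAINED_MIC_MDC"
    SCATTER_PLOT = "SCATTER_PLOT"


@dataclass(frozen=True)
class PowerCalculation:
    """The assumptions of a trial's a-priori sample-size calculation."""

    md_est: Optional[float] = None
    sd_est: Optional[float] = None
    rationale: RationaleCode = RationaleCode.NONE
    power_target: Optional[float] = None
    alpha: Optional[float] = None
    # md_est already standardized (an effect size, not native units)
    standardized: bool = False


@dataclass(frozen=True)
class EligibilityFlags:
    """Derived record-level eligibility, mirroring a screening flow chart."""

    has_power_calc: bool = False
    has_outcome_summaries: bool = False
    has_scale: bool = False
    has_followup: bool = False

    @property
    def ratio_eligible(self) -> bool:
        # observed and estimated effect sizes both computable
        return self.has_power_calc and self.has_outcome_summaries


@dataclass(frozen=True)
class TrialRecord:
    """One extracted two-arm (1:1) randomized trial.

    ``followup_days is None`` encodes a "not applicable" follow-up (length of
    hospital stay, intra-operative blood loss and similar endpoints have no
    follow-up time-point).
    """

    trial_id: str
    arm_a: ArmSummary
    arm_b: ArmSummary
    scale: Optional[PromScale] = None
    power: Optional[PowerCalculation] = None
    total_sd: Optional[float] = None
    followup_days: Optional[float] = None
    distribution_codes: frozenset[DistributionCode] = field(default_factory=frozenset)
    ceiling_discussed: bool = False
    flags: Optional[EligibilityFlags] = None


@dataclass(frozen=True)
class RecordRejection:
    trial_id: str
    reason: RejectionReason
    detail: str = ""


def _check_arm(arm: ArmSummary, label: str) -> Optional[tuple[RejectionReason, str]]:
    if arm.n is None:
        return RejectionReason.MISSING_N, f"arm {label}: n missing"
    if arm.n < 1:
        return RejectionReason.NONPOSITIVE_N, f"arm {label}: n = {arm.n}"
    if arm.mean is None or (isinstance(arm.mean, float) and math.isnan(arm.mean)):
        return RejectionReason.MISSING_MEAN, f"arm {label}: mean missing"
    if arm.sd is not None and arm.sd < 0:
        return RejectionReason.NEGATIVE_SD, f"arm {label}: sd = {arm.sd}"
    if arm.se is not None and arm.se < 0:
        return RejectionReason.NEGATIVE_SE, f"arm {label}: se = {arm.se}"
    if arm.ci is not None:
        if arm.ci.lower > arm.ci.upper:
            return RejectionReason.BAD_CI, f"arm {label}: CI lower > upper"
        if not (0.0 < arm.ci.level < 1.0):
            return RejectionReason.BAD_CI, f"arm {label}: CI level {arm.ci.level}"
    return None


def _arm_sd_recoverable(arm: ArmSummary) -> bool:
    return arm.sd is not None or arm.se is not None or arm.ci is not None


def validate_record(record: TrialRecord) -> TrialRecord | RecordRejection:
    """Validate structure and attach eligibility flags.

    Returns the record (values untouched, ``flags`` populated) or a
    :class:`RecordRejection` with a reason code. A record missing variability
    statistics is *kept* with ``has_outcome_summaries = False`` — it is still
    countable in rationale and follow-up tabulations — whereas structural
    nonsense (negative n, inverted CI, a scale whose best equals its worst)
    is refused.
    """
    for arm, label in ((record.arm_a, "a"), (record.arm_b, "b")):
        problem = _check_arm(arm, label)
        if problem is not None:
            return RecordRejection(record.trial_id, problem[0], problem[1])

    if record.scale is not None and record.scale.is_degenerate():
        return RecordRejection(
            record.trial_id,
            RejectionReason.DEGENERATE_SCALE,
            f"best = worst = {record.scale.best_score}",
        )
    if record.followup_days is not None and record.followup_days < 0:
        return RecordRejection(
            record.trial_id,
            RejectionReason.NEGATIVE_FOLLOWUP,
            f"followup_days = {record.followup_days}",
        )
    if record.total_sd is not None and record.total_sd < 0:
        return RecordRejection(
            record.trial_id, RejectionReason.NEGATIVE_SD, f"total_sd = {record.total_sd}"
        )
    if record.power is not None:
        if record.power.md_est is not None and record.power.md_est == 0:
            return RecordRejection(
                record.trial_id, RejectionReason.ZERO_MD_EST, "md_est = 0"
            )
        if record.power.sd_est is not None and record.power.sd_est <= 0:
            return RecordRejection(
                record.trial_id,
                RejectionReason.NONPOSITIVE_SD_EST,
                f"sd_est = {record.power.sd_est}",
            )

    has_power = record.power is not None and (
        record.power.md_est is not None
        and (record.power.sd_est is not None or record.power.standardized)
    )
    summaries = (
        _arm_sd_recoverable(record.arm_a) and _arm_sd_recoverable(record.arm_b)
    ) or record.total_sd is not None
    flags = EligibilityFlags(
        has_power_calc=has_power,
        has_outcome_summaries=summaries,
        has_scale=record.scale is not None,
        has_followup=record.followup_days is not None,
    )
    return replace(record, flags=flags)
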