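"""Normalization of outcome summaries onto a bounded scale.

A bounded patient-reported outcome is re-expressed as percent of the best
attainable score: 0 % is the worst score, 100 % is the ceiling, whatever the
instrument's native direction. A trial whose weighted mean plus k pooled
SDs (k = 1 by default) exceeds 100 % carries a *crossover flag*: were the
latent outcome unbounded-normal, a non-trivial share of patients — about
16 % at k = 1 — would sit at or beyond the ceiling, so a ceiling effect in
the observed data is plausible.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .records import PromScale

__all__ = [
    "ScaledSummary",
    "OutOfRangeError",
    "to_scale_percent",
    "sd_to_percent",
    "ceiling_crossover",
    "floor_crossover",
    "tail_beyond_ceiling",
    "scaled_summary",
]

# absolute slop, as a fraction of the scale span, absorbed before an
# out-of-range native mean is treated as an extraction mistake
DEFAULT_RANGE_TOL = 1e-6


class OutOfRangeError(ValueError):
    """Native mean lies outside the scale bounds beyond tolerance."""


@dataclass(frozen=True)
class ScaledSummary:
    """A trial's outcome on the percent-of-best-score scale."""

    mean_pct: float
    sd_pct: float
    crossover_flag: bool
    k: float = 1.0


def to_scale_percent(
    mean: float, scale: PromScale, tol: float = DEFAULT_RANGE_TOL
) -> float:
    """Percent of the best score: 100·(mean − worst)/(best − worst).

    Direction-aware — works whether the best score is the top or the bottom
    of the native range. A mean outside the scale by more than ``tol·span``
    raises :class:`OutOfRangeError` (no silent clipping); within tolerance
    it is snapped to the boundary.
    """
    if scale.is_degenerate():
        raise ValueError("degenerate scale: best = worst")
    slop = tol * scale.span
    if mean < scale.lo - slop or mean > scale.hi + slop:
        raise OutOfRangeError(
            f"mean {mean} outside scale [{scale.lo}, {scale.hi}]"
        )
    mean = min(max(mean, scale.lo), scale.hi)
    return 100.0 * (mean - scale.worst_score) / (scale.best_score - scale.worst_score)


def sd_to_percent(sd: float, scale: PromScale) -> float:
    """SD in percent of the scale span (direction-free)."""
    if sd < 0:
        raise ValueError(f"sd must be >= 0, got {sd}")
    if scale.is_degenerate():
        raise ValueError("degenerate scale: best = worst")
    return 100.0 * sd / scale.span


def ceiling_crossover(mean_pct: float, sd_pct: float, k: float = 1.0) -> bool:
    """True iff mean + k·SD strictly exceeds the ceiling (100 %)."""
    return mean_pct + k * sd_pct > 100.0


def floor_crossover(mean_pct: float, sd_pct: float, k: float = 1.0) -> bool:
    """Mirror-image floor check (mean − k·SD below 0 %); off by default in
    the audit pipeline, provided for symmetric analyses."""
    return mean_pct - k * sd_pct < 0.0


def tail_beyond_ceiling(mean_pct: float, sd_pct: float) -> float:
    """Normal upper-tail mass beyond the ceiling.

    P[X > 100] for X ~ N(mean_pct, sd_pct): the model-implied fraction of
    patients at or above the best score were the latent outcome unbounded.
    At mean + SD = 100 this is 1 − Φ(1) ≈ 0.1587 (the "about 16 %" rule of
    thumb). Degenerate sd_pct = 0 returns the point-mass limit: 0 below the
    ceiling, 1 above, 0.5 exactly at it.
    """
    if sd_pct < 0:
        raise ValueError(f"sd_pct must be >= 0, got {sd_pct}")
    if sd_pct == 0:
        return 0.0 if mean_pct < 100.0 else (1.0 if mean_pct > 100.0 else 0.5)
    return float(stats.norm.sf(100.0, loc=mean_pct, scale=sd_pct))


def scaled_summary(
    mean: float,
    sd: float,
    scale: PromScale,
    k: float = 1.0,
    tol: float = DEFAULT_RANGE_TOL,
) -> ScaledSummary:
    """Convert a native-unit (mean, SD) pair onto the percent scale and flag
    ceiling crossover."""
    mean_pct = to_scale_percent(mean, scale, tol)
    sd_pct = sd_to_percent(sd, scale)
    return ScaledSummary(mean_pct, sd_pct, ceiling_crossover(mean_pct, sd_pct, k), k)
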