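"""Categorization schemes and report tables.

Frequencies, cross-tabulations and median (IQR) summaries over classified
trial records. Two follow-up binning schemes are provided: a coarse
five-category scheme (not applicable / <3 m / 3–6 m / 6–12 m / >12 m) used
by the cross-tabulated reports, and a finer nine-category scheme. Weighted
means on the percent scale and observed/estimated effect-size ratios get
their own bin schemes.

Boundary conventions (the published labels leave several boundaries open;
one convention is fixed here and documented):

* follow-up bins are half-open on the right, with months = 30.4375 days and
  years = 365.25 days;
* percent bins: ≤60 includes 60; (60, 75]; (75, 85]; (85, 90); 90 exactly
  falls in the ≥90 bin;
* ratio bins are half-open on the right with 1.0 in the 1.0–1.5 bin;
* percents render as nearest integer, half away from zero, with one decimal
  place below 1 %.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DAYS_PER_MONTH",
    "DAYS_PER_YEAR",
    "FollowupBin",
    "FollowupBin9",
    "MeanPctBin",
    "RatioBin",
    "AuditTable",
    "bin_followup",
    "bin_mean_pct",
    "bin_ratio",
    "frequency_table",
    "crosstab",
    "median_iqr",
    "render_percent",
]

DAYS_PER_MONTH = 30.4375
DAYS_PER_YEAR = 365.25


class FollowupBin(str, enum.Enum):
    """Coarse follow-up categories used by the cross-tabulated reports."""

    NOT_APPLICABLE = "Follow-up time not applicable"
    UNDER_3M = "Follow-up under 3 months"
    M3_TO_6M = "Follow-up between 3 and 6 months"
    M6_TO_12M = "Follow-up between 6 and 12 months"
    OVER_12M = "Follow-up over 12 months"


class FollowupBin9(str, enum.Enum):
    """Finer follow-up view. The 1–3 month bin completes the partition of
    the time axis (without it, follow-ups between one and three months would
    have no home)."""

    NOT_APPLICABLE = "Not applicable"
    LE_1D = "1 day or less"
    D1_TO_1W = "1 day to 1 week"
    W1_TO_1M = "1 week to 1 month"
    M1_TO_3M = "1 month to 3 months"
    M3_TO_1Y = "3 months to 1 year"
    Y1_TO_3Y = "1 to 3 years"
    Y3_TO_10Y = "3 to 10 years"
    OVER_10Y = "Over 10 years"


class MeanPctBin(str, enum.Enum):
    LE_60 = "<=60 %"
    GT60_LE75 = "Over 60 % and <=75 %"
    GT75_LE85 = "Over 75 % and <=85 %"
    GT85_LT90 = "Over 85 % and <90 %"
    GE_90 = "Over 90 %"


class RatioBin(str, enum.Enum):
    LT_0_5 = "< 0.5"
    R0_5_TO_1 = "0.5-1.0"
    R1_TO_1_5 = "1.0-1.5"
    GT_1_5 = "> 1.5"


def bin_followup(
    followup_days: Optional[float], scheme: str = "coarse"
) -> FollowupBin | FollowupBin9:
    """Deterministic follow-up bin; ``None`` means not applicable.

    ``scheme``: ``"coarse"`` (five categories) or ``"nine"``.
    """
    if followup_days is not None and followup_days < 0:
        raise ValueError(f"negative follow-up: {followup_days}")
    if scheme == "coarse":
        if followup_days is None:
            return FollowupBin.NOT_APPLICABLE
        t = followup_days
        if t < 3 * DAYS_PER_MONTH:
            return FollowupBin.UNDER_3M
        if t < 6 * DAYS_PER_MONTH:
            return FollowupBin.M3_TO_6M
        if t < DAYS_PER_YEAR:
            return FollowupBin.M6_TO_12M
        return FollowupBin.OVER_12M
    if scheme == "nine":
        if followup_days is None:
            return FollowupBin9.NOT_APPLICABLE
        t = followup_days
        if t <= 1:
            return FollowupBin9.LE_1D
        if t <= 7:
            return FollowupBin9.D1_TO_1W
        if t <= DAYS_PER_MONTH:
            return FollowupBin9.W1_TO_1M
        if t <= 3 * DAYS_PER_MONTH:
            return FollowupBin9.M1_TO_3M
        if t <= DAYS_PER_YEAR:
            return FollowupBin9.M3_TO_1Y
        if t <= 3 * DAYS_PER_YEAR:
            return FollowupBin9.Y1_TO_3Y
        if t <= 10 * DAYS_PER_YEAR:
            return FollowupBin9.Y3_TO_10Y
        return FollowupBin9.OVER_10Y
    raise ValueError(f"unknown follow-up scheme {scheme!r}")


def bin_mean_pct(mean_pct: float) -> MeanPctBin:
    if not (0.0 <= mean_pct <= 100.0):
        raise ValueError(f"mean_pct out of [0, 100]: {mean_pct}")
    if mean_pct <= 60.0:
        return MeanPctBin.LE_60
    if mean_pct <= 75.0:
        return MeanPctBin.GT60_LE75
    if mean_pct <= 85.0:
        return MeanPctBin.GT75_LE85
    if mean_pct < 90.0:
        return MeanPctBin.GT85_LT90
    return MeanPctBin.GE_90


def bin_ratio(ratio: float) -> RatioBin:
    if ratio < 0:
        raise ValueError(f"negative ratio: {ratio}")
    if ratio < 0.5:
        return RatioBin.LT_0_5
    if ratio < 1.0:
        return RatioBin.R0_5_TO_1
    if ratio < 1.5:
        return RatioBin.R1_TO_1_5
    return RatioBin.GT_1_5


def render_percent(count: int, denominator: int, mode: str = "half-away") -> str:
    """Display percent: nearest integer (half away from zero by default,
    banker's rounding with ``mode="half-even"``); one decimal below 1 %."""
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    pct = 100.0 * count / denominator
    if 0 < pct < 1:
        return f"{pct:.1f} %"
    if mode == "half-away":
        rounded = math.floor(pct + 0.5) if pct >= 0 else math.ceil(pct - 0.5)
    elif mode == "half-even":
        rounded = round(pct)
    else:
        raise ValueError(f"unknown rounding mode {mode!r}")
    return f"{rounded:d} %"


def median_iqr(values: Sequence[float]) -> tuple[float, float, float]:
    """(median, Q1, Q3) with linear interpolation between order statistics."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("median_iqr of empty list")
    q1, med, q3 = np.percentile(arr, [25, 50, 75], method="linear")
    return float(med), float(q1), float(q3)


@dataclass
class AuditTable:
    """Labelled counts with rendered percents.

    ``counts`` is rows × cols; ``denominators`` follow ``percent_axis``:
    ``"row"`` (each cell over its row total), ``"col"`` (over its column
    total), or ``"grand"``/``"fixed"`` (every cell over one denominator —
    ``fixed`` with an explicit, possibly per-row, denominator for
    multi-valued classifiers whose counts do not sum to the denominator).
    """

    title: str
    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray
    percent_axis: str = "grand"
    fixed_denominators: Optional[np.ndarray] = None  # per-row, for axis="fixed"
    rounding: str = "half-away"
    extra_rows: dict[str, list[str]] = field(default_factory=dict)
    # column holding row margins; excluded from row denominators and scored
    # against the grand total itself
    total_col_index: Optional[int] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim == 1:
            self.counts = self.counts[:, None]
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")

    def _body(self) -> np.ndarray:
        if self.total_col_index is None:
            return self.counts
        return np.delete(self.counts, self.total_col_index, axis=1)

    def denominator_for(self, i: int, j: int) -> int:
        body = self._body()
        if j == self.total_col_index:
            return int(body.sum())
        if self.percent_axis == "row":
            return int(body[i].sum())
        if self.percent_axis == "col":
            return int(self.counts[:, j].sum())
        if self.percent_axis == "grand":
            return int(body.sum())
        if self.percent_axis == "fixed":
            if self.fixed_denominators is None:
                raise ValueError("fixed percent_axis needs fixed_denominators")
            return int(self.fixed_denominators[i])
        raise ValueError(f"unknown percent_axis {self.percent_axis!r}")

    def cell(self, i: int, j: int) -> str:
        count = int(self.counts[i, j])
        denom = self.denominator_for(i, j)
        if denom == 0:
            return f"{count}"
        return f"{count} ({render_percent(count, denom, self.rounding)})"

    def to_frame(self) -> pd.DataFrame:
        """Rendered "n (p %)" cells as a DataFrame (extra rows first)."""
        body = [
            [self.cell(i, j) for j in range(len(self.col_labels))]
            for i in range(len(self.row_labels))
        ]
        rows = list(self.extra_rows.values()) + body
        index = list(self.extra_rows.keys()) + self.row_labels
        return pd.DataFrame(rows, index=index, columns=self.col_labels)

    def counts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.row_labels, columns=self.col_labels
        )

    def to_markdown(self) -> str:
        frame = self.to_frame()
        lines = [f"### {self.title}", ""]
        header = "| | " + " | ".join(frame.columns) + " |"
        sep = "|" + "---|" * (len(frame.columns) + 1)
        lines += [header, sep]
        for label, row in frame.iterrows():
            lines.append("| " + str(label) + " | " + " | ".join(row) + " |")
        return "\n".join(lines) + "\n"


def frequency_table(
    items: Iterable,
    classifier: Callable,
    denominator: Optional[int] = None,
    title: str = "Frequency",
    class_order: Optional[Sequence] = None,
    rounding: str = "half-away",
) -> AuditTable:
    """One-column frequency table.

    ``classifier`` maps an item to a class label, a list of labels (the item
    is counted once per label — set-valued taxonomies), or None (skipped).
    Percents use ``denominator`` if given (so multi-valued counts can share
    one denominator), else the number of classified items.
    """
    items = list(items)
    tallies: dict = {}
    classified = 0
    for item in items:
        labels = classifier(item)
        if labels is None:
            continue
        if not isinstance(labels, (list, tuple, set, frozenset)):
            labels = [labels]
        if labels:
            classified += 1
        for label in labels:
            tallies[label] = tallies.get(label, 0) + 1

    if class_order is None:
        class_order = sorted(tallies, key=str)
    denom = denominator if denominator is not None else classified
    if denom == 0:
        raise ValueError("zero denominator")
    labels = [str(getattr(c, "value", c)) for c in class_order]
    counts = np.array([[tallies.get(c, 0)] for c in class_order], dtype=int)
    return AuditTable(
        title=title,
        row_labels=labels,
        col_labels=["Number (%)"],
        counts=counts,
        percent_axis="fixed",
        fixed_denominators=np.full(len(labels), denom),
        rounding=rounding,
    )


def crosstab(
    items: Iterable,
    row_classifier: Callable,
    col_classifier: Callable,
    percent_axis: str = "row",
    row_order: Optional[Sequence] = None,
    col_order: Optional[Sequence] = None,
    title: str = "Crosstab",
    rounding: str = "half-away",
) -> AuditTable:
    """Two-way table of counts with percents along the configured axis.

    Items for which either classifier returns None are skipped.
    """
    items = list(items)
    pairs = []
    for item in items:
        r, c = row_classifier(item), col_classifier(item)
        if r is None or c is None:
            continue
        pairs.append((r, c))
    if not pairs:
        raise ValueError("empty axis: no classifiable items")
    if row_order is None:
        row_order = sorted({r for r, _ in pairs}, key=str)
    if col_order is None:
        col_order = sorted({c for _, c in pairs}, key=str)
    counts = np.zeros((len(row_order), len(col_order)), dtype=int)
    r_index = {r: i for i, r in enumerate(row_order)}
    c_index = {c: j for j, c in enumerate(col_order)}
    for r, c in pairs:
        if r in r_index and c in c_index:
            counts[r_index[r], c_index[c]] += 1
    return AuditTable(
        title=title,
        row_labels=[str(getattr(r, "value", r)) for r in row_order],
        col_labels=[str(getattr(c, "value", c)) for c in col_order],
        counts=counts,
        percent_axis=percent_axis,
        rounding=rounding,
    )
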