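"""Registry CSV schema, reading/writing, and run configuration.

Schema (one header row, UTF-8, comma-separated; empty cell = missing;
``followup_days`` uses the literal sentinel ``NA`` for endpoints with no
follow-up time-point; ``distribution_codes`` is semicolon-joined)::

    trial_id, n_a, mean_a, sd_a, se_a, ci_low_a, ci_high_a, ci_level_a,
    n_b, mean_b, sd_b, se_b, ci_low_b, ci_high_b, ci_level_b, total_sd,
    scale_worst, scale_best, is_prom, md_est, sd_est, rationale,
    power_target, alpha, followup_days, distribution_codes, ceiling_discussed

Unknown columns warn and are ignored; unknown rationale strings map to NONE
with a warning (the taxonomy is post hoc — be permissive at ingest).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, TextIO, Union

import yaml

from .records import (
    ArmSummary,
    ConfidenceInterval,
    DistributionCode,
    PowerCalculation,
    PromScale,
    RationaleCode,
    RecordRejection,
    TrialRecord,
    validate_record,
)

log = logging.getLogger("powergap.io")

FOLLOWUP_NA = "NA"

COLUMNS = [
    "trial_id",
    "n_a", "mean_a", "sd_a", "se_a", "ci_low_a", "ci_high_a", "ci_level_a",
    "n_b", "mean_b", "sd_b", "se_b", "ci_low_b", "ci_high_b", "ci_level_b",
    "total_sd",
    "scale_worst", "scale_best", "is_prom",
    "md_est", "sd_est", "rationale", "power_target", "alpha",
    "followup_days", "distribution_codes", "ceiling_discussed",
]

MANDATORY_COLUMNS = ["trial_id", "n_a", "mean_a", "n_b", "mean_b"]


class RegistryError(Exception):
    """Fatal registry problem: unreadable file or missing mandatory column."""


def _opt_float(cell: str) -> Optional[float]:
    cell = cell.strip()
    return float(cell) if cell else None


def _opt_int(cell: str) -> Optional[int]:
    cell = cell.strip()
    return int(float(cell)) if cell else None


def _bool(cell: str) -> bool:
    return cell.strip().lower() in {"1", "true", "yes", "y"}


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(float(value))  # shortest round-trippable decimal
    return str(value)


def _parse_arm(row: dict[str, str], suffix: str) -> ArmSummary:
    ci = None
    lo, hi = _opt_float(row.get(f"ci_low_{suffix}", "")), _opt_float(
        row.get(f"ci_high_{suffix}", "")
    )
    if lo is not None and hi is not None:
        level = _opt_float(row.get(f"ci_level_{suffix}", "")) or 0.95
        ci = ConfidenceInterval(lo, hi, level)
    return ArmSummary(
        n=_opt_int(row.get(f"n_{suffix}", "")),
        mean=_opt_float(row.get(f"mean_{suffix}", "")),
        sd=_opt_float(row.get(f"sd_{suffix}", "")),
        se=_opt_float(row.get(f"se_{suffix}", "")),
        ci=ci,
    )


def parse_row(row: dict[str, str]) -> TrialRecord:
    """Build an (unvalidated) TrialRecord from one CSV row."""
    scale = None
    worst, best = _opt_float(row.get("scale_worst", "")), _opt_float(
        row.get("scale_best", "")
    )
    if worst is not None and best is not None:
        scale = PromScale(worst, best, is_prom=_bool(row.get("is_prom", "")))

    power = None
    md_est = _opt_float(row.get("md_est", ""))
    if md_est is not None:
        rationale_raw = row.get("rationale", "").strip() or "NONE"
        try:
            rationale = RationaleCode(rationale_raw)
        except ValueError:
            log.warning("unknown rationale %r -> NONE", rationale_raw)
            rationale = RationaleCode.NONE
        power = PowerCalculation(
            md_est=md_est,
            sd_est=_opt_float(row.get("sd_est", "")),
            rationale=rationale,
            power_target=_opt_float(row.get("power_target", "")),
            alpha=_opt_float(row.get("alpha", "")),
        )

    fu_cell = row.get("followup_days", "").strip()
    followup = None if fu_cell in ("", FOLLOWUP_NA) else float(fu_cell)

    codes = []
    for token in row.get("distribution_codes", "").split(";"):
        token = token.strip()
        if not token:
            continue
        try:
            codes.append(DistributionCode(token))
        except ValueError:
            log.warning("unknown distribution code %r ignored", token)

    return TrialRecord(
        trial_id=row.get("trial_id", "").strip(),
        arm_a=_parse_arm(row, "a"),
        arm_b=_parse_arm(row, "b"),
        scale=scale,
        power=power,
        total_sd=_opt_float(row.get("total_sd", "")),
        followup_days=followup,
        distribution_codes=frozenset(codes),
        ceiling_discussed=_bool(row.get("ceiling_discussed", "")),
    )


def record_to_row(record: TrialRecord) -> dict[str, str]:
    row: dict[str, str] = {c: "" for c in COLUMNS}
    row["trial_id"] = record.trial_id
    for arm, sfx in ((record.arm_a, "a"), (record.arm_b, "b")):
        row[f"n_{sfx}"] = _fmt(arm.n)
        row[f"mean_{sfx}"] = _fmt(arm.mean)
        row[f"sd_{sfx}"] = _fmt(arm.sd)
        row[f"se_{sfx}"] = _fmt(arm.se)
        if arm.ci is not None:
            row[f"ci_low_{sfx}"] = _fmt(arm.ci.lower)
            row[f"ci_high_{sfx}"] = _fmt(arm.ci.upper)
            row[f"ci_level_{sfx}"] = _fmt(arm.ci.level)
    row["total_sd"] = _fmt(record.total_sd)
    if record.scale is not None:
        row["scale_worst"] = _fmt(record.scale.worst_score)
        row["scale_best"] = _fmt(record.scale.best_score)
        row["is_prom"] = _fmt(record.scale.is_prom)
    if record.power is not None:
        row["md_est"] = _fmt(record.power.md_est)
        row["sd_est"] = _fmt(record.power.sd_est)
        row["rationale"] = record.power.rationale.value
        row["power_target"] = _fmt(record.power.power_target)
        row["alpha"] = _fmt(record.power.alpha)
    row["followup_days"] = (
        FOLLOWUP_NA if record.followup_days is None else _fmt(record.followup_days)
    )
    row["distribution_codes"] = ";".join(
        sorted(code.value for code in record.distribution_codes)
    )
    row["ceiling_discussed"] = _fmt(record.ceiling_discussed)
    return row


def read_registry(
    path: Union[str, Path, TextIO],
) -> tuple[list[TrialRecord], list[RecordRejection]]:
    """Read a registry CSV; every row becomes a validated record or a logged
    rejection, in input order (rows = records + rejections, always)."""
    if hasattr(path, "read"):
        return _read_stream(path)  # type: ignore[arg-type]
    path = Path(path)
    if not path.exists():
        raise RegistryError(f"registry file not found: {path}")
    with path.open(newline="", encoding="utf-8") as fh:
        return _read_stream(fh)


def _read_stream(fh: TextIO) -> tuple[list[TrialRecord], list[RecordRejection]]:
    reader = csv.DictReader(fh)
    if reader.fieldnames is None:
        raise RegistryError("registry has no header row")
    missing = [c for c in MANDATORY_COLUMNS if c not in reader.fieldnames]
    if missing:
        raise RegistryError(f"mandatory column(s) missing: {', '.join(missing)}")
    unknown = [c for c in reader.fieldnames if c not in COLUMNS]
    if unknown:
        log.warning("unknown column(s) ignored: %s", ", ".join(unknown))

    records: list[TrialRecord] = []
    rejections: list[RecordRejection] = []
    for i, row in enumerate(reader):
        record = parse_row(row)
        if not record.trial_id:
            record = TrialRecord(
                trial_id=f"row{i + 2}", arm_a=record.arm_a, arm_b=record.arm_b,
                scale=record.scale, power=record.power, total_sd=record.total_sd,
                followup_days=record.followup_days,
                distribution_codes=record.distribution_codes,
                ceiling_discussed=record.ceiling_discussed,
            )
        result = validate_record(record)
        if isinstance(result, RecordRejection):
            log.warning("row %d (%s): rejected %s (%s)",
                        i + 2, result.trial_id, result.reason.value, result.detail)
            rejections.append(result)
        else:
            records.append(result)
    return records, rejections


def write_registry(records: Iterable[TrialRecord], path: Union[str, Path]) -> Path:
    """Write records to CSV; ``read_registry`` round-trips field-for-field."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=COLUMNS)
        writer.writeheader()
        for record in records:
            writer.writerow(record_to_row(record))
    return path


@dataclass
class RunConfig:
    """Run configuration (YAML/JSON): paths, crossover multiplier, rounding,
    follow-up binning scheme and the random seed."""

    input_path: Optional[str] = None
    output_dir: str = "out"
    k: float = 1.0
    rounding: str = "half-away"  # or "half-even"
    followup_scheme: str = "coarse"  # or "nine"
    seed: int = 0
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        extra = {k: v for k, v in raw.items() if k not in known}
        return cls(**kwargs, extra=extra)

    def to_yaml(self, path: Union[str, Path]) -> Path:
        path = Path(path)
        data = {
            "input_path": self.input_path,
            "output_dir": self.output_dir,
            "k": self.k,
            "rounding": self.rounding,
            "followup_scheme": self.followup_scheme,
            "seed": self.seed,
            **self.extra,
        }
        path.write_text(yaml.safe_dump(data, sort_keys=False))
        return path
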