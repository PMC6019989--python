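"""Registry data model: pregnancy records, gestational-age conventions, CSV I/O, validation.

Gestational age is handled everywhere in integer days since the last menstrual
period (LMP); "X weeks Y days" maps to ``7*X + Y`` days, and a week-labelled
window "a,0 - b,6 weeks" maps to the half-open day interval ``[7a, 7(b+1))``.
This convention makes boundaries such as "7 weeks 6 days" vs "8 weeks 0 days"
unambiguous at the day level.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, fields
from enum import Enum
from pathlib import Path
from typing import Iterator, Mapping, Optional, Sequence, Union

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

DAYS_PER_WEEK = 7
#: Gestational day at which a loss stops being a miscarriage and a delivery
#: with no signs of life becomes a stillbirth (20 completed weeks).
STILLBIRTH_MIN_GA_DAYS = 20 * DAYS_PER_WEEK


class Outcome(str, Enum):
    """Final outcome recorded for a pregnancy."""

    MISCARRIAGE = "MISCARRIAGE"
    MTP = "MTP"  # medically terminated pregnancy (elective, medical or surgical)
    STILLBIRTH = "STILLBIRTH"
    LIVEBIRTH = "LIVEBIRTH"


#: Outcomes that count as early pregnancy loss for risk-set bookkeeping.
LOSS_OUTCOMES = frozenset({Outcome.MISCARRIAGE, Outcome.MTP})


class Education(str, Enum):
    NONE = "NONE"
    PRIMARY = "PRIMARY"
    SECONDARY = "SECONDARY"
    UNIVERSITY_PLUS = "UNIVERSITY_PLUS"


class Attendant(str, Enum):
    PHYSICIAN = "PHYSICIAN"
    NURSE_MIDWIFE = "NURSE_MIDWIFE"
    TBA = "TBA"  # traditional birth attendant
    FAMILY_SELF_OTHER = "FAMILY_SELF_OTHER"


class Location(str, Enum):
    HOSPITAL = "HOSPITAL"
    CLINIC_HEALTH_CENTER = "CLINIC_HEALTH_CENTER"
    HOME_OTHER = "HOME_OTHER"


@dataclass(frozen=True, order=True)
class GAInterval:
    """Half-open gestational-age window ``[start_days, end_days)`` in days since LMP."""

    start_days: int
    end_days: int
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start_days < self.end_days):
            raise ValueError(
                f"invalid interval [{self.start_days}, {self.end_days}): "
                "need 0 <= start < end"
            )
        if not self.label:
            object.__setattr__(self, "label", self._week_label())

    def _week_label(self) -> str:
        sw, sd = divmod(self.start_days, DAYS_PER_WEEK)
        ew, ed = divmod(self.end_days - 1, DAYS_PER_WEEK)
        return f"{sw},{sd}-{ew},{ed} weeks"

    @classmethod
    def from_weeks(cls, start_week: int, end_week_inclusive: int) -> "GAInterval":
        """Window labelled "a,0 - b,6 weeks": days ``[7a, 7(b+1))``."""
        return cls(DAYS_PER_WEEK * start_week, DAYS_PER_WEEK * (end_week_inclusive + 1))

    def contains(self, ga_days: int) -> bool:
        return self.start_days <= ga_days < self.end_days


#: The three windows over which early-loss rates are estimated:
#: 6,0-7,6 / 8,0-11,6 / 12,0-19,6 weeks.
CANONICAL_INTERVALS: tuple[GAInterval, ...] = (
    GAInterval.from_weeks(6, 7),
    GAInterval.from_weeks(8, 11),
    GAInterval.from_weeks(12, 19),
)


@dataclass(frozen=True)
class PregnancyRecord:
    """One enrolled pregnancy.

    ``enroll_ga_days`` may be ``None`` for pregnancies with unknown enrollment
    gestational age (these are excluded from analysis by
    :func:`exclude_unknown_ga`). ``outcome_ga_days`` is ``None`` only if the
    pregnancy is still ongoing at the data cut.
    """

    woman_id: str
    cluster_id: str
    outcome: Optional[Outcome] = None
    enroll_ga_days: Optional[int] = None
    outcome_ga_days: Optional[int] = None
    neonatal_death_by_28d: Optional[bool] = None
    maternal_age_years: Optional[int] = None
    education: Optional[Education] = None
    parity: Optional[int] = None
    weight_kg: Optional[float] = None
    height_m: Optional[float] = None
    hemoglobin_g_dl: Optional[float] = None
    anc_visits: Optional[int] = None
    attendant: Optional[Attendant] = None
    location: Optional[Location] = None


#: Canonical CSV column order; also the attribute order of PregnancyRecord.
CANONICAL_COLUMNS: tuple[str, ...] = tuple(f.name for f in fields(PregnancyRecord))

#: Columns that must be resolvable in any input file.
REQUIRED_COLUMNS: frozenset = frozenset(
    {"woman_id", "cluster_id", "outcome", "enroll_ga_days", "outcome_ga_days"}
)

_ENUM_FIELDS = {
    "outcome": Outcome,
    "education": Education,
    "attendant": Attendant,
    "location": Location,
}
_INT_FIELDS = ("enroll_ga_days", "outcome_ga_days", "maternal_age_years", "parity", "anc_visits")
_FLOAT_FIELDS = ("weight_kg", "height_m", "hemoglobin_g_dl")


@dataclass(frozen=True)
class RowError:
    """One rejected input row: 1-based data row number and the reason."""

    row_number: int
    message: str


@dataclass
class ReadResult:
    """Outcome of :func:`read_registry`: parsed records plus a rejection report."""

    records: list[PregnancyRecord]
    rejections: list[RowError]

    def __iter__(self) -> Iterator[PregnancyRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _parse_cell(field_name: str, raw: str):
    raw = raw.strip()
    if raw == "":
        return None
    if field_name in _ENUM_FIELDS:
        try:
            return _ENUM_FIELDS[field_name](raw)
        except ValueError:
            raise ValueError(f"{field_name}: unknown category {raw!r}") from None
    if field_name in _INT_FIELDS:
        try:
            return int(raw)
        except ValueError:
            raise ValueError(f"{field_name}: not an integer: {raw!r}") from None
    if field_name in _FLOAT_FIELDS:
        try:
            return float(raw)
        except ValueError:
            raise ValueError(f"{field_name}: not a number: {raw!r}") from None
    if field_name == "neonatal_death_by_28d":
        low = raw.lower()
        if low in ("true", "1", "yes"):
            return True
        if low in ("false", "0", "no"):
            return False
        raise ValueError(f"neonatal_death_by_28d: not a boolean: {raw!r}")
    return raw  # opaque identifiers


def load_schema(schema: Union[None, Mapping[str, str], str, Path]) -> dict[str, str]:
    """Resolve a column-mapping config (canonical name -> file column name).

    Accepts a mapping, a YAML/JSON file path, or ``None`` (identity mapping).
    """
    if schema is None:
        return {}
    if isinstance(schema, Mapping):
        return dict(schema)
    path = Path(schema)
    text = path.read_text()
    if path.suffix in (".json",):
        return dict(json.loads(text))
    return dict(yaml.safe_load(text))


def read_registry(
    path: Union[str, Path],
    schema: Union[None, Mapping[str, str], str, Path] = None,
) -> ReadResult:
    """Read a registry CSV into records, collecting unparseable rows.

    Rows failing type coercion are reported in ``ReadResult.rejections`` with
    their 1-based data-row number rather than silently dropped. A missing file
    or a missing required column is fatal.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"registry file not found: {path}")
    mapping = load_schema(schema)

    records: list[PregnancyRecord] = []
    rejections: list[RowError] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"registry file has no header row: {path}")
        header = set(reader.fieldnames)
        colmap = {}
        for canonical in CANONICAL_COLUMNS:
            actual = mapping.get(canonical, canonical)
            if actual in header:
                colmap[canonical] = actual
            elif canonical in REQUIRED_COLUMNS:
                raise ValueError(f"required column missing from {path}: {actual!r}")
        for i, row in enumerate(reader, start=1):
            kwargs = {}
            try:
                for canonical, actual in colmap.items():
                    kwargs[canonical] = _parse_cell(canonical, row[actual] or "")
                if kwargs.get("woman_id") is None:
                    raise ValueError("woman_id: missing")
                records.append(PregnancyRecord(**kwargs))
            except ValueError as exc:
                rejections.append(RowError(i, str(exc)))
    logger.info("read %d records, rejected %d rows from %s", len(records), len(rejections), path)
    return ReadResult(records, rejections)


def write_registry(records: Sequence[PregnancyRecord], path: Union[str, Path]) -> None:
    """Write records as a canonical-column CSV re-readable by :func:`read_registry`."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CANONICAL_COLUMNS)
        for rec in records:
            row = []
            for col in CANONICAL_COLUMNS:
                val = getattr(rec, col)
                if val is None:
                    row.append("")
                elif isinstance(val, Enum):
                    row.append(val.value)
                elif isinstance(val, bool):
                    row.append("true" if val else "false")
                else:
                    row.append(val)
            writer.writerow(row)


def validate_record(record: PregnancyRecord) -> list[str]:
    """Check a record's invariants; return one descriptor per violation.

    Violations are data, not exceptions: each string names the offending field
    and the rule it breaks. An empty list means the record is internally
    consistent.
    """
    v: list[str] = []
    if record.enroll_ga_days is not None and record.enroll_ga_days < 0:
        v.append("enroll_ga_days: must be >= 0")
    if (
        record.outcome_ga_days is not None
        and record.enroll_ga_days is not None
        and record.outcome_ga_days < record.enroll_ga_days
    ):
        v.append("outcome_ga_days: earlier than enroll_ga_days")
    if record.outcome is not None and record.outcome_ga_days is None:
        v.append("outcome_ga_days: required when outcome is recorded")
    if record.outcome == Outcome.MISCARRIAGE and record.outcome_ga_days is not None:
        if record.outcome_ga_days >= STILLBIRTH_MIN_GA_DAYS:
            v.append(
                "outcome: miscarriage at/after 140 days (spontaneous loss at >= 20 weeks is a stillbirth)"
            )
    if record.outcome == Outcome.STILLBIRTH and record.outcome_ga_days is not None:
        if record.outcome_ga_days < STILLBIRTH_MIN_GA_DAYS:
            v.append("outcome: stillbirth before 140 days (must be >= 20 weeks)")
    if record.outcome == Outcome.LIVEBIRTH:
        if record.neonatal_death_by_28d is None:
            v.append("neonatal_death_by_28d: required for livebirths")
    elif record.neonatal_death_by_28d is not None:
        v.append("neonatal_death_by_28d: only defined for livebirths")
    if record.weight_kg is not None and record.weight_kg <= 0:
        v.append("weight_kg: must be positive")
    if record.height_m is not None and record.height_m <= 0:
        v.append("height_m: must be positive")
    if record.hemoglobin_g_dl is not None and record.hemoglobin_g_dl <= 0:
        v.append("hemoglobin_g_dl: must be positive")
    if record.parity is not None and record.parity < 0:
        v.append("parity: must be >= 0")
    if record.anc_visits is not None and record.anc_visits < 0:
        v.append("anc_visits: must be >= 0")
    return v


def exclude_unknown_ga(
    records: Sequence[PregnancyRecord],
) -> tuple[list[PregnancyRecord], int]:
    """Drop records with unknown enrollment GA or enrolled at pregnancy end.

    Mirrors the analysis funnel of a registry where women enrolling only at
    delivery contribute no time at risk. Returns ``(kept, n_excluded)``.
    """
    kept = [
        r
        for r in records
        if r.enroll_ga_days is not None
        and (r.outcome_ga_days is None or r.enroll_ga_days < r.outcome_ga_days)
    ]
    n_excluded = len(records) - len(kept)
    if n_excluded:
        logger.info("excluded %d of %d records with unknown/at-delivery enrollment GA",
                    n_excluded, len(records))
    return kept, n_excluded


def records_to_frame(records: Sequence[PregnancyRecord]) -> pd.DataFrame:
    """Tabular view of a record collection (enums as their string values)."""
    data = {col: [] for col in CANONICAL_COLUMNS}
    for rec in records:
        for col in CANONICAL_COLUMNS:
            val = getattr(rec, col)
            data[col].append(val.value if isinstance(val, Enum) else val)
    df = pd.DataFrame(data)
    for col in _INT_FIELDS:
        df[col] = df[col].astype("Int64")
    return df


def frame_to_records(df: pd.DataFrame) -> list[PregnancyRecord]:
    """Inverse of :func:`records_to_frame` for frames with canonical columns."""
    out = []
    for row in df.itertuples(index=False):
        kwargs = {}
        for col in CANONICAL_COLUMNS:
            val = getattr(row, col, None)
            if pd.isna(val):
                val = None
            elif col in _ENUM_FIELDS and val is not None:
                val = _ENUM_FIELDS[col](val)
            elif col in _INT_FIELDS and val is not None:
                val = int(val)
            kwargs[col] = val
        out.append(PregnancyRecord(**kwargs))
    return out
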