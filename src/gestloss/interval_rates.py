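"""Left-truncation-aware risk sets and per-1000 interval loss rates.

Enrollment is staggered: a woman contributes to the risk set of a
gestational-age window only if she enrolled strictly before the window opens
and had no recorded loss (miscarriage or MTP) before it. Within a window the
two loss types compete, and each type's denominator excludes women who
experienced the *other* loss type in that window — the convention under which
``miscarriage_denominator + MTPs_in_window = riskset_n`` (and symmetrically).

Stillbirths and livebirths never count as window losses; upstream validation
rejects deliveries mis-dated before 140 days.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .registry_model import (
    CANONICAL_INTERVALS,
    GAInterval,
    Outcome,
    PregnancyRecord,
    records_to_frame,
)

_LOSS_VALUES = (Outcome.MISCARRIAGE.value, Outcome.MTP.value)


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return records_to_frame(records)


@dataclass(frozen=True)
class RiskSet:
    """Women at risk in an interval: enrolled before it opens, no prior loss."""

    interval: GAInterval
    member_ids: frozenset
    n: int


@dataclass(frozen=True)
class IntervalRate:
    """One cell of the rate table: numerator, competing-exclusion denominator, rate."""

    interval: GAInterval
    event: Outcome
    numerator: int
    denominator: int
    rate_per_1000: float


def _membership_mask(df: pd.DataFrame, interval: GAInterval) -> np.ndarray:
    enroll = df["enroll_ga_days"].to_numpy(dtype=float, na_value=np.nan)
    out_ga = df["outcome_ga_days"].to_numpy(dtype=float, na_value=np.nan)
    is_loss = df["outcome"].isin(_LOSS_VALUES).to_numpy()
    enrolled_before = ~np.isnan(enroll) & (enroll < interval.start_days)
    lost_before = is_loss & ~np.isnan(out_ga) & (out_ga < interval.start_days)
    return enrolled_before & ~lost_before


def _event_mask(df: pd.DataFrame, interval: GAInterval, event: Outcome) -> np.ndarray:
    out_ga = df["outcome_ga_days"].to_numpy(dtype=float, na_value=np.nan)
    is_event = (df["outcome"] == event.value).to_numpy()
    return (
        is_event
        & ~np.isnan(out_ga)
        & (out_ga >= interval.start_days)
        & (out_ga < interval.end_days)
    )


def build_risk_set(records: Sequence[PregnancyRecord], interval: GAInterval) -> RiskSet:
    """Women enrolled strictly before ``interval.start_days`` without earlier loss.

    Ongoing pregnancies (no outcome yet) with early enough enrollment are
    included. An empty risk set is legal.
    """
    df = _as_frame(records)
    mask = _membership_mask(df, interval)
    ids = frozenset(df.loc[mask, "woman_id"])
    return RiskSet(interval=interval, member_ids=ids, n=int(mask.sum()))


def count_interval_events(
    records: Sequence[PregnancyRecord], interval: GAInterval, event: Outcome
) -> int:
    """Risk-set members whose ``event`` fell on a day in ``[start, end)``."""
    df = _as_frame(records)
    return int((_membership_mask(df, interval) & _event_mask(df, interval, event)).sum())


def interval_rate(
    records: Sequence[PregnancyRecord], interval: GAInterval, event: Outcome
) -> IntervalRate:
    """Per-1000 rate of ``event`` in ``interval`` with competing-event exclusion.

    The denominator is the risk-set size minus the count of the competing loss
    type in the same interval. Full precision is retained in ``rate_per_1000``;
    round to one decimal for display. A zero denominator raises rather than
    producing a silent NaN.
    """
    if event not in (Outcome.MISCARRIAGE, Outcome.MTP):
        raise ValueError(f"interval rates are defined for losses only, not {event}")
    df = _as_frame(records)
    membership = _membership_mask(df, interval)
    n_at_risk = int(membership.sum())
    if n_at_risk == 0:
        raise ValueError(f"empty risk set for {interval.label}")
    competing = Outcome.MTP if event == Outcome.MISCARRIAGE else Outcome.MISCARRIAGE
    numerator = int((membership & _event_mask(df, interval, event)).sum())
    n_competing = int((membership & _event_mask(df, interval, competing)).sum())
    denominator = n_at_risk - n_competing
    if denominator == 0:
        raise ValueError(
            f"zero denominator for {event.value} in {interval.label}: "
            f"all {n_at_risk} at-risk women had the competing event"
        )
    return IntervalRate(
        interval=interval,
        event=event,
        numerator=numerator,
        denominator=denominator,
        rate_per_1000=1000.0 * numerator / denominator,
    )


@dataclass(frozen=True)
class IntervalRateTable:
    """Per-interval, per-event numerators, denominators and per-1000 rates."""

    rows: tuple[IntervalRate, ...]

    def get(self, interval: GAInterval, event: Outcome) -> IntervalRate:
        for row in self.rows:
            if row.interval == interval and row.event == event:
                return row
        raise KeyError(f"no rate for {event.value} in {interval.label}")

    def rate(self, interval: GAInterval, event: Outcome) -> float:
        return self.get(interval, event).rate_per_1000

    @property
    def intervals(self) -> tuple[GAInterval, ...]:
        seen: list[GAInterval] = []
        for row in self.rows:
            if row.interval not in seen:
                seen.append(row.interval)
        return tuple(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "interval": [r.interval.label for r in self.rows],
                "start_days": [r.interval.start_days for r in self.rows],
                "end_days": [r.interval.end_days for r in self.rows],
                "event": [r.event.value for r in self.rows],
                "numerator": [r.numerator for r in self.rows],
                "denominator": [r.denominator for r in self.rows],
                "rate_per_1000": [round(r.rate_per_1000, 1) for r in self.rows],
            }
        )

    @classmethod
    def from_counts(
        cls,
        counts: Sequence[tuple[GAInterval, Outcome, int, int]],
    ) -> "IntervalRateTable":
        """Build a table directly from (interval, event, numerator, denominator).

        Useful when only published counts, not record-level data, are available.
        """
        rows = tuple(
            IntervalRate(interval, event, num, den, 1000.0 * num / den)
            for interval, event, num, den in counts
        )
        return cls(rows)


def rate_table(
    records: Sequence[PregnancyRecord],
    intervals: Sequence[GAInterval] = CANONICAL_INTERVALS,
) -> IntervalRateTable:
    """Miscarriage and MTP rates per 1000 ongoing pregnancies for each interval."""
    df = _as_frame(records)
    rows = []
    for interval in intervals:
        for event in (Outcome.MISCARRIAGE, Outcome.MTP):
            rows.append(interval_rate(df, interval, event))
    return IntervalRateTable(tuple(rows))
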