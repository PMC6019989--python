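"""Antenatal-care and obstetric summaries by outcome group.

Women are grouped as miscarriage, MTP, or ongoing pregnancy at 20 weeks (the
latter includes everyone whose pregnancy reached 140 days, i.e. stillbirths
and livebirths, whose delivery attendant/location populate that column).
Terminations recorded after 20 weeks sit in the MTP column by default; this
is configurable since registries differ on the convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import pandas as pd

from .registry_model import (
    Attendant,
    Location,
    Outcome,
    PregnancyRecord,
    STILLBIRTH_MIN_GA_DAYS,
)
from .interval_rates import _as_frame

MISCARRIAGE_GROUP = "MISCARRIAGE"
MTP_GROUP = "MTP"
ONGOING_GROUP = "ONGOING_20W"
GROUPS = (MISCARRIAGE_GROUP, MTP_GROUP, ONGOING_GROUP)


def assign_outcome_group(
    record: PregnancyRecord,
    post20_mtp_group: Literal["MTP", "ONGOING_20W"] = MTP_GROUP,
) -> Optional[str]:
    """Classify one record; ``None`` for records that fit no group.

    Losses before 140 days go to their loss group; pregnancies that reached
    140 days (stillbirth or livebirth) count as ongoing at 20 weeks. Records
    with no outcome recorded yet cannot be classified.
    """
    if record.outcome is None or record.outcome_ga_days is None:
        return None
    day = record.outcome_ga_days
    if record.outcome == Outcome.MISCARRIAGE:
        return MISCARRIAGE_GROUP if day < STILLBIRTH_MIN_GA_DAYS else None
    if record.outcome == Outcome.MTP:
        if day < STILLBIRTH_MIN_GA_DAYS:
            return MTP_GROUP
        return post20_mtp_group
    return ONGOING_GROUP  # stillbirth or livebirth: pregnancy reached 20 weeks


@dataclass(frozen=True)
class OutcomeGroupSummary:
    """One column of the care-descriptives table, percentages to one decimal."""

    group: str
    n: int
    pct_any_anc: Optional[float]
    anc_band_pct: dict[str, float]  # bands "0", "1-2", ">2"
    attendant_pct: dict[str, float]
    location_pct: dict[str, float]


def _pct_block(series: pd.Series, categories: Sequence[str]) -> dict[str, float]:
    valid = series.dropna()
    if len(valid) == 0:
        return {c: float("nan") for c in categories}
    counts = valid.value_counts()
    return {c: round(100.0 * counts.get(c, 0) / len(valid), 1) for c in categories}


def summarize_groups(
    records: Sequence[PregnancyRecord],
    post20_mtp_group: Literal["MTP", "ONGOING_20W"] = MTP_GROUP,
) -> list[OutcomeGroupSummary]:
    """Per-group ANC-visit, attendant and location percentage blocks.

    Unclassifiable records (no outcome yet) are excluded from every group but
    never silently lost: they are reported as a residual ``UNCLASSIFIED``
    summary with ``n`` only.
    """
    df = _as_frame(records).copy()
    out_ga = df["outcome_ga_days"].astype(float)
    group = pd.Series(pd.NA, index=df.index, dtype="object")
    has_outcome = df["outcome"].notna() & out_ga.notna()
    group[has_outcome & (df["outcome"] == Outcome.MISCARRIAGE.value)
          & (out_ga < STILLBIRTH_MIN_GA_DAYS)] = MISCARRIAGE_GROUP
    pre20_mtp = has_outcome & (df["outcome"] == Outcome.MTP.value) & (out_ga < STILLBIRTH_MIN_GA_DAYS)
    post20_mtp = has_outcome & (df["outcome"] == Outcome.MTP.value) & (out_ga >= STILLBIRTH_MIN_GA_DAYS)
    group[pre20_mtp] = MTP_GROUP
    group[post20_mtp] = post20_mtp_group
    group[has_outcome & df["outcome"].isin((Outcome.STILLBIRTH.value, Outcome.LIVEBIRTH.value))] = ONGOING_GROUP

    anc = df["anc_visits"].astype(float)
    anc_band = pd.Series(pd.NA, index=df.index, dtype="object")
    anc_band[anc == 0] = "0"
    anc_band[(anc >= 1) & (anc <= 2)] = "1-2"
    anc_band[anc > 2] = ">2"

    summaries = []
    for g in GROUPS:
        sub = df[group == g]
        n = len(sub)
        anc_sub = anc[group == g].dropna()
        pct_any = round(100.0 * (anc_sub >= 1).mean(), 1) if len(anc_sub) else None
        summaries.append(
            OutcomeGroupSummary(
                group=g,
                n=n,
                pct_any_anc=pct_any,
                anc_band_pct=_pct_block(anc_band[group == g], ("0", "1-2", ">2")),
                attendant_pct=_pct_block(sub["attendant"], [a.value for a in Attendant]),
                location_pct=_pct_block(sub["location"], [l.value for l in Location]),
            )
        )
    n_unclassified = int(group.isna().sum())
    if n_unclassified:
        summaries.append(
            OutcomeGroupSummary(
                group="UNCLASSIFIED", n=n_unclassified, pct_any_anc=None,
                anc_band_pct={}, attendant_pct={}, location_pct={},
            )
        )
    return summaries


def summaries_to_frame(summaries: Sequence[OutcomeGroupSummary]) -> pd.DataFrame:
    """Wide rendering: one column per group, one row per statistic."""
    rows: dict[str, dict[str, object]] = {}

    def put(row: str, group: str, value) -> None:
        rows.setdefault(row, {})[group] = value

    for s in summaries:
        put("n", s.group, s.n)
        put("any_anc_pct", s.group, s.pct_any_anc)
        for band, v in s.anc_band_pct.items():
            put(f"anc_{band}_pct", s.group, v)
        for cat, v in s.attendant_pct.items():
            put(f"attendant_{cat}_pct", s.group, v)
        for cat, v in s.location_pct.items():
            put(f"location_{cat}_pct", s.group, v)
    return pd.DataFrame(rows).T
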