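"""Multiple-decrement projection of a hypothetical cohort of ongoing pregnancies.

A closed cohort (by default 1000 pregnancies ongoing at 6 weeks) is walked
through the three early gestational-age windows, removing miscarriages and
MTPs at each step using that window's per-1000 rates, then through an absolute
post-20-week MTP count, a stillbirth decrement, and a 28-day neonatal-death
decrement, ending with the number of infants alive at 28 days.

Within a window both decrements are computed simultaneously from the same
entering count (not sequentially), and counts are rounded to whole pregnancies
under a configurable policy. Published flow figures of this kind round each
cell independently, so cumulative counts under any single consistent policy
can differ from a printed figure by one pregnancy; the ``rounding="none"``
mode keeps full precision and satisfies the exact product-survival identity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence, Union

import pandas as pd

from .registry_model import CANONICAL_INTERVALS, GAInterval, Outcome
from .interval_rates import IntervalRateTable

RoundingPolicy = Literal["nearest", "floor", "none"]

#: Sentinel step labels for the perinatal tail of the projection.
POST_20_MTP = "POST_20_MTP"
STILLBIRTH_STEP = "STILLBIRTH"
NEONATAL_STEP = "NEONATAL"

Count = Union[int, float]


def _apply(x: float, policy: RoundingPolicy) -> Count:
    if policy == "nearest":  # half away from zero, matching whole-pregnancy tallies
        return math.floor(x + 0.5)
    if policy == "floor":
        return math.floor(x)
    if policy == "none":
        return x
    raise ValueError(f"unknown rounding policy: {policy!r}")


@dataclass(frozen=True)
class DecrementStep:
    """One decrement of the cohort: entering count, losses, exiting count."""

    label: str
    entering: Count
    miscarriages: Count = 0
    mtps: Count = 0
    stillbirths: Count = 0
    neonatal_deaths: Count = 0

    @property
    def decrements(self) -> Count:
        return self.miscarriages + self.mtps + self.stillbirths + self.neonatal_deaths

    @property
    def exiting(self) -> Count:
        return self.entering - self.decrements


@dataclass(frozen=True)
class PerinatalRates:
    """Stillbirth and 28-day neonatal mortality rates plus post-20-week MTP count.

    ``post20_mtp_count`` is an absolute number of terminations after 20 weeks,
    not a rate.
    """

    stillbirth_per_1000: float
    nmr_per_1000: float
    post20_mtp_count: int = 0

    def __post_init__(self) -> None:
        for name in ("stillbirth_per_1000", "nmr_per_1000"):
            val = getattr(self, name)
            if not (0 <= val <= 1000):
                raise ValueError(f"{name} must lie in [0, 1000], got {val}")


@dataclass(frozen=True)
class CohortProjection:
    """Chained decrement steps; ``alive_at_28d`` is set once the perinatal tail runs."""

    initial_n: Count
    steps: tuple[DecrementStep, ...]
    alive_at_28d: Optional[Count] = None

    @property
    def ongoing(self) -> Count:
        """Cohort size after the last step so far."""
        return self.steps[-1].exiting if self.steps else self.initial_n

    def step(self, label: str) -> DecrementStep:
        for s in self.steps:
            if s.label == label:
                return s
        raise KeyError(f"no step labelled {label!r}")


def project_interval(
    entering: Count,
    misc_rate_per_1000: float,
    mtp_rate_per_1000: float,
    rounding: RoundingPolicy = "nearest",
    label: str = "",
) -> DecrementStep:
    """Apply one window's miscarriage and MTP rates to the entering count.

    Both decrements are taken from the same entering count; the step errors
    out rather than let rounded decrements exceed it.
    """
    if entering < 0:
        raise ValueError("entering count must be >= 0")
    for name, rate in (("miscarriage", misc_rate_per_1000), ("MTP", mtp_rate_per_1000)):
        if not (0 <= rate <= 1000):
            raise ValueError(f"{name} rate must lie in [0, 1000] per 1000, got {rate}")
    misc = _apply(entering * misc_rate_per_1000 / 1000.0, rounding)
    mtps = _apply(entering * mtp_rate_per_1000 / 1000.0, rounding)
    if misc + mtps > entering:
        raise ValueError(
            f"decrements ({misc} + {mtps}) exceed entering count {entering}"
        )
    return DecrementStep(label=label, entering=entering, miscarriages=misc, mtps=mtps)


def project_cohort(
    rates: IntervalRateTable,
    initial_n: Count = 1000,
    rounding: RoundingPolicy = "nearest",
    intervals: Sequence[GAInterval] = CANONICAL_INTERVALS,
) -> CohortProjection:
    """Project the cohort through the early-loss windows (through 20 weeks).

    Each step applies the corresponding interval's miscarriage and MTP rates
    from ``rates``; a missing interval is fatal.
    """
    steps: list[DecrementStep] = []
    entering: Count = initial_n
    for interval in intervals:
        try:
            misc_rate = rates.rate(interval, Outcome.MISCARRIAGE)
            mtp_rate = rates.rate(interval, Outcome.MTP)
        except KeyError as exc:
            raise ValueError(f"rate table lacks interval {interval.label}") from exc
        step = project_interval(entering, misc_rate, mtp_rate, rounding, label=interval.label)
        steps.append(step)
        entering = step.exiting
    return CohortProjection(initial_n=initial_n, steps=tuple(steps))


def extend_perinatal(
    projection: CohortProjection,
    perinatal: PerinatalRates,
    rounding: RoundingPolicy = "nearest",
) -> CohortProjection:
    """Carry the 20-week survivors through post-20-week MTP, stillbirth and
    neonatal-death decrements to infants alive at 28 days."""
    if projection.alive_at_28d is not None:
        raise ValueError("projection already extended through the perinatal stage")
    entering = projection.ongoing
    if perinatal.post20_mtp_count > entering:
        raise ValueError("post-20-week MTP count exceeds ongoing pregnancies")
    mtp_step = DecrementStep(POST_20_MTP, entering, mtps=perinatal.post20_mtp_count)

    remaining = mtp_step.exiting
    stillbirths = _apply(remaining * perinatal.stillbirth_per_1000 / 1000.0, rounding)
    if stillbirths > remaining:
        raise ValueError("stillbirth decrement exceeds remaining pregnancies")
    sb_step = DecrementStep(STILLBIRTH_STEP, remaining, stillbirths=stillbirths)

    live = sb_step.exiting
    neonatal = _apply(live * perinatal.nmr_per_1000 / 1000.0, rounding)
    if neonatal > live:
        raise ValueError("neonatal-death decrement exceeds live births")
    nn_step = DecrementStep(NEONATAL_STEP, live, neonatal_deaths=neonatal)

    return CohortProjection(
        initial_n=projection.initial_n,
        steps=projection.steps + (mtp_step, sb_step, nn_step),
        alive_at_28d=nn_step.exiting,
    )


def render_projection(projection: CohortProjection) -> pd.DataFrame:
    """Flow report: one row per step with entering/decrement/exiting columns.

    Rendered counts conserve the cohort: the final exiting count plus every
    decrement re-sums to ``initial_n``.
    """
    rows = [
        {
            "step": s.label,
            "entering": s.entering,
            "miscarriages": s.miscarriages,
            "mtps": s.mtps,
            "stillbirths": s.stillbirths,
            "neonatal_deaths": s.neonatal_deaths,
            "exiting": s.exiting,
        }
        for s in projection.steps
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "step",
            "entering",
            "miscarriages",
            "mtps",
            "stillbirths",
            "neonatal_deaths",
            "exiting",
        ],
    )
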