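"""Synthetic pregnancy registries with known ground truth.

The generator emulates the statistical structure a prospective,
population-based pregnancy registry analysis assumes: staggered enrollment
across gestational-age bands, interval-specific competing miscarriage/MTP
hazards, multiplicative covariate effects on loss risk, cluster-level
heterogeneity on the log-risk scale, and perinatal (stillbirth /
28-day-neonatal-death) outcomes for pregnancies reaching 20 weeks. Every
planted quantity is recorded so estimator tests can compare against truth.

Calibration notes
-----------------
Configured per-interval per-1000 rates are interpreted as the estimand of the
competing-exclusion estimator: for target miscarriage fraction ``a`` and MTP
fraction ``b`` in a window, the per-woman categorical probabilities are
``q_m = a(1-b)/(1-ab)`` and ``q_t = b(1-a)/(1-ab)``, which makes the
denominator-exclusion ratio equal ``a`` (resp. ``b``) in expectation.
Cluster intercepts are centred multiplicatively (``exp(b_j - sd^2/2)``) so the
marginal rate is unbiased for the configured target. Women whose simulated
loss predates their simulated enrollment never enter the registry and are
re-drawn, reproducing the observation that very early losses may never enrol.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .registry_model import (
    CANONICAL_INTERVALS,
    Attendant,
    Education,
    GAInterval,
    Location,
    Outcome,
    PregnancyRecord,
)
from .interval_rates import IntervalRate

#: Enrollment-GA bands (days) matching the <6w / 6-8w / 8-12w / 12-20w / >=20w
#: description of registry enrollment timing.
ENROLLMENT_BANDS: tuple[tuple[int, int], ...] = (
    (28, 42),
    (42, 56),
    (56, 84),
    (84, 140),
    (140, 190),
)

_EDUCATION_LEVELS = tuple(e.value for e in Education)
_ATTENDANTS = tuple(a.value for a in Attendant)
_LOCATIONS = tuple(l.value for l in Location)

# Care-descriptor distributions by outcome group, shaped like a rural
# South-Asian registry: losses mostly unattended at home for miscarriage,
# facility-based for MTP, facility deliveries for ongoing pregnancies.
_DEFAULT_ANC_BANDS = {
    "MISCARRIAGE": (0.061, 0.930, 0.009),  # 0 / 1-2 / >2 visits
    "MTP": (0.048, 0.914, 0.038),
    "ONGOING": (0.0, 0.052, 0.948),
}
_DEFAULT_ATTENDANT = {
    "MISCARRIAGE": (0.026, 0.007, 0.001, 0.966),
    "MTP": (0.848, 0.012, 0.007, 0.133),
    "ONGOING": (0.611, 0.358, 0.004, 0.027),
}
_DEFAULT_LOCATION = {
    "MISCARRIAGE": (0.028, 0.009, 0.963),
    "MTP": (0.696, 0.097, 0.207),
    "ONGOING": (0.713, 0.243, 0.044),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for a synthetic registry.

    Defaults reproduce the structure of a large prospective rural registry:
    ~9.2% of women enrolled before 6 weeks, 28.9% at 6-8 weeks, 36.4% at
    8-12 weeks, 19.9% at 12-20 weeks and 5.6% at or after 20 weeks; interval
    loss rates of 115.3/101.9/60.3 per 1000 for miscarriage and
    45.4/48.3/40.2 per 1000 for MTP; stillbirth 26/1000 and 28-day neonatal
    mortality 24/1000 among 20-week survivors; and 2.2% of records missing
    enrollment gestational age.

    ``rr_miscarriage`` / ``rr_mtp`` plant multiplicative covariate effects,
    keyed ``"factor:level"`` (e.g. ``{"age_cat:GT30": 2.19}``); unlisted
    levels have effect 1. ``cluster_sd`` is the SD of cluster log-risk
    intercepts shared by both loss types.
    """

    n_women: int = 30_000
    n_clusters: int = 20
    enrollment_dist: tuple[float, ...] = (0.092, 0.289, 0.364, 0.199, 0.056)
    misc_rates_per_1000: tuple[float, ...] = (115.3, 101.9, 60.3)
    mtp_rates_per_1000: tuple[float, ...] = (45.4, 48.3, 40.2)
    rr_miscarriage: dict[str, float] = field(default_factory=dict)
    rr_mtp: dict[str, float] = field(default_factory=dict)
    cluster_sd: float = 0.15
    sb_per_1000: float = 26.0
    nmr_per_1000: float = 24.0
    post20_mtp_per_1000: float = 3.1
    missing_ga_frac: float = 0.022
    hb_missing_frac: float = 0.03
    # covariate marginals
    age_band_probs: tuple[float, ...] = (0.25, 0.45, 0.22, 0.08)
    education_probs: tuple[float, ...] = (0.15, 0.25, 0.50, 0.10)
    parity_probs: tuple[float, ...] = (0.35, 0.35, 0.20, 0.07, 0.03)
    bmi_mean: float = 20.5
    bmi_sd: float = 3.0
    height_mean_m: float = 1.56
    height_sd_m: float = 0.06
    hb_mean: float = 10.8
    hb_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if abs(sum(self.enrollment_dist) - 1.0) > 1e-9:
            raise ValueError("enrollment_dist must sum to 1")
        for name in ("misc_rates_per_1000", "mtp_rates_per_1000"):
            for r in getattr(self, name):
                if not (0 <= r <= 1000):
                    raise ValueError(f"{name}: rate {r} outside [0, 1000]")


_AGE_BANDS = ((17, 20), (21, 25), (26, 30), (31, 40))
_AGE_CATS = ("LE20", "A21_25", "A26_30", "GT30")


@dataclass
class GroundTruth:
    """Per-woman planted values and the cluster effects used to generate them."""

    women: pd.DataFrame
    cluster_effects: np.ndarray
    config: GeneratorConfig


def _competing_probs(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-woman (miscarriage, MTP) categorical probabilities whose
    denominator-exclusion ratios equal the targets ``a`` and ``b``."""
    denom = 1.0 - a * b
    return a * (1.0 - b) / denom, b * (1.0 - a) / denom


def _rr_multiplier(cats: dict[str, np.ndarray], rr: dict[str, float], m: int) -> np.ndarray:
    out = np.ones(m)
    for key, mult in rr.items():
        factor, level = key.split(":", 1)
        if factor not in cats:
            raise ValueError(f"unknown covariate factor in effect key {key!r}")
        out[cats[factor] == level] *= mult
    return out


def _draw_batch(rng: np.random.Generator, cfg: GeneratorConfig, m: int,
                cluster_frailty: np.ndarray) -> dict[str, np.ndarray]:
    cluster = rng.integers(0, cfg.n_clusters, size=m)

    age_band = rng.choice(len(_AGE_BANDS), size=m, p=cfg.age_band_probs)
    lo = np.array([b[0] for b in _AGE_BANDS])[age_band]
    hi = np.array([b[1] for b in _AGE_BANDS])[age_band]
    age = lo + np.floor(rng.random(m) * (hi - lo + 1)).astype(int)

    education = np.array(_EDUCATION_LEVELS)[
        rng.choice(len(_EDUCATION_LEVELS), size=m, p=cfg.education_probs)
    ]
    parity = rng.choice(len(cfg.parity_probs), size=m, p=cfg.parity_probs)

    height = np.clip(rng.normal(cfg.height_mean_m, cfg.height_sd_m, m), 1.35, 1.85).round(2)
    bmi = np.clip(rng.normal(cfg.bmi_mean, cfg.bmi_sd, m), 14.0, 35.0)
    weight = (bmi * height**2).round(1)
    hb = np.clip(rng.normal(cfg.hb_mean, cfg.hb_sd, m), 5.0, 16.0).round(1)
    hb_missing = rng.random(m) < cfg.hb_missing_frac

    band = rng.choice(len(ENROLLMENT_BANDS), size=m, p=cfg.enrollment_dist)
    blo = np.array([b[0] for b in ENROLLMENT_BANDS])[band]
    bhi = np.array([b[1] for b in ENROLLMENT_BANDS])[band]
    enroll = blo + np.floor(rng.random(m) * (bhi - blo)).astype(int)

    # categories for effect multipliers (from the values that will be emitted)
    bmi_emitted = weight / height**2
    cats = {
        "age_cat": np.array(_AGE_CATS)[age_band],
        "education_cat": education,
        "parity_cat": np.where(parity == 0, "P0", np.where(parity <= 2, "P1_2", "GT2")),
        "bmi_cat": np.where(
            bmi_emitted < 18.5, "UNDER_18_5",
            np.where(bmi_emitted <= 25.0, "NORMAL_18_5_25", "OVER_25"),
        ),
        "hb_cat": np.where(
            hb_missing, "MISSING",
            np.where(hb <= 9.0, "SEV_MOD_LE9", np.where(hb <= 11.0, "MILD_9_11", "NORMAL_GT11")),
        ),
    }
    rr_m = _rr_multiplier(cats, cfg.rr_miscarriage, m)
    rr_t = _rr_multiplier(cats, cfg.rr_mtp, m)
    frailty = cluster_frailty[cluster]

    outcome = np.full(m, "", dtype=object)
    outcome_day = np.full(m, -1, dtype=int)
    ongoing = np.ones(m, dtype=bool)
    for k, interval in enumerate(CANONICAL_INTERVALS):
        a = cfg.misc_rates_per_1000[k] / 1000.0 * rr_m * frailty
        b = cfg.mtp_rates_per_1000[k] / 1000.0 * rr_t * frailty
        bad = (a >= 1.0) | (b >= 1.0)
        if np.any(bad):
            i = int(np.argmax(bad))
            levels = {f: str(cats[f][i]) for f in cats}
            raise ValueError(
                f"covariate/cluster effects push loss probability >= 1 in "
                f"{interval.label} for covariate profile {levels}"
            )
        q_m, q_t = _competing_probs(a, b)
        if np.any(q_m + q_t >= 1.0):
            i = int(np.argmax(q_m + q_t >= 1.0))
            levels = {f: str(cats[f][i]) for f in cats}
            raise ValueError(
                f"combined loss probability >= 1 in {interval.label} "
                f"for covariate profile {levels}"
            )
        u = rng.random(m)
        day = interval.start_days + np.floor(
            rng.random(m) * (interval.end_days - interval.start_days)
        ).astype(int)
        misc_hit = ongoing & (u < q_m)
        mtp_hit = ongoing & (u >= q_m) & (u < q_m + q_t)
        outcome[misc_hit] = Outcome.MISCARRIAGE.value
        outcome[mtp_hit] = Outcome.MTP.value
        outcome_day[misc_hit | mtp_hit] = day[misc_hit | mtp_hit]
        ongoing &= ~(misc_hit | mtp_hit)

    # perinatal stage for 20-week survivors: post-20-week MTP, stillbirth, livebirth
    u_p20 = rng.random(m)
    p20_day = 140 + np.floor(rng.random(m) * 21).astype(int)
    u_sb = rng.random(m)
    sb_day = 140 + np.floor(rng.random(m) * 154).astype(int)
    lb_day = np.clip(np.rint(rng.normal(273.0, 10.0, m)), 197, 300).astype(int)
    u_nn = rng.random(m)

    p20_hit = ongoing & (u_p20 < cfg.post20_mtp_per_1000 / 1000.0)
    outcome[p20_hit] = Outcome.MTP.value
    outcome_day[p20_hit] = p20_day[p20_hit]
    ongoing &= ~p20_hit

    sb_hit = ongoing & (u_sb < cfg.sb_per_1000 / 1000.0)
    outcome[sb_hit] = Outcome.STILLBIRTH.value
    outcome_day[sb_hit] = sb_day[sb_hit]
    ongoing &= ~sb_hit

    outcome[ongoing] = Outcome.LIVEBIRTH.value
    outcome_day[ongoing] = lb_day[ongoing]
    neonatal = np.where(ongoing, u_nn < cfg.nmr_per_1000 / 1000.0, False)

    return {
        "cluster": cluster,
        "age": age,
        "education": education,
        "parity": parity,
        "height": height,
        "weight": weight,
        "hb": hb,
        "hb_missing": hb_missing,
        "enroll": enroll,
        "outcome": outcome,
        "outcome_day": outcome_day,
        "neonatal": neonatal,
        "rr_m": rr_m,
        "rr_t": rr_t,
        **{f"cat_{k}": v for k, v in cats.items()},
    }


def generate(
    config: GeneratorConfig, seed: Optional[int] = None
) -> tuple[list[PregnancyRecord], GroundTruth]:
    """Generate a registry and its ground truth; reproducible given (config, seed).

    Women whose simulated loss falls before their simulated enrollment day are
    re-drawn (they would never have entered the registry), keeping ``n_women``
    enrolled records. A fraction ``missing_ga_frac`` of emitted records then
    have their enrollment GA blanked.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    n = config.n_women
    cluster_effects = rng.normal(0.0, config.cluster_sd, config.n_clusters)
    # multiplicative frailty centred to realized mean 1: calibrates planted rates
    # within each realization; ratios between clusters (the RR structure) are
    # unchanged by the common rescaling
    cluster_frailty = np.exp(cluster_effects)
    cluster_frailty /= cluster_frailty.mean()

    columns: dict[str, np.ndarray] = {}
    pending = np.arange(n)
    for _ in range(1000):
        if len(pending) == 0:
            break
        batch = _draw_batch(rng, config, len(pending), cluster_frailty)
        # strictly after enrollment: women losing or delivering on their
        # enrollment day never enter the analysis registry
        valid = batch["outcome_day"] > batch["enroll"]
        if not columns:
            columns = {k: np.empty(n, dtype=v.dtype) for k, v in batch.items()}
        take = pending[valid]
        for k, v in batch.items():
            columns[k][take] = v[valid]
        pending = pending[~valid]
    else:
        raise RuntimeError("generator failed to produce enough enrolled pregnancies")

    if n == 0:
        columns = {k: np.empty(0) for k in ("cluster", "enroll", "outcome", "outcome_day")}

    ga_missing = rng.random(n) < config.missing_ga_frac if n else np.zeros(0, bool)

    # care descriptors drawn by outcome group
    outcome = columns["outcome"] if n else np.empty(0, object)
    group = np.where(
        outcome == Outcome.MISCARRIAGE.value, "MISCARRIAGE",
        np.where(outcome == Outcome.MTP.value, "MTP", "ONGOING"),
    )
    anc_visits = np.zeros(n, dtype=int)
    attendant = np.empty(n, dtype=object)
    location = np.empty(n, dtype=object)
    u_band = rng.random(n)
    extra = rng.poisson(1.5, n)
    one_or_two = 1 + (rng.random(n) < 0.5).astype(int)
    u_att = rng.random(n)
    u_loc = rng.random(n)
    for g in ("MISCARRIAGE", "MTP", "ONGOING"):
        mask = group == g
        if not mask.any():
            continue
        cb = np.cumsum(_DEFAULT_ANC_BANDS[g])
        band_idx = np.searchsorted(cb, u_band[mask], side="right")
        visits = np.where(band_idx == 0, 0, np.where(band_idx == 1, one_or_two[mask], 3 + extra[mask]))
        anc_visits[mask] = visits
        att_idx = np.searchsorted(np.cumsum(_DEFAULT_ATTENDANT[g]), u_att[mask], side="right")
        attendant[mask] = np.array(_ATTENDANTS)[np.clip(att_idx, 0, 3)]
        loc_idx = np.searchsorted(np.cumsum(_DEFAULT_LOCATION[g]), u_loc[mask], side="right")
        location[mask] = np.array(_LOCATIONS)[np.clip(loc_idx, 0, 2)]

    id_width = max(6, len(str(max(n, 1))))
    records: list[PregnancyRecord] = []
    for i in range(n):
        out = Outcome(columns["outcome"][i])
        records.append(
            PregnancyRecord(
                woman_id=f"W{i + 1:0{id_width}d}",
                cluster_id=f"C{columns['cluster'][i] + 1:03d}",
                outcome=out,
                enroll_ga_days=None if ga_missing[i] else int(columns["enroll"][i]),
                outcome_ga_days=int(columns["outcome_day"][i]),
                neonatal_death_by_28d=bool(columns["neonatal"][i]) if out == Outcome.LIVEBIRTH else None,
                maternal_age_years=int(columns["age"][i]),
                education=Education(columns["education"][i]),
                parity=int(columns["parity"][i]),
                weight_kg=float(columns["weight"][i]),
                height_m=float(columns["height"][i]),
                hemoglobin_g_dl=None if columns["hb_missing"][i] else float(columns["hb"][i]),
                anc_visits=int(anc_visits[i]),
                attendant=Attendant(attendant[i]),
                location=Location(location[i]),
            )
        )

    truth_df = pd.DataFrame(
        {
            "woman_id": [r.woman_id for r in records],
            "cluster": columns["cluster"][:n] if n else [],
            "cluster_effect": cluster_effects[columns["cluster"]] if n else [],
            "enroll_ga_days": columns["enroll"][:n] if n else [],
            "ga_missing": ga_missing,
            "outcome": columns["outcome"][:n] if n else [],
            "outcome_ga_days": columns["outcome_day"][:n] if n else [],
            "rr_miscarriage": columns.get("rr_m", np.empty(0)),
            "rr_mtp": columns.get("rr_t", np.empty(0)),
            **{
                f: columns.get(f"cat_{f}", np.empty(0, object))
                for f in ("age_cat", "education_cat", "parity_cat", "bmi_cat", "hb_cat")
            },
        }
    )
    return records, GroundTruth(women=truth_df, cluster_effects=cluster_effects, config=config)


def truth_rate(truth: GroundTruth, interval: GAInterval, event: Outcome) -> IntervalRate:
    """Realized per-1000 rate from planted values, using the same left-truncated
    risk set and competing-exclusion denominator as the estimator.

    Computed directly from the ground-truth table (missing-GA women excluded,
    as the estimator cannot see them), so it must agree exactly with the rate
    estimated from the emitted records.
    """
    df = truth.women
    enroll = df["enroll_ga_days"].to_numpy(float)
    day = df["outcome_ga_days"].to_numpy(float)
    out = df["outcome"].to_numpy()
    visible = ~df["ga_missing"].to_numpy(bool)
    is_loss = (out == Outcome.MISCARRIAGE.value) | (out == Outcome.MTP.value)
    member = visible & (enroll < interval.start_days) & ~(is_loss & (day < interval.start_days))
    in_window = (day >= interval.start_days) & (day < interval.end_days)
    n_event = int((member & (out == event.value) & in_window).sum())
    competing = Outcome.MTP if event == Outcome.MISCARRIAGE else Outcome.MISCARRIAGE
    n_competing = int((member & (out == competing.value) & in_window).sum())
    denominator = int(member.sum()) - n_competing
    if denominator == 0:
        raise ValueError(f"zero truth denominator for {event.value} in {interval.label}")
    return IntervalRate(
        interval=interval,
        event=event,
        numerator=n_event,
        denominator=denominator,
        rate_per_1000=1000.0 * n_event / denominator,
    )


def registry_from_interval_counts(
    risk_set_sizes: Sequence[int],
    miscarriages: Sequence[int],
    mtps: Sequence[int],
    intervals: Sequence[GAInterval] = CANONICAL_INTERVALS,
) -> list[PregnancyRecord]:
    """Deterministic registry realizing given risk-set sizes and event counts.

    Reconstructs record-level data from published interval tallies: for each
    window, enough new women are enrolled just before it opens to bring the
    risk set to its target size, the stated numbers of miscarriages and MTPs
    occur at the window's first day, and final survivors deliver live at term.
    Useful for checking the estimator against printed numerators/denominators.
    """
    if not (len(risk_set_sizes) == len(miscarriages) == len(mtps) == len(intervals)):
        raise ValueError("count sequences and intervals must have equal length")
    records: list[PregnancyRecord] = []
    survivors = 0
    counter = 0

    def new_woman(enroll_day: int, outcome: Outcome, outcome_day: int,
                  neonatal: Optional[bool] = None) -> PregnancyRecord:
        nonlocal counter
        counter += 1
        return PregnancyRecord(
            woman_id=f"R{counter:06d}",
            cluster_id="C001",
            outcome=outcome,
            enroll_ga_days=enroll_day,
            outcome_ga_days=outcome_day,
            neonatal_death_by_28d=neonatal,
        )

    pending_survivor_enrollments: deque[int] = deque()
    for k, interval in enumerate(intervals):
        n_new = risk_set_sizes[k] - survivors
        if n_new < 0:
            raise ValueError(
                f"risk set for {interval.label} smaller than survivors from the previous window"
            )
        enroll_day = interval.start_days - 2
        pending_survivor_enrollments.extend([enroll_day] * n_new)
        n_events = miscarriages[k] + mtps[k]
        if n_events > risk_set_sizes[k]:
            raise ValueError(f"more events than women at risk in {interval.label}")
        # events are assigned to the earliest-enrolled women still pending
        for _ in range(miscarriages[k]):
            records.append(new_woman(pending_survivor_enrollments.popleft(),
                                     Outcome.MISCARRIAGE, interval.start_days))
        for _ in range(mtps[k]):
            records.append(new_woman(pending_survivor_enrollments.popleft(),
                                     Outcome.MTP, interval.start_days))
        survivors = risk_set_sizes[k] - n_events
    for enroll_day in pending_survivor_enrollments:
        records.append(new_woman(enroll_day, Outcome.LIVEBIRTH, 280, neonatal=False))
    return records
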