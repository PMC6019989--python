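"""Relative risks of early pregnancy loss by maternal characteristics.

Covariates are categorized with the field's conventional cutpoints (maternal
age <=20 / 21-25 / 26-30 / >30 years; education; parity 0 / 1-2 / >2; BMI
<18.5 / 18.5-25 / >25 kg/m2; hemoglobin <=9 / >9-11 / >11 g/dl) and, for each
loss type and gestational-age window, a log-link binomial model compares women
with the loss in the window against risk-set members still ongoing at its end.
Exponentiated coefficients are adjusted relative risks with Wald 95% CIs.

Clustered sampling (geographic study clusters) is handled with a cluster-level
random intercept on the log-risk scale, estimated by Laplace-approximate
maximum marginal likelihood; with a single cluster the model falls back to a
fixed intercept with a warning. Covariate missingness is handled complete-case
per model. A log-binomial fit without the random effect on a 2x2 table equals
the closed-form risk ratio and its standard log-scale CI.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
import statsmodels.api as sm
from statsmodels.tools.numdiff import approx_hess1
from statsmodels.tools.sm_exceptions import DomainWarning

from .registry_model import (
    CANONICAL_INTERVALS,
    GAInterval,
    Outcome,
    PregnancyRecord,
)
from .interval_rates import _as_frame, _event_mask, _membership_mask

logger = logging.getLogger(__name__)

#: Factor -> ordered levels (reference level marked in REFERENCE_LEVELS).
FACTOR_LEVELS: dict[str, tuple[str, ...]] = {
    "age_cat": ("LE20", "A21_25", "A26_30", "GT30"),
    "education_cat": ("NONE", "PRIMARY", "SECONDARY", "UNIVERSITY_PLUS"),
    "parity_cat": ("P0", "P1_2", "GT2"),
    "bmi_cat": ("UNDER_18_5", "NORMAL_18_5_25", "OVER_25"),
    "hb_cat": ("SEV_MOD_LE9", "MILD_9_11", "NORMAL_GT11"),
}

REFERENCE_LEVELS: dict[str, str] = {
    "age_cat": "A21_25",
    "education_cat": "PRIMARY",
    "parity_cat": "P1_2",
    "bmi_cat": "NORMAL_18_5_25",
    "hb_cat": "NORMAL_GT11",
}

DEFAULT_FACTORS: tuple[str, ...] = tuple(FACTOR_LEVELS)


class FitRefusedError(ValueError):
    """Raised when the data cannot support a model fit (too few cases/comparisons)."""


@dataclass(frozen=True)
class CovariateProfile:
    """Categorized maternal covariates; ``None`` marks a missing value."""

    age_cat: Optional[str]
    education_cat: Optional[str]
    parity_cat: Optional[str]
    bmi_cat: Optional[str]
    hb_cat: Optional[str]


def bmi(weight_kg: float, height_m: float) -> float:
    if weight_kg <= 0 or height_m <= 0:
        raise ValueError("weight and height must be positive")
    return weight_kg / height_m**2


def categorize(record: PregnancyRecord) -> CovariateProfile:
    """Deterministic covariate categorization.

    Boundaries: age <=20 / 21-25 / 26-30 / >30; parity 0 / 1-2 / >2;
    BMI <18.5 / [18.5, 25] / >25; Hb <=9 / (9, 11] / >11 g/dl.
    Missing inputs map to ``None`` category flags.
    """
    age = record.maternal_age_years
    if age is None:
        age_cat = None
    elif age <= 20:
        age_cat = "LE20"
    elif age <= 25:
        age_cat = "A21_25"
    elif age <= 30:
        age_cat = "A26_30"
    else:
        age_cat = "GT30"

    education_cat = record.education.value if record.education is not None else None

    parity = record.parity
    if parity is None:
        parity_cat = None
    elif parity == 0:
        parity_cat = "P0"
    elif parity <= 2:
        parity_cat = "P1_2"
    else:
        parity_cat = "GT2"

    if record.weight_kg is None or record.height_m is None:
        bmi_cat = None
    else:
        b = bmi(record.weight_kg, record.height_m)
        if b < 18.5:
            bmi_cat = "UNDER_18_5"
        elif b <= 25.0:
            bmi_cat = "NORMAL_18_5_25"
        else:
            bmi_cat = "OVER_25"

    hb = record.hemoglobin_g_dl
    if hb is None:
        hb_cat = None
    elif hb <= 9.0:
        hb_cat = "SEV_MOD_LE9"
    elif hb <= 11.0:
        hb_cat = "MILD_9_11"
    else:
        hb_cat = "NORMAL_GT11"

    return CovariateProfile(age_cat, education_cat, parity_cat, bmi_cat, hb_cat)


def _profile_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorized categorization of a canonical-column frame."""
    age = df["maternal_age_years"].astype(float)
    age_cat = pd.Series(pd.NA, index=df.index, dtype="object")
    age_cat[age <= 20] = "LE20"
    age_cat[(age > 20) & (age <= 25)] = "A21_25"
    age_cat[(age > 25) & (age <= 30)] = "A26_30"
    age_cat[age > 30] = "GT30"

    parity = df["parity"].astype(float)
    parity_cat = pd.Series(pd.NA, index=df.index, dtype="object")
    parity_cat[parity == 0] = "P0"
    parity_cat[(parity >= 1) & (parity <= 2)] = "P1_2"
    parity_cat[parity > 2] = "GT2"

    w = df["weight_kg"].astype(float)
    h = df["height_m"].astype(float)
    b = w / h**2
    bmi_cat = pd.Series(pd.NA, index=df.index, dtype="object")
    bmi_cat[b < 18.5] = "UNDER_18_5"
    bmi_cat[(b >= 18.5) & (b <= 25.0)] = "NORMAL_18_5_25"
    bmi_cat[b > 25.0] = "OVER_25"

    hb = df["hemoglobin_g_dl"].astype(float)
    hb_cat = pd.Series(pd.NA, index=df.index, dtype="object")
    hb_cat[hb <= 9.0] = "SEV_MOD_LE9"
    hb_cat[(hb > 9.0) & (hb <= 11.0)] = "MILD_9_11"
    hb_cat[hb > 11.0] = "NORMAL_GT11"

    return pd.DataFrame(
        {
            "age_cat": age_cat,
            "education_cat": df["education"],
            "parity_cat": parity_cat,
            "bmi_cat": bmi_cat,
            "hb_cat": hb_cat,
        }
    )


def build_comparison_set(
    records: Sequence[PregnancyRecord], interval: GAInterval, event: Outcome
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cases vs ongoing-pregnancy comparisons within an interval's risk set.

    Cases are risk-set members whose ``event`` fell in the interval;
    comparisons are risk-set members with pregnancy still ongoing at the
    interval's end. Members losing the pregnancy to the *competing* loss type
    in the interval belong to neither group, mirroring the denominator
    convention of the rate table. Returns two canonical-column frames.
    """
    df = _as_frame(records)
    membership = _membership_mask(df, interval)
    case_mask = membership & _event_mask(df, interval, event)

    out_ga = df["outcome_ga_days"].to_numpy(dtype=float, na_value=np.nan)
    is_loss = df["outcome"].isin((Outcome.MISCARRIAGE.value, Outcome.MTP.value)).to_numpy()
    lost_before_end = is_loss & ~np.isnan(out_ga) & (out_ga < interval.end_days)
    comparison_mask = membership & ~lost_before_end

    return df.loc[case_mask], df.loc[comparison_mask]


@dataclass(frozen=True)
class RREstimate:
    rr: float
    ci_low: Optional[float]
    ci_high: Optional[float]
    reference: bool = False


@dataclass
class RRResult:
    """Adjusted relative risks for one event x interval model."""

    event: Optional[Outcome]
    interval: Optional[GAInterval]
    estimates: dict[tuple[str, str], RREstimate]
    n_cases: int
    n_comparisons: int
    converged: bool
    message: str = ""
    cluster_sd: Optional[float] = None
    random_effect: bool = True
    error: Optional[str] = None

    def rr(self, factor: str, level: str) -> float:
        return self.estimates[(factor, level)].rr

    def ci(self, factor: str, level: str) -> tuple[float, float]:
        est = self.estimates[(factor, level)]
        if est.reference:
            raise ValueError("reference level has no CI")
        return est.ci_low, est.ci_high


def _design_matrix(
    profiles: pd.DataFrame, factors: Sequence[str]
) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Intercept + treatment-coded dummies against each factor's reference level."""
    cols = [np.ones(len(profiles))]
    names: list[tuple[str, str]] = []
    for factor in factors:
        ref = REFERENCE_LEVELS[factor]
        for level in FACTOR_LEVELS[factor]:
            if level == ref:
                continue
            cols.append((profiles[factor] == level).to_numpy(dtype=float))
            names.append((factor, level))
    return np.column_stack(cols), names


def _aggregate(X: np.ndarray, y: np.ndarray, groups: np.ndarray):
    """Collapse rows with identical (cluster, covariate pattern) into binomial counts."""
    key = np.column_stack([groups, X])
    _, idx, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    m = np.bincount(inverse).astype(float)
    s = np.bincount(inverse, weights=y)
    Xa = X[idx]
    ga = groups[idx]
    order = np.argsort(ga, kind="stable")
    return Xa[order], s[order], m[order], ga[order]


class _LaplaceLogBinomial:
    """Laplace-approximate marginal likelihood for a log-binomial model with a
    scalar Gaussian random intercept per cluster."""

    #: linear predictors are capped just below 0 so fitted risks stay < 1
    _ETA_CAP = -1e-9

    def __init__(self, Xa, s, m, groups, n_groups):
        self.Xa, self.s, self.m = Xa, s, m
        self.g = groups
        self.J = n_groups
        self.p = Xa.shape[1]
        self._u = np.zeros(n_groups)  # warm start for the inner mode search

    def _inner_mode(self, eta: np.ndarray, sigma2: float) -> tuple[np.ndarray, np.ndarray]:
        u = self._u.copy()
        for _ in range(100):
            lp = np.minimum(eta + u[self.g], self._ETA_CAP)
            prob = np.exp(lp)
            frac = prob / (1.0 - prob)
            grad_i = self.s - (self.m - self.s) * frac
            grad = np.bincount(self.g, weights=grad_i, minlength=self.J) - u / sigma2
            hess_i = (self.m - self.s) * frac / (1.0 - prob)
            hess = np.bincount(self.g, weights=hess_i, minlength=self.J) + 1.0 / sigma2
            step = np.clip(grad / hess, -2.0, 2.0)
            u = u + step
            if np.max(np.abs(grad)) < 1e-9:
                break
        self._u = u
        lp = np.minimum(eta + u[self.g], self._ETA_CAP)
        prob = np.exp(lp)
        hess_i = (self.m - self.s) * prob / (1.0 - prob) ** 2
        hess = np.bincount(self.g, weights=hess_i, minlength=self.J) + 1.0 / sigma2
        return u, hess

    def negll(self, theta: np.ndarray) -> float:
        beta, log_sigma = theta[: self.p], theta[self.p]
        sigma2 = np.exp(2.0 * log_sigma)
        eta = self.Xa @ beta
        u, hess = self._inner_mode(eta, sigma2)
        lp = np.minimum(eta + u[self.g], self._ETA_CAP)
        prob = np.exp(lp)
        ll_i = self.s * lp + (self.m - self.s) * np.log1p(-prob)
        f = np.bincount(self.g, weights=ll_i, minlength=self.J)
        ll = np.sum(f - u**2 / (2.0 * sigma2) - 0.5 * np.log(sigma2 * hess))
        if not np.isfinite(ll):
            return 1e12
        return -ll


def _fixed_effect_fit(X, y, names, alpha):
    """Log-binomial GLM without random effect (statsmodels IRLS)."""
    start = np.zeros(X.shape[1])
    start[0] = np.log(max(y.mean(), 1e-6))
    with warnings.catch_warnings():
        # statsmodels warns that log is not the canonical Binomial link
        warnings.simplefilter("ignore", DomainWarning)
        model = sm.GLM(y, X, family=sm.families.Binomial(sm.families.links.Log()))
        res = model.fit(start_params=start, maxiter=200)
    beta = np.asarray(res.params)
    se = np.asarray(res.bse)
    converged = bool(res.converged)
    return beta, se, converged, "fixed-intercept log-binomial GLM"


def fit_rr(
    cases,
    comparisons,
    factors: Sequence[str] = DEFAULT_FACTORS,
    random_effect: bool = True,
    alpha: float = 0.05,
    event: Optional[Outcome] = None,
    interval: Optional[GAInterval] = None,
) -> RRResult:
    """Fit the adjusted log-binomial RR model for cases vs comparisons.

    All requested covariate factors enter one jointly adjusted model together
    with a cluster random intercept; each level's RR is the exponentiated
    coefficient against its reference level with a Wald ``1 - alpha`` CI.
    Rows missing any model covariate are dropped (complete case). Deterministic
    given the data and configuration.
    """
    case_df = _as_frame(cases)
    comp_df = _as_frame(comparisons)
    if len(case_df) < 2 or len(comp_df) < 2:
        raise FitRefusedError(
            f"need at least 2 cases and 2 comparisons to fit "
            f"(got {len(case_df)} cases, {len(comp_df)} comparisons)"
        )
    data = pd.concat([case_df, comp_df], ignore_index=True)
    y = np.concatenate([np.ones(len(case_df)), np.zeros(len(comp_df))])
    profiles = _profile_frame(data)
    complete = profiles[list(factors)].notna().all(axis=1).to_numpy()
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("complete-case analysis dropped %d records with missing covariates", n_dropped)
    profiles, y = profiles.loc[complete], y[complete]
    clusters = data.loc[complete, "cluster_id"]
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise FitRefusedError("fewer than 2 cases or comparisons after complete-case filtering")

    X, names = _design_matrix(profiles, factors)
    codes, uniques = pd.factorize(clusters, sort=True)
    n_clusters = len(uniques)

    use_re = random_effect
    if use_re and n_clusters < 2:
        warnings.warn(
            "only one cluster present; falling back to a fixed intercept",
            stacklevel=2,
        )
        logger.warning("single-cluster input: fitting fixed-intercept model")
        use_re = False

    z = scipy.stats.norm.ppf(1 - alpha / 2)
    cluster_sd = None
    if not use_re:
        beta, se, converged, message = _fixed_effect_fit(X, y, names, alpha)
    else:
        Xa, s, m, ga = _aggregate(X, y, codes.astype(np.int64))
        lik = _LaplaceLogBinomial(Xa, s, m, ga, n_clusters)
        try:
            beta0, _, _, _ = _fixed_effect_fit(X, y, names, alpha)
        except Exception:
            beta0 = np.zeros(X.shape[1])
            beta0[0] = np.log(max(y.mean(), 1e-6))
        theta0 = np.append(beta0, np.log(0.1))
        bounds = [(None, None)] * X.shape[1] + [(np.log(1e-3), np.log(3.0))]
        opt = scipy.optimize.minimize(
            lik.negll, theta0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-11},
        )
        theta = opt.x
        beta = theta[: X.shape[1]]
        cluster_sd = float(np.exp(theta[-1]))
        H = approx_hess1(theta, lik.negll)
        try:
            cov = np.linalg.inv(H)
            se_full = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(H)
            se_full = np.sqrt(np.clip(np.diag(cov), 0, None))
        se = se_full[: X.shape[1]]
        converged = bool(opt.success)
        message = (
            f"Laplace log-binomial mixed model ({n_clusters} clusters): "
            + str(opt.message)
        )

    if np.any(np.abs(beta[1:]) > 10):
        converged = False
        message += "; possible separation (|log RR| > 10)"

    estimates: dict[tuple[str, str], RREstimate] = {}
    for factor in factors:
        ref = REFERENCE_LEVELS[factor]
        estimates[(factor, ref)] = RREstimate(1.0, None, None, reference=True)
    for k, (factor, level) in enumerate(names, start=1):
        estimates[(factor, level)] = RREstimate(
            rr=float(np.exp(beta[k])),
            ci_low=float(np.exp(beta[k] - z * se[k])),
            ci_high=float(np.exp(beta[k] + z * se[k])),
        )

    if not converged:
        logger.warning("model did not converge cleanly: %s", message)
    return RRResult(
        event=event,
        interval=interval,
        estimates=estimates,
        n_cases=int(y.sum()),
        n_comparisons=int((1 - y).sum()),
        converged=converged,
        message=message,
        cluster_sd=cluster_sd,
        random_effect=use_re,
    )


def rr_table(
    records: Sequence[PregnancyRecord],
    events: Sequence[Outcome] = (Outcome.MISCARRIAGE, Outcome.MTP),
    intervals: Sequence[GAInterval] = CANONICAL_INTERVALS,
    factors: Sequence[str] = DEFAULT_FACTORS,
    random_effect: bool = True,
) -> list[RRResult]:
    """Fit every event x interval model; per-model failures are isolated.

    A model that cannot be fitted yields an ``RRResult`` whose ``error`` field
    carries the reason instead of aborting the remaining fits.
    """
    df = _as_frame(records)
    results = []
    for event in events:
        for interval in intervals:
            try:
                cases, comparisons = build_comparison_set(df, interval, event)
                res = fit_rr(
                    cases, comparisons, factors=factors,
                    random_effect=random_effect, event=event, interval=interval,
                )
            except (FitRefusedError, ValueError) as exc:
                res = RRResult(
                    event=event, interval=interval, estimates={},
                    n_cases=0, n_comparisons=0, converged=False,
                    error=str(exc), random_effect=random_effect,
                )
            results.append(res)
    return results


def rr_results_to_frame(results: Sequence[RRResult]) -> pd.DataFrame:
    """Long-format rendering: one row per event, interval, factor and level.

    Reference rows carry RR 1 and the display string ``REF``.
    """
    rows = []
    for res in results:
        ev = res.event.value if res.event else ""
        iv = res.interval.label if res.interval else ""
        if res.error:
            rows.append(
                {"event": ev, "interval": iv, "factor": "", "level": "",
                 "rr": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                 "display": f"ERROR: {res.error}", "n_cases": res.n_cases,
                 "n_comparisons": res.n_comparisons, "converged": False}
            )
            continue
        for factor in FACTOR_LEVELS:
            for level in FACTOR_LEVELS[factor]:
                if (factor, level) not in res.estimates:
                    continue
                est = res.estimates[(factor, level)]
                if est.reference:
                    display = "REF"
                else:
                    display = f"{est.rr:.2f} ({est.ci_low:.2f}, {est.ci_high:.2f})"
                rows.append(
                    {"event": ev, "interval": iv, "factor": factor, "level": level,
                     "rr": est.rr, "ci_low": est.ci_low, "ci_high": est.ci_high,
                     "display": display, "n_cases": res.n_cases,
                     "n_comparisons": res.n_comparisons, "converged": res.converged}
                )
    return pd.DataFrame(rows)
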