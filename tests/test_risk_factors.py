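"""Covariate categorization and the log-binomial RR models."""

import warnings

import numpy as np
import pytest
from scipy.stats import norm

from gestloss import (
    GeneratorConfig,
    Outcome,
    PregnancyRecord,
    build_comparison_set,
    build_risk_set,
    categorize,
    exclude_unknown_ga,
    fit_rr,
    generate,
    rr_results_to_frame,
    rr_table,
)
from gestloss.registry_model import CANONICAL_INTERVALS, Education
from gestloss.risk_factors import FACTOR_LEVELS, FitRefusedError

IV1, IV2, IV3 = CANONICAL_INTERVALS


def _rec(**overrides) -> PregnancyRecord:
    base = dict(woman_id="W1", cluster_id="C1", outcome=Outcome.LIVEBIRTH,
                enroll_ga_days=40, outcome_ga_days=280, neonatal_death_by_28d=False)
    base.update(overrides)
    return PregnancyRecord(**base)


class TestCategorize:
    @pytest.mark.parametrize(
        "field, value, factor, expected",
        [
            ("maternal_age_years", 20, "age_cat", "LE20"),
            ("maternal_age_years", 21, "age_cat", "A21_25"),
            ("maternal_age_years", 30, "age_cat", "A26_30"),
            ("maternal_age_years", 31, "age_cat", "GT30"),
            ("parity", 0, "parity_cat", "P0"),
            ("parity", 2, "parity_cat", "P1_2"),
            ("parity", 3, "parity_cat", "GT2"),
            ("hemoglobin_g_dl", 9.0, "hb_cat", "SEV_MOD_LE9"),
            ("hemoglobin_g_dl", 9.1, "hb_cat", "MILD_9_11"),
            ("hemoglobin_g_dl", 11.0, "hb_cat", "MILD_9_11"),
            ("hemoglobin_g_dl", 11.1, "hb_cat", "NORMAL_GT11"),
        ],
    )
    def test_boundaries(self, field, value, factor, expected):
        profile = categorize(_rec(**{field: value}))
        assert getattr(profile, factor) == expected

    def test_bmi_from_weight_and_height(self):
        profile = categorize(_rec(weight_kg=45.0, height_m=1.60))  # BMI 17.6
        assert profile.bmi_cat == "UNDER_18_5"
        assert categorize(_rec(weight_kg=64.0, height_m=1.60)).bmi_cat == "NORMAL_18_5_25"
        assert categorize(_rec(weight_kg=65.0, height_m=1.60)).bmi_cat == "OVER_25"

    def test_missing_covariates_flagged_none(self):
        profile = categorize(_rec())
        assert profile.age_cat is None and profile.hb_cat is None


class TestComparisonSets:
    def test_partition_of_risk_set(self, default_kept):
        """Cases, competing-event women and comparisons tile the risk set."""
        for iv in CANONICAL_INTERVALS:
            riskset = build_risk_set(default_kept, iv)
            cases, comps = build_comparison_set(default_kept, iv, Outcome.MISCARRIAGE)
            competing, _ = build_comparison_set(default_kept, iv, Outcome.MTP)
            assert len(cases) + len(comps) + len(competing) == riskset.n

    def test_comparison_women_are_ongoing_at_window_end(self):
        records = [
            _rec(woman_id="A", outcome=Outcome.MISCARRIAGE, outcome_ga_days=60,
                 neonatal_death_by_28d=None),
            _rec(woman_id="B", outcome=Outcome.MTP, outcome_ga_days=70,
                 neonatal_death_by_28d=None),
            _rec(woman_id="C"),
            _rec(woman_id="D", enroll_ga_days=60),  # enrolled mid-window
        ]
        cases, comps = build_comparison_set(records, IV2, Outcome.MISCARRIAGE)
        assert list(cases["woman_id"]) == ["A"]
        assert list(comps["woman_id"]) == ["C"]


class TestFitRR:
    def test_two_by_two_matches_closed_form_risk_ratio(self):
        a, b, c, d = 30, 70, 20, 80  # exposed cases/noncases, unexposed cases/noncases
        def block(n, outcome, edu, tag):
            day = 50 if outcome == Outcome.MISCARRIAGE else 280
            nn = False if outcome == Outcome.LIVEBIRTH else None
            return [_rec(woman_id=f"{tag}{i}", outcome=outcome, outcome_ga_days=day,
                         neonatal_death_by_28d=nn, education=edu) for i in range(n)]
        cases = block(a, Outcome.MISCARRIAGE, Education.SECONDARY, "a") + \
                block(c, Outcome.MISCARRIAGE, Education.PRIMARY, "c")
        comps = block(b, Outcome.LIVEBIRTH, Education.SECONDARY, "b") + \
                block(d, Outcome.LIVEBIRTH, Education.PRIMARY, "d")
        res = fit_rr(cases, comps, factors=("education_cat",), random_effect=False)
        rr = (a / (a + b)) / (c / (c + d))
        se = np.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
        z = norm.ppf(0.975)
        assert res.rr("education_cat", "SECONDARY") == pytest.approx(rr, rel=1e-6)
        lo, hi = res.ci("education_cat", "SECONDARY")
        assert lo == pytest.approx(rr * np.exp(-z * se), rel=1e-6)
        assert hi == pytest.approx(rr * np.exp(z * se), rel=1e-6)

    def test_too_few_cases_refused(self):
        cases = [_rec(woman_id="A", outcome=Outcome.MISCARRIAGE, outcome_ga_days=50,
                      neonatal_death_by_28d=None, education=Education.PRIMARY)]
        comps = [_rec(woman_id=f"B{i}", education=Education.PRIMARY) for i in range(5)]
        with pytest.raises(FitRefusedError, match="at least 2"):
            fit_rr(cases, comps, factors=("education_cat",))

    def test_single_cluster_falls_back_with_warning(self):
        def block(n, outcome, edu, tag):
            day = 50 if outcome == Outcome.MISCARRIAGE else 280
            nn = False if outcome == Outcome.LIVEBIRTH else None
            return [_rec(woman_id=f"{tag}{i}", outcome=outcome, outcome_ga_days=day,
                         neonatal_death_by_28d=nn, education=edu) for i in range(n)]
        cases = block(20, Outcome.MISCARRIAGE, Education.SECONDARY, "a") + \
                block(15, Outcome.MISCARRIAGE, Education.PRIMARY, "c")
        comps = block(80, Outcome.LIVEBIRTH, Education.SECONDARY, "b") + \
                block(85, Outcome.LIVEBIRTH, Education.PRIMARY, "d")
        with pytest.warns(UserWarning, match="one cluster"):
            res = fit_rr(cases, comps, factors=("education_cat",), random_effect=True)
        assert res.random_effect is False

    def test_cluster_relabeling_and_order_invariance(self):
        cfg = GeneratorConfig(n_women=8000, rr_miscarriage={"parity_cat:GT2": 1.5})
        records, _ = generate(cfg, seed=21)
        kept, _ = exclude_unknown_ga(records)
        cases, comps = build_comparison_set(kept, IV2, Outcome.MISCARRIAGE)
        base = fit_rr(cases, comps)

        rng = np.random.default_rng(0)
        relabel = {f"C{i + 1:03d}": f"site-{chr(65 + i)}" for i in range(20)}
        cases2 = cases.sample(frac=1, random_state=1).copy()
        comps2 = comps.sample(frac=1, random_state=2).copy()
        cases2["cluster_id"] = cases2["cluster_id"].map(relabel)
        comps2["cluster_id"] = comps2["cluster_id"].map(relabel)
        perm = fit_rr(cases2, comps2)
        for key, est in base.estimates.items():
            if est.reference:
                continue
            assert perm.estimates[key].rr == pytest.approx(est.rr, rel=1e-5)


@pytest.fixture(scope="module")
def table_results():
    records, _ = generate(GeneratorConfig(n_women=15_000), seed=33)
    kept, _ = exclude_unknown_ga(records)
    return rr_table(kept)


class TestRRTable:
    def test_six_models_with_five_factor_blocks(self, table_results):
        assert len(table_results) == 6
        for res in table_results:
            assert res.error is None
            factors = {f for (f, _) in res.estimates}
            assert factors == set(FACTOR_LEVELS)

    def test_reference_rows_are_unit_rr(self, table_results):
        frame = rr_results_to_frame(table_results)
        refs = frame[frame["display"] == "REF"]
        assert len(refs) == 6 * 5
        assert (refs["rr"] == 1.0).all()

    def test_frame_layout(self, table_results):
        frame = rr_results_to_frame(table_results)
        assert list(frame.columns) == [
            "event", "interval", "factor", "level", "rr", "ci_low", "ci_high",
            "display", "n_cases", "n_comparisons", "converged",
        ]
        assert set(frame["event"]) == {"MISCARRIAGE", "MTP"}
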