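"""Hypothetical-cohort multiple-decrement projection."""

import numpy as np
import pytest

from gestloss import (
    IntervalRateTable,
    Outcome,
    PerinatalRates,
    extend_perinatal,
    project_cohort,
    project_interval,
    render_projection,
)
from gestloss.registry_model import CANONICAL_INTERVALS

from .conftest import MISC_COUNTS, MISC_DENOMS, MTP_COUNTS, MTP_DENOMS


def reference_rate_table() -> IntervalRateTable:
    counts = []
    for k, iv in enumerate(CANONICAL_INTERVALS):
        counts.append((iv, Outcome.MISCARRIAGE, MISC_COUNTS[k], MISC_DENOMS[k]))
        counts.append((iv, Outcome.MTP, MTP_COUNTS[k], MTP_DENOMS[k]))
    return IntervalRateTable.from_counts(counts)


def zero_rate_table() -> IntervalRateTable:
    counts = []
    for iv in CANONICAL_INTERVALS:
        counts.append((iv, Outcome.MISCARRIAGE, 0, 1000))
        counts.append((iv, Outcome.MTP, 0, 1000))
    return IntervalRateTable.from_counts(counts)


class TestProjectInterval:
    def test_first_window_whole_pregnancy_counts(self):
        step = project_interval(1000, 115.3, 45.4)
        assert (step.miscarriages, step.mtps, step.exiting) == (115, 45, 840)

    def test_nearest_rounds_half_and_above_up(self):
        step = project_interval(840, 101.9, 48.3)
        assert step.miscarriages == 86  # 85.6 -> 86
        assert step.mtps == 41  # 40.57 -> 41 (printed flow figures carry a 40 here)

    def test_zero_entering_gives_all_zero_step(self):
        step = project_interval(0, 115.3, 45.4)
        assert (step.miscarriages, step.mtps, step.exiting) == (0, 0, 0)

    def test_floor_policy(self):
        step = project_interval(840, 101.9, 48.3, rounding="floor")
        assert (step.miscarriages, step.mtps) == (85, 40)

    def test_decrements_exceeding_entering_error(self):
        with pytest.raises(ValueError, match="exceed"):
            project_interval(1, 1000, 1000)

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            project_interval(100, 1200, 0)


class TestProjectCohort:
    def test_chained_steps_and_20_week_count(self):
        proj = project_cohort(reference_rate_table(), 1000)
        entering = [s.entering for s in proj.steps]
        assert entering == [1000, 840, 713]
        assert abs(proj.ongoing - 642) <= 1

    def test_zero_rates_identity(self):
        proj = project_cohort(zero_rate_table(), 1000)
        assert all(s.exiting == 1000 for s in proj.steps)

    def test_total_first_window_loss_empties_cohort(self):
        counts = [(CANONICAL_INTERVALS[0], Outcome.MISCARRIAGE, 1000, 1000),
                  (CANONICAL_INTERVALS[0], Outcome.MTP, 0, 1000)]
        for iv in CANONICAL_INTERVALS[1:]:
            counts += [(iv, Outcome.MISCARRIAGE, 0, 1000), (iv, Outcome.MTP, 0, 1000)]
        proj = project_cohort(IntervalRateTable.from_counts(counts), 1000)
        assert proj.ongoing == 0

    def test_missing_interval_fatal(self):
        partial = IntervalRateTable.from_counts(
            [(CANONICAL_INTERVALS[0], Outcome.MISCARRIAGE, 10, 100),
             (CANONICAL_INTERVALS[0], Outcome.MTP, 5, 100)]
        )
        with pytest.raises(ValueError, match="lacks interval"):
            project_cohort(partial, 1000)


class TestExtendPerinatal:
    def test_printed_20_week_survivors_flow(self):
        from gestloss.cohort_projection import CohortProjection, DecrementStep

        base = CohortProjection(1000, (DecrementStep("through 20w", 1000, miscarriages=358),))
        assert base.ongoing == 642
        full = extend_perinatal(base, PerinatalRates(26.0, 24.0, post20_mtp_count=2))
        assert full.step("STILLBIRTH").stillbirths == 17
        assert full.step("NEONATAL").neonatal_deaths == 15
        assert full.alive_at_28d == 608

    def test_rounding_of_stillbirth_cell(self):
        from gestloss.cohort_projection import CohortProjection, DecrementStep

        base = CohortProjection(640, (DecrementStep("through 20w", 640),))
        full = extend_perinatal(base, PerinatalRates(26.0, 24.0))
        assert full.step("STILLBIRTH").stillbirths == 17  # 640*0.026 = 16.64

    def test_zero_rates_leave_cohort_intact(self):
        proj = project_cohort(zero_rate_table(), 500)
        full = extend_perinatal(proj, PerinatalRates(0.0, 0.0))
        assert full.alive_at_28d == 500

    def test_double_extension_rejected(self):
        proj = extend_perinatal(project_cohort(zero_rate_table(), 10), PerinatalRates(0, 0))
        with pytest.raises(ValueError):
            extend_perinatal(proj, PerinatalRates(0, 0))


class TestProperties:
    def test_conservation_after_rendering(self):
        proj = extend_perinatal(
            project_cohort(reference_rate_table(), 1000),
            PerinatalRates(26.0, 24.0, post20_mtp_count=2),
        )
        flow = render_projection(proj)
        assert len(flow) == 6
        total_losses = (flow["miscarriages"] + flow["mtps"] + flow["stillbirths"]
                        + flow["neonatal_deaths"]).sum()
        assert total_losses + proj.alive_at_28d == 1000

    def test_continuous_mode_matches_survival_product(self):
        table = reference_rate_table()
        proj = extend_perinatal(
            project_cohort(table, 1000, rounding="none"),
            PerinatalRates(26.0, 24.0),
            rounding="none",
        )
        expected = 1000.0
        for iv in CANONICAL_INTERVALS:
            expected *= 1.0 - (table.rate(iv, Outcome.MISCARRIAGE)
                               + table.rate(iv, Outcome.MTP)) / 1000.0
        expected *= (1 - 0.026) * (1 - 0.024)
        assert proj.alive_at_28d == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("bump", ["misc", "mtp", "sb", "nmr"])
    def test_raising_any_rate_never_increases_survivors(self, bump):
        def alive(misc0, mtp0, sb, nmr):
            counts = []
            for k, iv in enumerate(CANONICAL_INTERVALS):
                m = misc0 if k == 0 else MISC_COUNTS[k]
                counts.append((iv, Outcome.MISCARRIAGE, m, MISC_DENOMS[k]))
                t = mtp0 if k == 0 else MTP_COUNTS[k]
                counts.append((iv, Outcome.MTP, t, MTP_DENOMS[k]))
            proj = project_cohort(IntervalRateTable.from_counts(counts), 1000,
                                  rounding="none")
            return extend_perinatal(proj, PerinatalRates(sb, nmr), rounding="none").alive_at_28d

        base = alive(307, 112, 26.0, 24.0)
        bumped = {
            "misc": alive(340, 112, 26.0, 24.0),
            "mtp": alive(307, 150, 26.0, 24.0),
            "sb": alive(307, 112, 40.0, 24.0),
            "nmr": alive(307, 112, 26.0, 40.0),
        }[bump]
        assert bumped <= base

    def test_empty_projection_renders_header_only(self):
        from gestloss.cohort_projection import CohortProjection

        flow = render_projection(CohortProjection(0, ()))
        assert len(flow) == 0
        assert list(flow.columns)[0] == "step"
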