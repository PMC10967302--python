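"""DCF kinetics: background correction, start-normalized AUC, anchors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phytoscreen import (
    auc_normalized,
    background_correct,
    normalize_two_anchor,
    summarize_ros,
)
from phytoscreen.errors import (
    DegenerateAnchorError,
    InsufficientDataError,
    InvalidBaselineError,
    ScheduleError,
)

TIMES = np.array([0.0, 15.0, 30.0, 60.0, 90.0])


class TestBackgroundCorrect:
    def test_elementwise_subtraction(self):
        raw = np.array([100.0, 150, 200, 300, 400])
        blank = np.full(5, 50.0)
        np.testing.assert_allclose(
            background_correct(TIMES, raw, blank), [50, 100, 150, 250, 350]
        )

    def test_blank_equal_to_raw_invalidates_baseline(self):
        raw = np.array([100.0, 150, 200, 300, 400])
        with pytest.raises(InvalidBaselineError):
            background_correct(TIMES, raw, raw)

    def test_zero_blank_is_identity(self):
        raw = np.array([100.0, 150, 200, 300, 400])
        np.testing.assert_array_equal(
            background_correct(TIMES, raw, np.zeros(5)), raw
        )

    def test_schedule_mismatch_rejected(self):
        with pytest.raises(ScheduleError):
            background_correct(TIMES, np.ones(5), np.ones(4))


class TestAuc:
    def test_flat_trace_gives_window_length(self):
        f_rel, auc = auc_normalized(TIMES, np.full(5, 123.0))
        np.testing.assert_allclose(f_rel, 1.0)
        assert auc == pytest.approx(90.0)

    def test_hand_summed_trapezoids(self):
        # f_rel = (1,2,3,5,7): trapezoids 22.5 + 37.5 + 120 + 180 = 360
        _, auc = auc_normalized(TIMES, np.array([100.0, 200, 300, 500, 700]))
        assert auc == pytest.approx(360.0)

    def test_two_reads_single_trapezoid(self):
        _, auc = auc_normalized(np.array([0.0, 90.0]), np.array([10.0, 30.0]))
        assert auc == pytest.approx(180.0)

    def test_start_value_is_exactly_one(self):
        f_rel, _ = auc_normalized(TIMES, np.array([73.0, 90, 110, 160, 210]))
        assert f_rel[0] == 1.0

    def test_single_read_rejected(self):
        with pytest.raises(InsufficientDataError):
            auc_normalized(np.array([0.0]), np.array([100.0]))

    def test_trapezoid_matches_fine_riemann_sum(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            f = np.abs(rng.normal(100, 30, size=5)) + 1.0
            _, auc = auc_normalized(TIMES, f)
            grid = np.linspace(0, 90, 90_001)
            riemann = np.sum(np.interp(grid, TIMES, f / f[0])) * (90 / 90_000)
            riemann -= 0.5 * (f[0] / f[0] + f[-1] / f[0]) * (90 / 90_000)
            assert abs(auc - riemann) / auc < 1e-7


class TestTwoAnchor:
    @pytest.mark.parametrize(
        "sample,untreated,stress,expected",
        [(290.0, 90.0, 290.0, 100.0), (90.0, 90.0, 290.0, 0.0), (190.0, 90.0, 290.0, 50.0)],
    )
    def test_anchor_arithmetic(self, sample, untreated, stress, expected):
        assert normalize_two_anchor(sample, untreated, stress) == pytest.approx(expected)

    def test_values_outside_anchors_permitted(self):
        assert normalize_two_anchor(390.0, 90.0, 290.0) == pytest.approx(150.0)
        assert normalize_two_anchor(40.0, 90.0, 290.0) == pytest.approx(-25.0)

    def test_equal_anchors_rejected(self):
        with pytest.raises(DegenerateAnchorError):
            normalize_two_anchor(100.0, 90.0, 90.0)


class TestSummaries:
    def test_mean_and_sample_sd(self):
        res = summarize_ros("EXT0001", [40.0, 50.0, 60.0])
        assert res.ros_pct == pytest.approx(50.0)
        assert res.sd == pytest.approx(10.0)
        assert res.n == 3

    def test_single_replicate_flagged_by_n(self):
        res = summarize_ros("EXT0001", [70.0])
        assert (res.ros_pct, res.sd, res.n) == (70.0, 0.0, 1)

    def test_no_replicates_rejected(self):
        with pytest.raises(InsufficientDataError):
            summarize_ros("EXT0001", [])


def full_chain(times, raw, blank, auc_untreated, auc_stress):
    corrected = background_correct(times, raw, blank)
    _, auc = auc_normalized(times, corrected)
    return normalize_two_anchor(auc, auc_untreated, auc_stress)


class TestChainProperties:
    def test_anchor_identity_for_arbitrary_noise(self):
        """Stress wells average 100% and untreated wells 0% by construction."""
        rng = np.random.default_rng(11)
        blank = np.abs(rng.normal(50, 5, size=5))
        for _ in range(10):
            stress_aucs, untreated_aucs = [], []
            for _ in range(3):
                raw = blank + np.abs(rng.normal(1000, 100)) * (
                    1 + rng.uniform(0.01, 0.05) * TIMES
                ) * (1 + 0.1 * rng.standard_normal(5))
                _, auc = auc_normalized(TIMES, background_correct(TIMES, raw, blank))
                stress_aucs.append(auc)
            for _ in range(3):
                raw = blank + np.abs(rng.normal(1000, 100)) * (
                    1 + 0.002 * TIMES
                ) * (1 + 0.1 * rng.standard_normal(5))
                _, auc = auc_normalized(TIMES, background_correct(TIMES, raw, blank))
                untreated_aucs.append(auc)
            u, s = np.mean(untreated_aucs), np.mean(stress_aucs)
            stress_pcts = [normalize_two_anchor(a, u, s) for a in stress_aucs]
            untr_pcts = [normalize_two_anchor(a, u, s) for a in untreated_aucs]
            assert np.mean(stress_pcts) == pytest.approx(100.0, abs=1e-9)
            assert np.mean(untr_pcts) == pytest.approx(0.0, abs=1e-9)

    @given(scale=st.floats(0.1, 10.0))
    @settings(max_examples=30, deadline=None)
    def test_affine_invariance_of_corrected_signal(self, scale):
        """Scaling corrected fluorescence by any factor leaves ROS% unchanged."""
        f = np.array([80.0, 120, 180, 260, 340])
        _, auc1 = auc_normalized(TIMES, f)
        _, auc2 = auc_normalized(TIMES, f * scale)
        assert auc2 == pytest.approx(auc1, rel=1e-12)
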