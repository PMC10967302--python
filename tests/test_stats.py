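"""Dunnett hit calling, selectivity rules and Spearman correlation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from phytoscreen import (
    HitCall,
    call_hits,
    classify_selectivity,
    dunnett_test,
    spearman,
)
from phytoscreen.errors import (
    DegenerateVarianceError,
    InsufficientDataError,
    UndefinedCorrelationError,
)


def make_call(endpoint, mean, p=0.001):
    return call_hits({"x": mean}, {"x": p}, endpoint)["x"]


class TestDunnett:
    def test_single_group_reduces_to_pooled_t_test(self):
        rng = np.random.default_rng(1)
        ctrl, treat = rng.normal(0, 1, 3), rng.normal(1, 1, 3)
        p = dunnett_test(ctrl, {"t": treat})["t"]
        expected = sps.ttest_ind(treat, ctrl).pvalue
        assert p == pytest.approx(expected, abs=1e-6)

    def test_zero_statistic_gives_p_one(self):
        ctrl = [100.0, 100.0, 100.0]
        groups = {"same": [100.0, 100.0, 100.0], "noisy": [90.0, 95.0, 105.0]}
        p = dunnett_test(ctrl, groups)
        assert p["same"] == pytest.approx(1.0)
        assert p["noisy"] < 1.0

    @pytest.mark.parametrize("seed", [0, 5, 9])
    def test_matches_scipy_dunnett(self, seed):
        """Independent route: scipy's QMC multivariate-t evaluation."""
        rng = np.random.default_rng(seed)
        ctrl = rng.normal(100, 8, 3)
        groups = {f"g{i}": rng.normal(100 - 5 * i, 8, 3) for i in range(5)}
        mine = dunnett_test(ctrl, groups)
        ref = sps.dunnett(*groups.values(), control=ctrl, random_state=1).pvalue
        np.testing.assert_allclose(
            [mine[k] for k in groups], ref, atol=2e-3
        )

    def test_matches_scipy_unbalanced(self):
        rng = np.random.default_rng(3)
        ctrl = rng.normal(0, 1, 5)
        groups = {"a": rng.normal(0, 1, 4), "b": rng.normal(1, 1, 3), "c": rng.normal(0.5, 1, 6)}
        mine = dunnett_test(ctrl, groups)
        ref = sps.dunnett(*groups.values(), control=ctrl, random_state=1).pvalue
        np.testing.assert_allclose([mine[k] for k in groups], ref, atol=2e-3)

    def test_dominance_between_t_test_and_bonferroni(self):
        rng = np.random.default_rng(4)
        ctrl = rng.normal(0, 1, 3)
        groups = {f"g{i}": rng.normal(0.8 * i, 1, 3) for i in range(6)}
        adjusted = dunnett_test(ctrl, groups)
        # pooled-variance t-test p using the family MSE, as Dunnett does
        all_groups = [np.asarray(ctrl)] + [np.asarray(v) for v in groups.values()]
        df = sum(g.size for g in all_groups) - len(all_groups)
        mse = sum(np.sum((g - g.mean()) ** 2) for g in all_groups) / df
        for name, g in groups.items():
            t = (np.mean(g) - np.mean(ctrl)) / np.sqrt(mse * (2 / 3))
            p_raw = 2 * sps.t.sf(abs(t), df)
            assert adjusted[name] >= p_raw - 1e-9
            assert adjusted[name] <= min(1.0, len(groups) * p_raw) + 1e-6

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateVarianceError):
            dunnett_test([1.0, 1.0, 1.0], {"a": [2.0, 2.0, 2.0]})

    def test_too_few_replicates_rejected(self):
        with pytest.raises(InsufficientDataError):
            dunnett_test([1.0], {"a": [2.0, 3.0]})
        with pytest.raises(InsufficientDataError):
            dunnett_test([1.0, 2.0], {})


class TestCallHits:
    def test_significant_strong_reduction(self):
        call = make_call("ros", 38.98, p=0.001)
        assert call.direction == "decrease"
        assert call.reduction30

    def test_reduction30_boundary_inclusive(self):
        assert make_call("ros", 70.0, p=0.5).reduction30
        assert not make_call("ros", 70.01, p=0.5).reduction30

    def test_significant_increase(self):
        assert make_call("no", 105.0, p=0.02).direction == "increase"

    def test_insignificant_is_none(self):
        call = make_call("ros", 60.0, p=0.20)
        assert call.direction == "none"
        assert call.reduction30  # independent of significance


def hit(endpoint, mean, direction):
    return HitCall(
        sample_id="x",
        endpoint=endpoint,
        mean_pct=mean,
        p_adj=0.001 if direction != "none" else 0.5,
        direction=direction,
        reduction30=mean <= 70,
    )


class TestSelectivity:
    def classify(self, no_pct, ros_pct, no_dir="none", ros_dir="none", **kw):
        return classify_selectivity(
            "x",
            no_pct,
            ros_pct,
            hit("no", no_pct, no_dir),
            hit("ros", ros_pct, ros_dir),
            **kw,
        ).selectivity

    def test_dual_when_both_strongly_reduced(self):
        assert self.classify(32.96, 38.98, "decrease", "decrease") == "dual"

    def test_no_selective(self):
        assert self.classify(8.03, 92.31, "decrease", "none") == "no_selective"

    def test_ros_selective(self):
        assert self.classify(105.76, 48.36, "none", "decrease") == "ros_selective"

    def test_rule_order_dual_wins(self):
        # both below 60 -> dual even if only one endpoint is significant
        assert self.classify(55.0, 55.0, "decrease", "none") == "dual"

    def test_unclassified_middle_ground(self):
        assert self.classify(75.0, 75.0, "decrease", "decrease") == "unclassified"

    def test_excluded_overrides(self):
        assert self.classify(30.0, 30.0, "decrease", "decrease", excluded_no=True) == "excluded"
        assert classify_selectivity("x", None, 50.0, None, None).selectivity == "excluded"

    @given(
        no_pct=st.floats(0, 150),
        ros_pct=st.floats(0, 150),
        no_dir=st.sampled_from(["decrease", "increase", "none"]),
        ros_dir=st.sampled_from(["decrease", "increase", "none"]),
    )
    @settings(max_examples=200, deadline=None)
    def test_every_gated_extract_gets_exactly_one_class(
        self, no_pct, ros_pct, no_dir, ros_dir
    ):
        cls = self.classify(no_pct, ros_pct, no_dir, ros_dir)
        assert cls in {"dual", "no_selective", "ros_selective", "unclassified"}


class TestSpearman:
    def test_monotone_is_one(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40]).r_s == pytest.approx(1.0)

    def test_antitone_is_minus_one(self):
        assert spearman([1, 2, 3], [3, 2, 1]).r_s == pytest.approx(-1.0)

    def test_ties_match_hand_rank_pearson(self):
        x, y = [1, 2, 2, 4], [1, 3, 2, 4]
        rx, ry = [1.0, 2.5, 2.5, 4.0], [1.0, 3.0, 2.0, 4.0]  # mid-ranks by hand
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman(x, y).r_s == pytest.approx(expected, rel=1e-12)

    def test_p_value_uses_t_approximation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        y = x + rng.normal(size=20)
        res = spearman(x, y)
        t = res.r_s * np.sqrt((res.n - 2) / (1 - res.r_s**2))
        assert res.p_value == pytest.approx(2 * sps.t.sf(abs(t), res.n - 2), rel=1e-6)

    def test_pairwise_complete_only(self):
        res = spearman([1, 2, np.nan, 4, 5], [2, 4, 6, np.nan, 10])
        assert res.n == 3

    def test_constant_vector_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            spearman([1, 1, 1], [1, 2, 3])

    def test_too_short_rejected(self):
        with pytest.raises(InsufficientDataError):
            spearman([1, 2], [2, 1])

    @given(st.lists(st.integers(-(10**6), 10**6), min_size=5, max_size=20, unique=True))
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_monotone_transform(self, xs):
        ys = list(range(len(xs)))
        base = spearman(xs, ys).r_s
        transformed = spearman([float(x) ** 3 for x in xs], ys).r_s
        assert transformed == pytest.approx(base, abs=1e-12)
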