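"""Standard-curve fitting, inversion and FRAP plateau detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phytoscreen import (
    StandardCurve,
    absorbance_to_concentration,
    fit_standard_curve,
    frap_endpoint,
)
from phytoscreen.errors import (
    CalibrationError,
    DegenerateDesignError,
    FormatError,
    InsufficientDataError,
)


def normal_equations_fit(points):
    """Independent oracle: solve the 2x2 least-squares normal equations."""
    x = np.array([p[0] for p in points])
    y = np.array([p[1] for p in points])
    n = len(x)
    a = np.array([[np.sum(x * x), np.sum(x)], [np.sum(x), n]])
    b = np.array([np.sum(x * y), np.sum(y)])
    slope, intercept = np.linalg.solve(a, b)
    return slope, intercept


class TestFit:
    def test_exact_line(self):
        curve = fit_standard_curve([(0, 0.0), (100, 0.2), (200, 0.4)])
        assert curve.slope == pytest.approx(0.002)
        assert curve.intercept == pytest.approx(0.0, abs=1e-12)
        assert curve.r_squared == pytest.approx(1.0)
        assert curve.n_points == 3

    def test_matches_normal_equations(self):
        points = [(0, 0.01), (50, 0.12), (100, 0.19), (200, 0.41)]
        slope, intercept = normal_equations_fit(points)
        curve = fit_standard_curve(points)
        assert curve.slope == pytest.approx(slope, rel=1e-12)
        assert curve.intercept == pytest.approx(intercept, rel=1e-10)

    def test_degenerate_design(self):
        with pytest.raises(DegenerateDesignError):
            fit_standard_curve([(100, 0.2), (100, 0.3)])

    def test_negative_slope_rejected(self):
        with pytest.raises(CalibrationError):
            fit_standard_curve([(0, 0.5), (100, 0.3), (200, 0.1)])

    @given(
        slope=st.floats(1e-4, 1e-2),
        intercept=st.floats(-0.05, 0.05),
        concs=st.lists(st.floats(0, 1000), min_size=3, max_size=8, unique=True),
    )
    @settings(max_examples=50, deadline=None)
    def test_noiseless_fit_recovers_line(self, slope, intercept, concs):
        points = [(c, slope * c + intercept) for c in concs]
        curve = fit_standard_curve(points)
        assert curve.slope == pytest.approx(slope, rel=1e-6)
        assert curve.intercept == pytest.approx(intercept, abs=1e-6)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-9)


class TestInversion:
    curve = StandardCurve("gallic_acid", slope=0.002, intercept=0.0, r_squared=1.0)

    @pytest.mark.parametrize(
        "curve,a,dilution,expected",
        [
            (curve, 0.5, 1, 250.0),
            (curve, 0.5, 10, 2500.0),
            (StandardCurve("gallic_acid", 0.002, 0.01, 1.0), 0.41, 1, 200.0),
        ],
    )
    def test_examples(self, curve, a, dilution, expected):
        assert absorbance_to_concentration(curve, a, dilution) == pytest.approx(expected)

    def test_non_finite_rejected(self):
        with pytest.raises(FormatError):
            absorbance_to_concentration(self.curve, float("nan"))

    @given(
        conc=st.floats(0, 5000),
        slope=st.floats(1e-4, 1e-2),
        intercept=st.floats(-0.1, 0.1),
        dilution=st.floats(1, 500),
    )
    @settings(max_examples=100, deadline=None)
    def test_round_trip(self, conc, slope, intercept, dilution):
        curve = StandardCurve("trolox", slope, intercept, 1.0)
        a = slope * conc + intercept
        got = absorbance_to_concentration(curve, a, dilution)
        assert got == pytest.approx(dilution * conc, rel=1e-9, abs=1e-6)

    def test_monotone_in_absorbance(self):
        vals = [absorbance_to_concentration(self.curve, a) for a in (0.1, 0.2, 0.5)]
        assert vals == sorted(vals)
        assert vals[0] < vals[1] < vals[2]


class TestFrapEndpoint:
    def test_constant_trace_plateaus_at_first_read(self):
        ep = frap_endpoint([0, 1, 2], [0.3, 0.3, 0.3], delta_tol=0.005)
        assert ep.endpoint_au == 0.3
        assert ep.t_plateau == 0
        assert ep.converged

    def test_walks_consecutive_difference_rule(self):
        ep = frap_endpoint(
            [0, 1, 2, 3, 4], [0.10, 0.20, 0.28, 0.29, 0.29], delta_tol=0.02
        )
        assert ep.t_plateau == 3  # 4th read
        assert ep.endpoint_au == pytest.approx(0.29)
        assert ep.converged

    def test_non_convergence_returns_last_read(self):
        ep = frap_endpoint([0, 1, 2, 3], [0.1, 0.2, 0.3, 0.4], delta_tol=0.0)
        assert not ep.converged
        assert ep.endpoint_au == 0.4
        assert ep.t_plateau == 3

    def test_single_read_rejected(self):
        with pytest.raises(InsufficientDataError):
            frap_endpoint([0], [0.3])

    def test_non_monotone_times_rejected(self):
        with pytest.raises(FormatError):
            frap_endpoint([0, 2, 1], [0.1, 0.2, 0.3])
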