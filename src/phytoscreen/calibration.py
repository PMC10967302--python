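"""Standard-curve calibration for the cell-free assays.

Total phenolic content (Folin–Ciocalteu, 750 nm) is calibrated against
gallic acid and reported as gallic-acid equivalents (mg GAE/L of the
undiluted extract); ferric reducing antioxidant power (TPTZ/Fe3+, 593 nm)
against Trolox, reported as µmol TE/L. Both use an ordinary least-squares
line with a free intercept on blank-corrected absorbances — over the
working ranges of these assays the response is linear and the intercept
absorbs residual blank signal.

FRAP is read kinetically (every minute until the reaction stops); the
endpoint of each well is located by :func:`frap_endpoint`, which walks the
trace for the first read after which consecutive absorbance changes stay
below a plateau tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import (
    CalibrationError,
    DegenerateDesignError,
    FormatError,
    InsufficientDataError,
)


@dataclass(frozen=True)
class StandardCurve:
    """A fitted linear calibration ``absorbance = slope * conc + intercept``.

    ``slope`` is in AU per concentration unit (mg/L for gallic acid,
    µmol/L for Trolox); ``blank_mean`` records the blank absorbance that
    was subtracted from standards before fitting (and must likewise be
    subtracted from samples before inversion).
    """

    analyte: str  # "gallic_acid" or "trolox"
    slope: float
    intercept: float
    r_squared: float
    blank_mean: float = 0.0
    n_points: int = 0


@dataclass(frozen=True)
class FrapEndpoint:
    """Plateau read of one FRAP well."""

    endpoint_au: float
    t_plateau: float
    converged: bool


def fit_standard_curve(
    points: Sequence[tuple[float, float]],
    analyte: str = "gallic_acid",
    blank_mean: float = 0.0,
) -> StandardCurve:
    """Fit an OLS line to (concentration, blank-corrected absorbance) pairs.

    Raises
    ------
    DegenerateDesignError
        Fewer than two distinct concentrations.
    CalibrationError
        Fitted slope is not positive (signal must rise with concentration).
    """
    if analyte not in ("gallic_acid", "trolox"):
        raise FormatError(f"unknown analyte {analyte!r}")
    conc = np.asarray([p[0] for p in points], dtype=float)
    absb = np.asarray([p[1] for p in points], dtype=float)
    if not (np.isfinite(conc).all() and np.isfinite(absb).all()):
        raise FormatError("non-finite calibration point")
    if len(np.unique(conc)) < 2:
        raise DegenerateDesignError(
            "standard curve needs >= 2 distinct concentrations"
        )
    fit = stats.linregress(conc, absb)
    if fit.slope <= 0:
        raise CalibrationError(
            f"calibration slope must be positive, got {fit.slope:.4g}"
        )
    return StandardCurve(
        analyte=analyte,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        blank_mean=float(blank_mean),
        n_points=len(conc),
    )


def absorbance_to_concentration(
    curve: StandardCurve, a_sample: float, dilution_factor: float = 1.0
) -> float:
    """Invert the curve, scaling back to the undiluted extract.

    ``a_sample`` is the blank-corrected sample absorbance. Returns
    ``dilution_factor * (a_sample - intercept) / slope``; sub-blank
    signals yield negative concentrations, which are reported as-is so
    downstream statistics see unbiased values (callers may flag them).
    """
    if not math.isfinite(a_sample):
        raise FormatError(f"non-finite sample absorbance {a_sample!r}")
    if dilution_factor < 1:
        raise FormatError("dilution_factor must be >= 1")
    if curve.slope <= 0:
        raise CalibrationError("curve slope must be positive")
    return dilution_factor * (a_sample - curve.intercept) / curve.slope


def frap_endpoint(
    times: Sequence[float], absorbances: Sequence[float], delta_tol: float = 0.005
) -> FrapEndpoint:
    """Locate the reaction plateau of a kinetic FRAP trace.

    The plateau is the first read after which every consecutive
    absorbance change is below ``delta_tol`` (AU). A trace that is flat
    from the very first pair plateaus at the first read. If the trace is
    still moving at the last pair, ``converged`` is False and the last
    read is returned as the best available endpoint.
    """
    t = np.asarray(times, dtype=float)
    a = np.asarray(absorbances, dtype=float)
    if t.size != a.size:
        raise FormatError("times and absorbances differ in length")
    if t.size < 2:
        raise InsufficientDataError("FRAP endpoint needs >= 2 reads")
    if not np.all(np.diff(t) > 0):
        raise FormatError("times must be strictly increasing")
    diffs = np.abs(np.diff(a))
    below = diffs < delta_tol
    if not below[-1]:
        # still moving at the final pair: no plateau inside the window
        return FrapEndpoint(float(a[-1]), float(t[-1]), converged=False)
    # smallest k such that all consecutive diffs from pair k on are below tol
    not_below = np.nonzero(~below)[0]
    k = 0 if not_below.size == 0 else int(not_below[-1]) + 1
    idx = 0 if k == 0 else k + 1
    return FrapEndpoint(float(a[idx]), float(t[idx]), converged=True)
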