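"""DCF fluorescence kinetics: from raw time courses to normalized ROS %.

Intracellular ROS in AAPH-stressed Caco-2 cells is read as DCF
fluorescence at 0/15/30/60/90 min. The processing chain per well is

1. background correction — subtract the mean cell-free blank signal at
   each time point;
2. start-value normalization — divide the corrected trace by its own
   t=0 value, making traces dimensionless and insensitive to well-to-well
   loading differences;
3. area under the curve — trapezoidal integral of the relative trace
   over the actual read times;
4. two-anchor normalization — linear rescaling of the AUC so the AAPH
   stress-control mean maps to 100% and the untreated-control mean to 0%.

Values below 0% (stronger than full suppression of the stress increment)
and above 100% (pro-oxidant) are permitted and reported as-is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateAnchorError,
    InsufficientDataError,
    InvalidBaselineError,
    ScheduleError,
)
from .io import WellAddress


@dataclass
class KineticTrace:
    """One well's DCF time course and its derived quantities."""

    well: WellAddress | None
    sample_id: str | None
    times: np.ndarray
    f_raw: np.ndarray
    f_corrected: np.ndarray | None = None
    f_rel: np.ndarray | None = None
    auc_rel: float | None = None


@dataclass
class RosResult:
    """Per-sample normalized ROS summary (stress control = 100, untreated = 0)."""

    sample_id: str
    ros_pct: float
    sd: float
    n: int
    replicate_pcts: list[float] = field(default_factory=list)
    replicate_aucs: list[float] = field(default_factory=list)


def background_correct(
    times: np.ndarray, f_raw: np.ndarray, blank_mean_per_time: np.ndarray
) -> np.ndarray:
    """Subtract the per-time blank mean from a raw trace, elementwise.

    Raises
    ------
    ScheduleError
        Blank series does not cover the same time points.
    InvalidBaselineError
        Corrected fluorescence at t=0 is not positive; the well cannot be
        start-normalized and must be excluded (callers log the reason).
    """
    f_raw = np.asarray(f_raw, dtype=float)
    blank = np.asarray(blank_mean_per_time, dtype=float)
    if f_raw.shape != blank.shape or f_raw.shape != np.shape(times):
        raise ScheduleError(
            f"blank series shape {blank.shape} does not match trace "
            f"shape {f_raw.shape}"
        )
    corrected = f_raw - blank
    if corrected[0] <= 0:
        raise InvalidBaselineError(
            f"background-corrected baseline {corrected[0]:.4g} RFU is not positive"
        )
    return corrected


def auc_normalized(times: np.ndarray, f_corrected: np.ndarray) -> tuple[np.ndarray, float]:
    """Start-normalize a corrected trace and integrate it.

    Returns ``(f_rel, auc_rel)`` where ``f_rel(t) = f_corrected(t) /
    f_corrected(0)`` (so ``f_rel(0) == 1`` exactly) and ``auc_rel`` is the
    trapezoidal integral of ``f_rel`` over the actual read times.
    """
    t = np.asarray(times, dtype=float)
    f = np.asarray(f_corrected, dtype=float)
    if t.size < 2:
        raise InsufficientDataError("AUC needs >= 2 time points")
    if not np.all(np.diff(t) > 0):
        raise ScheduleError("times must be strictly increasing")
    if f[0] <= 0:
        raise InvalidBaselineError("corrected baseline must be positive")
    f_rel = f / f[0]
    auc_rel = float(np.trapezoid(f_rel, t))
    return f_rel, auc_rel


def normalize_two_anchor(
    auc_sample: float, auc_untreated_mean: float, auc_stress_mean: float
) -> float:
    """Map an AUC onto the 0% (untreated) … 100% (stress) scale.

    Raises :class:`DegenerateAnchorError` when the anchors coincide
    (stress induction failed on that plate).
    """
    span = auc_stress_mean - auc_untreated_mean
    if span == 0:
        raise DegenerateAnchorError(
            "stress and untreated AUC anchors are equal; no stress induction"
        )
    return 100.0 * (auc_sample - auc_untreated_mean) / span


def summarize_ros(
    sample_id: str,
    replicate_pcts,
    replicate_aucs=None,
) -> RosResult:
    """Mean and sample SD of replicate normalized percents for one sample.

    A single replicate yields sd 0 with n=1 (flagged by the count itself);
    replicate AUCs are retained for the Dunnett test.
    """
    pcts = [float(p) for p in replicate_pcts]
    if len(pcts) < 1:
        raise InsufficientDataError(f"no replicates for sample {sample_id!r}")
    mean = float(np.mean(pcts))
    sd = float(np.std(pcts, ddof=1)) if len(pcts) > 1 else 0.0
    return RosResult(
        sample_id=sample_id,
        ros_pct=mean,
        sd=sd,
        n=len(pcts),
        replicate_pcts=pcts,
        replicate_aucs=[float(a) for a in (replicate_aucs or [])],
    )
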