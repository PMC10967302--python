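"""Griess nitrite assay: absorbance to normalized NO % of the LPS control.

NO production by LPS-stimulated RAW264.7 macrophages is read as the
548 nm absorbance of the Griess azo product in the culture supernatant.
Readings are expressed relative to the LPS stress control (100%), with
the medium-only (DMEM) untreated control as the zero anchor — without a
zero anchor the reagent background would inflate every percentage, and
the two-anchor form deliberately parallels the ROS normalization.
Values above 100% indicate NO increase relative to the stress control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateAnchorError, FormatError, InsufficientDataError


@dataclass
class NoResult:
    """Per-sample normalized NO summary (LPS stress control = 100)."""

    sample_id: str
    no_pct: float
    sd: float
    n: int
    replicate_pcts: list[float] = field(default_factory=list)
    replicate_values: list[float] = field(default_factory=list)


def nitrite_percent(a_sample: float, a_stress_mean: float, a_blank_mean: float) -> float:
    """Normalize one Griess absorbance to percent of the LPS stress control.

    Returns ``100 * (a_sample - a_blank_mean) / (a_stress_mean -
    a_blank_mean)``. Raises :class:`DegenerateAnchorError` if the stress
    mean does not exceed the blank (no LPS induction).
    """
    if not all(map(math.isfinite, (a_sample, a_stress_mean, a_blank_mean))):
        raise FormatError("non-finite absorbance")
    span = a_stress_mean - a_blank_mean
    if span <= 0:
        raise DegenerateAnchorError(
            f"LPS stress mean {a_stress_mean:.4g} does not exceed blank "
            f"{a_blank_mean:.4g}; induction failed"
        )
    return 100.0 * (a_sample - a_blank_mean) / span


def summarize_no(sample_id: str, replicate_pcts, replicate_values=None) -> NoResult:
    """Mean and sample SD of replicate normalized NO percents for one sample."""
    pcts = [float(p) for p in replicate_pcts]
    if len(pcts) < 1:
        raise InsufficientDataError(f"no replicates for sample {sample_id!r}")
    mean = float(np.mean(pcts))
    sd = float(np.std(pcts, ddof=1)) if len(pcts) > 1 else 0.0
    return NoResult(
        sample_id=sample_id,
        no_pct=mean,
        sd=sd,
        n=len(pcts),
        replicate_pcts=pcts,
        replicate_values=[float(v) for v in (replicate_values or [])],
    )
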