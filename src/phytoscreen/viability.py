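"""Resazurin viability normalization and the cytotoxicity gate.

After each cell-based assay, metabolic reduction of resazurin to
fluorescent resorufin is read and expressed as percent of the untreated
control mean. Extracts whose mean viability falls strictly below the
threshold (default 80%) are considered cytotoxic and excluded from the
corresponding ROS or NO endpoint. Exclusion is per cell line: an extract
cytotoxic to RAW264.7 macrophages (NO assay) may still be evaluated in
Caco-2 cells (ROS assay), and vice versa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from .errors import DegenerateControlError, FormatError

CELL_LINES = ("caco2", "raw264_7")
DEFAULT_THRESHOLD_PCT = 80.0


@dataclass(frozen=True)
class ViabilityResult:
    """Mean viability of one extract in one cell line, with its gate flag."""

    sample_id: str
    cell_line: str
    viability_pct: float
    excluded: bool


def viability_percent(f_sample: float, f_control_mean: float) -> float:
    """Resorufin fluorescence as percent of the untreated-control mean."""
    if not (math.isfinite(f_sample) and math.isfinite(f_control_mean)):
        raise FormatError("non-finite fluorescence")
    if f_control_mean <= 0:
        raise DegenerateControlError(
            f"untreated-control mean {f_control_mean:.4g} RFU is not positive"
        )
    return 100.0 * f_sample / f_control_mean


def gate_cytotoxic(
    mean_viability: Mapping[str, float], threshold: float = DEFAULT_THRESHOLD_PCT
) -> dict[str, bool]:
    """Flag extracts whose mean viability is strictly below the threshold.

    Exactly 80.0% is retained ("below 80%" is strict); the gate is
    idempotent — re-applying it to an already-gated mapping changes
    nothing.
    """
    return {sid: float(v) < threshold for sid, v in mean_viability.items()}
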