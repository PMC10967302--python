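"""Synthetic screening-campaign generator with known ground truth.

Emulates a 375-extract library measured in five microplate assays (TPC,
FRAP, kinetic DCF ROS, Griess NO, resazurin viability), reproducing the
statistical structure the downstream analysis assumes:

* a latent phenolic content P, log-normal across extracts, drives both
  cell-free readouts: TPC is proportional to P and FRAP to P**gamma, each
  with independent log-normal assay scatter sized analytically so the
  TPC-FRAP Spearman correlation hits its target (default 0.857) in
  expectation;
* cellular endpoints follow a shared monotone link to P (more phenolic
  extracts suppress ROS/NO more) plus class-specific offsets for five
  latent selectivity classes — dual, NO-selective, ROS-selective,
  inactive, NO-increasing — whose default frequencies are calibrated so
  that on average ~34/375 extracts sit at ROS <= 70% and ~57/375 at
  NO <= 70%, ~40 increase NO, 3 are cytotoxic to Caco-2 and 15 to
  RAW264.7;
* DCF kinetics are linear in time, f(t) = F0 * (1 + R t), the simplest
  model consistent with an AUC readout (the analysis never assumes a
  kinetic form, so this mismatch is intentional and tests robustness);
* quercetin positive controls are emitted at 3.6% residual ROS
  (inhibition 0.964) and 66.5% residual NO, so the positive-control
  channel doubles as a pipeline sanity check;
* every well carries multiplicative measurement noise (default CV 2%)
  and each extract is plated in triplicate.

Everything is deterministic given the seed; identical config + seed
produce byte-identical CSV files.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import ROWS

QUERCETIN_ID = "QUERCETIN"

CLASSES = ("inactive", "dual", "no_selective", "ros_selective", "no_increasing")


def spearman_to_pearson(r_s: float) -> float:
    """Bivariate-normal Pearson rho giving Spearman r_s (Pearson's relation)."""
    return 2.0 * np.sin(np.pi * r_s / 6.0)


@dataclass
class SimConfig:
    """All knobs of the synthetic campaign (defaults = study conditions)."""

    n_extracts: int = 375
    seed: int = 0
    n_replicates: int = 3

    # latent phenolic content and cell-free scales
    tpc_median: float = 500.0  # mg GAE/L
    tpc_log_sigma: float = 0.9
    frap_per_tpc: float = 5.7  # µmol TE per mg GAE
    frap_exponent: float = 1.0
    rs_tpc_frap: float = 0.857  # target Spearman between TPC and FRAP
    # explicit assay log-scatter; None derives it from rs_tpc_frap
    cellfree_noise_sigma: float | None = None

    # cellular classes: frequencies and normalized-level offsets (percent)
    class_proportions: dict = field(
        default_factory=lambda: {
            "inactive": 0.727,
            "dual": 0.056,
            "no_selective": 0.075,
            "ros_selective": 0.035,
            "no_increasing": 0.107,
        }
    )
    class_ros_offset: dict = field(
        default_factory=lambda: {
            "inactive": 97.0,
            "dual": 52.0,
            "no_selective": 99.0,
            "ros_selective": 55.0,
            "no_increasing": 97.0,
        }
    )
    class_no_offset: dict = field(
        default_factory=lambda: {
            "inactive": 98.0,
            "dual": 48.0,
            "no_selective": 40.0,
            "ros_selective": 100.0,
            "no_increasing": 122.0,
        }
    )
    class_ros_sd: float = 10.0
    class_no_sd: float = 10.0
    # shared monotone link to standardized log-phenolic content (pct per SD)
    link_beta_ros: float = 8.0
    link_beta_no: float = 12.0

    p_cytotoxic_caco2: float = 3.0 / 375.0
    p_cytotoxic_raw: float = 15.0 / 375.0

    # measurement noise (CV, multiplicative) per assay
    noise_cv: dict = field(
        default_factory=lambda: {
            "tpc": 0.02,
            "frap": 0.02,
            "ros_dcf": 0.02,
            "no_griess": 0.02,
            "viability": 0.02,
        }
    )

    # standard series (plate-map concentrations) and true curve parameters
    gallic_standards: tuple = (0.0, 100.0, 200.0, 300.0, 400.0, 500.0)  # mg/L
    trolox_standards: tuple = (0.0, 250.0, 500.0, 750.0, 1000.0, 1250.0)  # µmol/L
    tpc_slope: float = 0.002  # AU per mg/L
    tpc_blank: float = 0.04  # AU
    frap_slope: float = 0.001  # AU per µmol/L
    frap_blank: float = 0.03  # AU
    tpc_dilution: float = 17.0
    frap_dilution: float = 50.0

    # FRAP kinetics (first-order approach to plateau, read every minute)
    frap_rate: float = 0.5  # 1/min
    frap_read_minutes: int = 15

    # DCF kinetics
    read_schedule: tuple = (0.0, 15.0, 30.0, 60.0, 90.0)
    dcf_f0: float = 1000.0  # RFU at t=0 (typical loading)
    dcf_loading_sigma: float = 0.05  # log-sd of per-well loading
    dcf_r_basal: float = 0.005  # 1/min, untreated slope
    dcf_r_stress: float = 0.040  # 1/min, AAPH increment at zero inhibition
    dcf_blank: float = 50.0  # RFU cell-free background
    quercetin_ros_inhibition: float = 0.964

    # Griess
    griess_blank: float = 0.05  # AU medium/reagent background
    griess_span: float = 0.60  # AU at full LPS induction
    quercetin_no_level: float = 0.665  # fraction of stress control

    # viability
    viab_f0: float = 20000.0  # RFU untreated resorufin signal
    viab_healthy_mean: float = 1.0
    viab_healthy_sd: float = 0.02
    viab_cytotoxic_mean: float = 0.60
    viab_cytotoxic_sd: float = 0.03

    # plate layouts
    extracts_per_plate_cellfree: int = 25
    extracts_per_plate_cell: int = 28

    def validate(self) -> None:
        if self.n_extracts < 1 or self.n_replicates < 1:
            raise ConfigError("n_extracts and n_replicates must be >= 1")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"class proportions must sum to 1, got {total}")
        if any(p < 0 or p > 1 for p in self.class_proportions.values()):
            raise ConfigError("class proportions must lie in [0, 1]")
        if set(self.class_proportions) != set(CLASSES):
            raise ConfigError(f"class proportions must cover {CLASSES}")
        if not (-1.0 < self.rs_tpc_frap < 1.0):
            raise ConfigError("rs_tpc_frap must lie strictly in (-1, 1)")
        if spearman_to_pearson(abs(self.rs_tpc_frap)) >= 1.0:
            raise ConfigError("rs_tpc_frap target is infeasible")
        for p in (self.p_cytotoxic_caco2, self.p_cytotoxic_raw):
            if not (0.0 <= p <= 1.0):
                raise ConfigError("cytotoxic probabilities must lie in [0, 1]")


def _assay_noise_sigma(config: SimConfig) -> float:
    """Log-scale scatter per cell-free assay hitting the TPC-FRAP target.

    With log P ~ N(mu, sig_p^2) and independent log-normal assay scatter
    of variance sig_n^2 on each of TPC and FRAP (gamma = 1), the Pearson
    correlation of the logs is rho = sig_p^2 / (sig_p^2 + sig_n^2);
    solving rho = 2 sin(pi r_s / 6) for sig_n is a closed form, so the
    calibration never looks at generated data.
    """
    if config.cellfree_noise_sigma is not None:
        return float(config.cellfree_noise_sigma)
    rho = spearman_to_pearson(config.rs_tpc_frap)
    return config.tpc_log_sigma * np.sqrt(1.0 / rho - 1.0)


def simulate_truth(config: SimConfig) -> pd.DataFrame:
    """Draw the per-extract ground truth table (deterministic given seed)."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 101]))
    n = config.n_extracts
    ids = [f"EXT{i + 1:04d}" for i in range(n)]

    z = rng.standard_normal(n)  # standardized log phenolic content
    phenolic = config.tpc_median * np.exp(config.tpc_log_sigma * z)
    sig_n = _assay_noise_sigma(config)
    true_tpc = phenolic * np.exp(sig_n * rng.standard_normal(n))
    true_frap = (
        config.frap_per_tpc
        * config.tpc_median ** (1.0 - config.frap_exponent)
        * phenolic**config.frap_exponent
        * np.exp(sig_n * rng.standard_normal(n))
    )

    classes = rng.choice(
        CLASSES,
        size=n,
        p=[config.class_proportions[c] for c in CLASSES],
    )
    ros_off = np.array([config.class_ros_offset[c] for c in classes])
    no_off = np.array([config.class_no_offset[c] for c in classes])
    true_ros_pct = np.clip(
        ros_off - config.link_beta_ros * z + config.class_ros_sd * rng.standard_normal(n),
        2.0,
        115.0,
    )
    true_no_pct = np.clip(
        no_off - config.link_beta_no * z + config.class_no_sd * rng.standard_normal(n),
        2.0,
        160.0,
    )

    cytotoxic_caco2 = rng.random(n) < config.p_cytotoxic_caco2
    cytotoxic_raw = rng.random(n) < config.p_cytotoxic_raw

    return pd.DataFrame(
        {
            "extract_id": ids,
            "phenolic_latent": phenolic,
            "true_tpc": true_tpc,
            "true_frap": true_frap,
            "true_ros_pct": true_ros_pct,
            "true_no_pct": true_no_pct,
            "ros_inhibition": 1.0 - true_ros_pct / 100.0,
            "no_inhibition": 1.0 - true_no_pct / 100.0,
            "selectivity_truth": classes,
            "cytotoxic_caco2": cytotoxic_caco2,
            "cytotoxic_raw": cytotoxic_raw,
        }
    )


# ---------------------------------------------------------------------------
# plate emission


def _well_order() -> list[tuple[str, int]]:
    return [(r, c) for r in ROWS for c in range(1, 13)]


def _chunk(seq, size):
    for i in range(0, len(seq), size):
        yield seq[i : i + size]


def _noisy(rng, value, cv):
    return value * (1.0 + cv * rng.standard_normal())


class _PlateWriter:
    """Accumulates plate-map and measurement rows for one assay file pair."""

    def __init__(self, assay: str):
        self.assay = assay
        self.map_rows: list[list] = []
        self.meas_rows: list[list] = []

    def add(self, plate_id, row, col, role, conc, sample, readings):
        self.map_rows.append(
            [
                plate_id,
                row,
                col,
                role,
                "" if conc is None else repr(float(conc)),
                sample or "",
            ]
        )
        for t, v in readings:
            self.meas_rows.append(
                [
                    plate_id,
                    row,
                    col,
                    self.assay,
                    "" if t is None else repr(float(t)),
                    repr(float(v)),
                ]
            )

    def write(self, outdir: Path, stem: str) -> tuple[Path, Path]:
        map_path = outdir / f"plate_map_{stem}.csv"
        meas_path = outdir / f"measurements_{stem}.csv"
        with open(map_path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["plate_id", "row", "col", "role", "standard_conc", "sample_id"])
            w.writerows(self.map_rows)
        with open(meas_path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["plate_id", "row", "col", "assay", "time_min", "value"])
            w.writerows(self.meas_rows)
        return map_path, meas_path


def _emit_cellfree(truth, config, rng, assay: str) -> _PlateWriter:
    """TPC or FRAP plates: blanks, a standard series, extracts in triplicate."""
    is_tpc = assay == "tpc"
    standards = config.gallic_standards if is_tpc else config.trolox_standards
    slope = config.tpc_slope if is_tpc else config.frap_slope
    blank = config.tpc_blank if is_tpc else config.frap_blank
    dilution = config.tpc_dilution if is_tpc else config.frap_dilution
    truth_col = "true_tpc" if is_tpc else "true_frap"
    cv = config.noise_cv[assay]
    writer = _PlateWriter(assay)

    def absorbance(conc_in_well):
        return blank + slope * conc_in_well

    def readings_for(conc_in_well):
        if is_tpc:
            return [(None, _noisy(rng, absorbance(conc_in_well), cv))]
        # kinetic FRAP: first-order approach to the plateau, read every minute
        times = np.arange(config.frap_read_minutes + 1, dtype=float)
        amp = slope * conc_in_well
        trace = config.frap_blank + amp * (1.0 - np.exp(-config.frap_rate * times))
        trace = trace * (1.0 + cv * rng.standard_normal(times.size))
        return list(zip(times, trace))

    extracts = list(truth.itertuples(index=False))
    for p, batch in enumerate(_chunk(extracts, config.extracts_per_plate_cellfree), 1):
        plate_id = f"{assay.upper()}{p:02d}"
        wells = iter(_well_order())
        for _ in range(config.n_replicates):
            r, c = next(wells)
            writer.add(plate_id, r, c, "blank", None, None, readings_for(0.0))
        for conc in standards:
            for _ in range(config.n_replicates):
                r, c = next(wells)
                writer.add(
                    plate_id, r, c, "standard", conc, None, readings_for(conc)
                )
        for ext in batch:
            conc_in_well = getattr(ext, truth_col) / dilution
            for _ in range(config.n_replicates):
                r, c = next(wells)
                writer.add(
                    plate_id,
                    r,
                    c,
                    "treatment",
                    None,
                    ext.extract_id,
                    readings_for(conc_in_well),
                )
    return writer


def _emit_ros(truth, config, rng) -> _PlateWriter:
    """DCF plates: blanks, untreated, AAPH stress, quercetin, extracts."""
    cv = config.noise_cv["ros_dcf"]
    times = np.asarray(config.read_schedule, dtype=float)
    writer = _PlateWriter("ros_dcf")

    def trace_for(inhibition, *, cellular=True):
        if not cellular:
            base = config.dcf_blank * np.ones_like(times)
        else:
            f0 = config.dcf_f0 * np.exp(
                config.dcf_loading_sigma * rng.standard_normal()
            )
            rate = config.dcf_r_basal + config.dcf_r_stress * (1.0 - inhibition)
            base = config.dcf_blank + f0 * (1.0 + rate * times)
        noisy = base * (1.0 + cv * rng.standard_normal(times.size))
        return list(zip(times, noisy))

    extracts = list(truth.itertuples(index=False))
    for p, batch in enumerate(_chunk(extracts, config.extracts_per_plate_cell), 1):
        plate_id = f"ROS{p:02d}"
        wells = iter(_well_order())
        for _ in range(config.n_replicates):
            r, c = next(wells)
            writer.add(plate_id, r, c, "blank", None, None, trace_for(0, cellular=False))
        for _ in range(config.n_replicates):
            r, c = next(wells)
            # untreated: basal slope only <=> full suppression of the stress term
            writer.add(plate_id, r, c, "untreated_control", None, None, trace_for(1.0))
        for _ in range(config.n_replicates):
            r, c = next(wells)
            writer.add(plate_id, r, c, "stress_control", None, None, trace_for(0.0))
        for _ in range(config.n_replicates):
            r, c = next(wells)
            writer.add(
                plate_id,
                r,
                c,
                "positive_control",
                None,
                QUERCETIN_ID,
                trace_for(config.quercetin_ros_inhibition),
            )
        for ext in batch:
            for _ in range(config.n_replicates):
                r, c = next(wells)
                writer.add(
                    plate_id,
                    r,
                    c,
                    "treatment",
                    None,
                    ext.extract_id,
                    trace_for(ext.ros_inhibition),
                )
    return writer


def _emit_no(truth, config, rng) -> _PlateWriter:
    """Griess plates: untreated (DMEM), LPS stress, quercetin, extracts."""
    cv = config.noise_cv["no_griess"]
    writer = _PlateWriter("no_griess")

    def reading_for(no_level):
        a = config.griess_blank + config.griess_span * no_level
        return [(None, _noisy(rng, a, cv))]

    extracts = list(truth.itertuples(index=False))
    for p, batch in enumerate(_chunk(extracts, config.extracts_per_plate_cell), 1):
        plate_id = f"NO{p:02d}"
        wells = iter(_well_order())
        for _ in range(config.n_replicates):
            r, c = next(wells)
            writer.add(plate_id, r, c, "untreated_control", None, None, reading_for(0.0))
        for _ in range(config.n_replicates):
            r, c = next(wells)
            writer.add(plate_id, r, c, "stress_control", None, None, reading_for(1.0))
        for _ in range(config.n_replicates):
            r, c = next(wells)
            writer.add(
                plate_id,
                r,
                c,
                "positive_control",
                None,
                QUERCETIN_ID,
                reading_for(config.quercetin_no_level),
            )
        for ext in batch:
            for _ in range(config.n_replicates):
                r, c = next(wells)
                writer.add(
                    plate_id,
                    r,
                    c,
                    "treatment",
                    None,
                    ext.extract_id,
                    reading_for(1.0 - ext.no_inhibition),
                )
    return writer


def _emit_viability(truth, config, rng, cell_line: str) -> _PlateWriter:
    """Resazurin plates mirroring the cell-assay layout, per cell line."""
    cv = config.noise_cv["viability"]
    cyto_col = "cytotoxic_caco2" if cell_line == "caco2" else "cytotoxic_raw"
    writer = _PlateWriter("viability")

    def reading_for(viability):
        return [(None, _noisy(rng, config.viab_f0 * viability, cv))]

    extracts = list(truth.itertuples(index=False))
    for p, batch in enumerate(_chunk(extracts, config.extracts_per_plate_cell), 1):
        plate_id = f"VIA{cell_line.upper()[0]}{p:02d}"
        wells = iter(_well_order())
        for _ in range(config.n_replicates):
            r, c = next(wells)
            v = rng.normal(config.viab_healthy_mean, config.viab_healthy_sd)
            writer.add(plate_id, r, c, "untreated_control", None, None, reading_for(v))
        for ext in batch:
            if getattr(ext, cyto_col):
                v_true = rng.normal(config.viab_cytotoxic_mean, config.viab_cytotoxic_sd)
            else:
                v_true = rng.normal(config.viab_healthy_mean, config.viab_healthy_sd)
            v_true = max(v_true, 0.0)
            for _ in range(config.n_replicates):
                r, c = next(wells)
                writer.add(
                    plate_id,
                    r,
                    c,
                    "treatment",
                    None,
                    ext.extract_id,
                    reading_for(v_true),
                )
    return writer


def emit_raw_plates(truth: pd.DataFrame, config: SimConfig, outdir) -> dict[str, dict]:
    """Write plate maps and measurement files for all five assays.

    Returns a manifest ``{assay_key: {"plate_map": path, "measurements":
    path}}`` with keys tpc, frap, ros, no, viability_caco2,
    viability_raw; also writes ``truth.csv``.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seq = np.random.SeedSequence([int(config.seed), 202])
    rngs = [np.random.default_rng(s) for s in seq.spawn(6)]

    writers = {
        "tpc": _emit_cellfree(truth, config, rngs[0], "tpc"),
        "frap": _emit_cellfree(truth, config, rngs[1], "frap"),
        "ros": _emit_ros(truth, config, rngs[2]),
        "no": _emit_no(truth, config, rngs[3]),
        "viability_caco2": _emit_viability(truth, config, rngs[4], "caco2"),
        "viability_raw": _emit_viability(truth, config, rngs[5], "raw264_7"),
    }
    manifest: dict[str, dict] = {}
    for stem, writer in writers.items():
        map_path, meas_path = writer.write(outdir, stem)
        manifest[stem] = {"plate_map": str(map_path), "measurements": str(meas_path)}
    truth.to_csv(outdir / "truth.csv", index=False)
    return manifest


def simulate_campaign(config: SimConfig, outdir) -> tuple[pd.DataFrame, dict]:
    """Convenience: draw the truth and emit all raw plate files."""
    truth = simulate_truth(config)
    manifest = emit_raw_plates(truth, config, outdir)
    return truth, manifest


def null_config(config: SimConfig | None = None, **overrides) -> SimConfig:
    """A copy of the config with all true effects switched off.

    Every extract is inactive with offsets at exactly 100% and no link to
    phenolic content — used for type-I-error calibration runs.
    """
    base = config or SimConfig()
    flat = {c: 100.0 for c in CLASSES}
    return replace(
        base,
        class_proportions={c: (1.0 if c == "inactive" else 0.0) for c in CLASSES},
        class_ros_offset=dict(flat),
        class_no_offset=dict(flat),
        class_ros_sd=0.0,
        class_no_sd=0.0,
        link_beta_ros=0.0,
        link_beta_no=0.0,
        p_cytotoxic_caco2=0.0,
        p_cytotoxic_raw=0.0,
        **overrides,
    )
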