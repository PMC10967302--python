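"""End-to-end campaign orchestration.

``run_screen`` chains calibrate -> normalize -> gate -> call -> classify
-> correlate over whatever subset of the five assays is configured, and
writes ``results.csv`` (fixed column order), ``correlations.csv`` and a
JSON report mirroring the campaign-level counts (significant decreases
and increases, >= 30% reductions, viability exclusions, selectivity
class sizes).

Conventions:

* every plate carries its own controls; calibration curves, ROS/NO
  anchors and Dunnett families are all per plate;
* the viability gate is applied per cell line before hit calling — a
  gated extract keeps its measured values in the results table but
  receives no significance call, is marked excluded and drops out of the
  correlations for that endpoint;
* correlations use per-extract means over pairwise-complete,
  non-excluded extracts, so the reported n per pair reflects exactly the
  extracts passing the gates involved.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import calibration as calib
from . import griess, ros, viability
from . import stats as screen_stats
from .errors import (
    DegenerateAnchorError,
    InsufficientDataError,
    InvalidBaselineError,
)
from .io import (
    ExtractResult,
    MeasurementTable,
    read_measurements,
    read_plate_map,
    write_results,
)
from .simulate import QUERCETIN_ID

logger = logging.getLogger("phytoscreen")

ASSAY_KEYS = ("tpc", "frap", "ros", "no", "viability_caco2", "viability_raw")


@dataclass
class RunConfig:
    """Paths and analysis parameters of one screening run.

    ``files`` maps assay keys (tpc, frap, ros, no, viability_caco2,
    viability_raw) to ``{"plate_map": path, "measurements": path}``; any
    assay may be omitted and downstream outputs degrade gracefully.
    """

    files: dict = field(default_factory=dict)
    outdir: str | None = None
    tpc_dilution: float = 17.0
    frap_dilution: float = 50.0
    frap_delta_tol: float = 0.005  # AU, FRAP plateau tolerance
    viability_threshold: float = 80.0  # percent
    alpha: float = 0.05
    read_schedule: tuple = (0.0, 15.0, 30.0, 60.0, 90.0)

    @classmethod
    def from_manifest(cls, manifest: dict, **kwargs) -> "RunConfig":
        """Build a config from :func:`phytoscreen.simulate.emit_raw_plates` output."""
        return cls(files={k: dict(v) for k, v in manifest.items()}, **kwargs)

    def load(self, key: str) -> MeasurementTable | None:
        entry = self.files.get(key)
        if entry is None:
            return None
        plate_map = read_plate_map(entry["plate_map"])
        return read_measurements(
            entry["measurements"], plate_map, read_schedule=self.read_schedule
        )


@dataclass
class ScreenResult:
    results: list[ExtractResult]
    correlations: list[screen_stats.CorrelationResult]
    report: dict
    curves: dict = field(default_factory=dict)
    hit_calls: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# per-assay stages


def _analyze_cellfree(
    table: MeasurementTable, analyte: str, dilution: float, delta_tol: float
) -> tuple[dict[str, float], dict[str, calib.StandardCurve]]:
    """Calibrated concentrations per extract for TPC or FRAP.

    FRAP wells are kinetic: each well is reduced to its plateau
    absorbance first. Curves are fitted per plate on blank-corrected
    standard means; sample wells are inverted against their own plate's
    curve and averaged per extract.
    """
    frame = table.frame
    kinetic = table.assay == "frap"
    per_extract: dict[str, list[float]] = {}
    curves: dict[str, calib.StandardCurve] = {}

    for plate_id, plate in frame.groupby("plate_id"):
        if kinetic:
            endpoint = {}
            for (row, col), well in plate.groupby(["row", "col"]):
                well = well.sort_values("time_min")
                ep = calib.frap_endpoint(
                    well["time_min"].to_numpy(),
                    well["value"].to_numpy(),
                    delta_tol=delta_tol,
                )
                endpoint[(row, col)] = ep.endpoint_au
            wells = (
                plate.drop_duplicates(["row", "col"])
                .assign(
                    value=lambda df: [
                        endpoint[(r, c)] for r, c in zip(df["row"], df["col"])
                    ]
                )
            )
        else:
            wells = plate

        blank_mean = float(wells.loc[wells["role"] == "blank", "value"].mean())
        if np.isnan(blank_mean):
            blank_mean = 0.0
            logger.warning("plate %s: no blank wells for %s", plate_id, table.assay)
        std = wells[wells["role"] == "standard"]
        points = [
            (float(conc), float(grp["value"].mean()) - blank_mean)
            for conc, grp in std.groupby("standard_conc")
        ]
        curve = calib.fit_standard_curve(points, analyte=analyte, blank_mean=blank_mean)
        curves[str(plate_id)] = curve

        treated = wells[wells["role"] == "treatment"]
        for sid, grp in treated.groupby("sample_id"):
            concs = [
                calib.absorbance_to_concentration(curve, float(v) - blank_mean, dilution)
                for v in grp["value"]
            ]
            per_extract.setdefault(str(sid), []).extend(concs)

    means = {sid: float(np.mean(v)) for sid, v in per_extract.items()}
    return means, curves


def _analyze_ros(table: MeasurementTable) -> tuple[dict, dict, list]:
    """Normalized ROS percents per sample plus per-plate Dunnett families.

    Returns ``(results, families, excluded_wells)`` where ``families``
    maps plate id to ``(control_pcts, {sample_id: pcts})`` and
    ``excluded_wells`` lists wells dropped for invalid baselines.
    """
    frame = table.frame
    per_sample: dict[str, list[float]] = {}
    per_sample_auc: dict[str, list[float]] = {}
    families: dict[str, tuple[list[float], dict[str, list[float]]]] = {}
    excluded_wells: list[str] = []

    for plate_id, plate in frame.groupby("plate_id"):
        blanks = plate[plate["role"] == "blank"]
        times_ref = None
        blank_mean = None
        if not blanks.empty:
            piv = blanks.pivot_table(index="time_min", values="value", aggfunc="mean")
            times_ref = piv.index.to_numpy(dtype=float)
            blank_mean = piv["value"].to_numpy(dtype=float)
        else:
            logger.warning(
                "plate %s: no cell-free blanks; skipping background correction "
                "(shared offsets cancel only approximately)",
                plate_id,
            )

        aucs: dict[tuple, tuple[str, str | None, float]] = {}
        cellular = plate[plate["role"] != "blank"]
        for (row, col), well in cellular.groupby(["row", "col"]):
            well = well.sort_values("time_min")
            times = well["time_min"].to_numpy(dtype=float)
            raw = well["value"].to_numpy(dtype=float)
            role = well["role"].iloc[0]
            sid = well["sample_id"].iloc[0]
            try:
                if blank_mean is not None:
                    if times_ref is None or not np.array_equal(times, times_ref):
                        # blank schedule must cover the well's reads
                        corrected = ros.background_correct(
                            times, raw, np.interp(times, times_ref, blank_mean)
                        )
                    else:
                        corrected = ros.background_correct(times, raw, blank_mean)
                else:
                    corrected = raw
                _, auc = ros.auc_normalized(times, corrected)
            except (InvalidBaselineError, InsufficientDataError) as exc:
                excluded_wells.append(f"{plate_id}:{row}{col} ({exc})")
                logger.info("excluding well %s:%s%s: %s", plate_id, row, col, exc)
                continue
            aucs[(row, col)] = (role, None if sid is None or sid != sid else str(sid), auc)

        untreated = [a for role, _, a in aucs.values() if role == "untreated_control"]
        stress = [a for role, _, a in aucs.values() if role == "stress_control"]
        if not untreated or not stress:
            raise DegenerateAnchorError(
                f"plate {plate_id}: missing stress or untreated controls"
            )
        u_mean, s_mean = float(np.mean(untreated)), float(np.mean(stress))

        control_pcts: list[float] = []
        fam_treat: dict[str, list[float]] = {}
        for role, sid, auc in aucs.values():
            pct = ros.normalize_two_anchor(auc, u_mean, s_mean)
            if role == "stress_control":
                control_pcts.append(pct)
            elif role in ("treatment", "positive_control") and sid:
                per_sample.setdefault(sid, []).append(pct)
                per_sample_auc.setdefault(sid, []).append(auc)
                fam_treat.setdefault(sid, []).append(pct)
        families[str(plate_id)] = (control_pcts, fam_treat)

    results = {
        sid: ros.summarize_ros(sid, pcts, per_sample_auc[sid])
        for sid, pcts in per_sample.items()
    }
    return results, families, excluded_wells


def _analyze_no(table: MeasurementTable) -> tuple[dict, dict]:
    """Normalized NO percents per sample plus per-plate Dunnett families."""
    frame = table.frame
    per_sample: dict[str, list[float]] = {}
    per_sample_raw: dict[str, list[float]] = {}
    families: dict[str, tuple[list[float], dict[str, list[float]]]] = {}

    for plate_id, plate in frame.groupby("plate_id"):
        untreated = plate.loc[plate["role"] == "untreated_control", "value"]
        stress = plate.loc[plate["role"] == "stress_control", "value"]
        if untreated.empty or stress.empty:
            raise DegenerateAnchorError(
                f"plate {plate_id}: missing stress or untreated controls"
            )
        blank_mean = float(untreated.mean())
        stress_mean = float(stress.mean())

        control_pcts = [
            griess.nitrite_percent(float(v), stress_mean, blank_mean) for v in stress
        ]
        fam_treat: dict[str, list[float]] = {}
        mask = plate["role"].isin(["treatment", "positive_control"])
        for sid, grp in plate[mask].groupby("sample_id"):
            pcts = [
                griess.nitrite_percent(float(v), stress_mean, blank_mean)
                for v in grp["value"]
            ]
            sid = str(sid)
            per_sample.setdefault(sid, []).extend(pcts)
            per_sample_raw.setdefault(sid, []).extend(
                float(v) - blank_mean for v in grp["value"]
            )
            fam_treat[sid] = pcts
        families[str(plate_id)] = (control_pcts, fam_treat)

    results = {
        sid: griess.summarize_no(sid, pcts, per_sample_raw[sid])
        for sid, pcts in per_sample.items()
    }
    return results, families


def _analyze_viability(
    table: MeasurementTable, cell_line: str, threshold: float
) -> dict[str, viability.ViabilityResult]:
    frame = table.frame
    per_sample: dict[str, list[float]] = {}
    for plate_id, plate in frame.groupby("plate_id"):
        ctrl = plate.loc[plate["role"] == "untreated_control", "value"]
        if ctrl.empty:
            raise DegenerateAnchorError(f"plate {plate_id}: missing untreated controls")
        ctrl_mean = float(ctrl.mean())
        for sid, grp in plate[plate["role"] == "treatment"].groupby("sample_id"):
            pcts = [viability.viability_percent(float(v), ctrl_mean) for v in grp["value"]]
            per_sample.setdefault(str(sid), []).extend(pcts)
    means = {sid: float(np.mean(p)) for sid, p in per_sample.items()}
    flags = viability.gate_cytotoxic(means, threshold=threshold)
    return {
        sid: viability.ViabilityResult(sid, cell_line, means[sid], flags[sid])
        for sid in means
    }


def _family_pvalues(families: dict) -> dict[str, float]:
    """Dunnett-adjusted p per sample, one family per plate."""
    p_adj: dict[str, float] = {}
    for _plate_id, (control_pcts, treat) in families.items():
        if not treat:
            continue
        p_adj.update(screen_stats.dunnett_test(control_pcts, treat))
    return p_adj


# ---------------------------------------------------------------------------
# campaign


def run_screen(config: RunConfig) -> ScreenResult:
    """Run every configured stage and assemble per-extract results.

    Raises :class:`DegenerateAnchorError` (naming the plate) when a
    cell-based plate lacks its stress or untreated controls.
    """
    tpc_tbl = config.load("tpc")
    frap_tbl = config.load("frap")
    ros_tbl = config.load("ros")
    no_tbl = config.load("no")
    via_caco2_tbl = config.load("viability_caco2")
    via_raw_tbl = config.load("viability_raw")

    curves: dict[str, dict] = {}
    tpc_means: dict[str, float] = {}
    frap_means: dict[str, float] = {}
    if tpc_tbl is not None and len(tpc_tbl):
        tpc_means, curves["tpc"] = _analyze_cellfree(
            tpc_tbl, "gallic_acid", config.tpc_dilution, config.frap_delta_tol
        )
    if frap_tbl is not None and len(frap_tbl):
        frap_means, curves["frap"] = _analyze_cellfree(
            frap_tbl, "trolox", config.frap_dilution, config.frap_delta_tol
        )

    via_caco2 = (
        _analyze_viability(via_caco2_tbl, "caco2", config.viability_threshold)
        if via_caco2_tbl is not None and len(via_caco2_tbl)
        else {}
    )
    via_raw = (
        _analyze_viability(via_raw_tbl, "raw264_7", config.viability_threshold)
        if via_raw_tbl is not None and len(via_raw_tbl)
        else {}
    )

    ros_results: dict[str, ros.RosResult] = {}
    ros_excluded_wells: list[str] = []
    ros_calls: dict[str, screen_stats.HitCall] = {}
    if ros_tbl is not None and len(ros_tbl):
        ros_results, ros_families, ros_excluded_wells = _analyze_ros(ros_tbl)
        p_ros = _family_pvalues(ros_families)
        gated = {
            sid: res.ros_pct
            for sid, res in ros_results.items()
            if not (sid in via_caco2 and via_caco2[sid].excluded)
        }
        ros_calls = screen_stats.call_hits(
            gated, p_ros, endpoint="ros", alpha=config.alpha
        )

    no_results: dict[str, griess.NoResult] = {}
    no_calls: dict[str, screen_stats.HitCall] = {}
    if no_tbl is not None and len(no_tbl):
        no_results, no_families = _analyze_no(no_tbl)
        p_no = _family_pvalues(no_families)
        gated = {
            sid: res.no_pct
            for sid, res in no_results.items()
            if not (sid in via_raw and via_raw[sid].excluded)
        }
        no_calls = screen_stats.call_hits(gated, p_no, endpoint="no", alpha=config.alpha)

    # assemble per-extract rows (positive control reported separately)
    extract_ids = sorted(
        (set(tpc_means) | set(frap_means) | set(ros_results) | set(no_results))
        - {QUERCETIN_ID}
    )
    results: list[ExtractResult] = []
    for sid in extract_ids:
        rr = ros_results.get(sid)
        nr = no_results.get(sid)
        vc = via_caco2.get(sid)
        vr = via_raw.get(sid)
        excl_ros = vc.excluded if vc is not None else (False if rr else None)
        excl_no = vr.excluded if vr is not None else (False if nr else None)
        rcall = ros_calls.get(sid)
        ncall = no_calls.get(sid)
        sel = screen_stats.classify_selectivity(
            sid,
            nr.no_pct if nr else None,
            rr.ros_pct if rr else None,
            ncall,
            rcall,
            excluded_no=bool(excl_no),
            excluded_ros=bool(excl_ros),
        )
        results.append(
            ExtractResult(
                extract_id=sid,
                tpc_gae_mg_L=tpc_means.get(sid),
                frap_te_umol_L=frap_means.get(sid),
                ros_pct=rr.ros_pct if rr else None,
                ros_sd=rr.sd if rr else None,
                no_pct=nr.no_pct if nr else None,
                no_sd=nr.sd if nr else None,
                viability_caco2_pct=vc.viability_pct if vc else None,
                viability_raw_pct=vr.viability_pct if vr else None,
                excluded_ros=excl_ros,
                excluded_no=excl_no,
                sig_ros=rcall.direction if rcall else None,
                sig_no=ncall.direction if ncall else None,
                reduction30_ros=rcall.reduction30 if rcall else None,
                reduction30_no=ncall.reduction30 if ncall else None,
                selectivity=sel.selectivity
                if (rr is not None or nr is not None)
                else None,
            )
        )

    correlations = _correlate(results)
    report = _build_report(
        results, correlations, ros_results, no_results, ros_excluded_wells, curves
    )

    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_results(results, outdir / "results.csv")
        with open(outdir / "correlations.csv", "w", encoding="utf-8") as fh:
            fh.write("pair,r_s,p_value,n\n")
            for c in correlations:
                fh.write(f"{c.pair[0]}_{c.pair[1]},{c.r_s!r},{c.p_value!r},{c.n}\n")
        with open(outdir / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2)

    return ScreenResult(
        results=results,
        correlations=correlations,
        report=report,
        curves=curves,
        hit_calls={"ros": ros_calls, "no": no_calls},
    )


def _correlate(results: list[ExtractResult]) -> list[screen_stats.CorrelationResult]:
    """Endpoint-pair Spearman correlations on gated, pairwise-complete means."""

    def series(endpoint):
        vals = {}
        for r in results:
            if endpoint == "tpc":
                v = r.tpc_gae_mg_L
            elif endpoint == "frap":
                v = r.frap_te_umol_L
            elif endpoint == "ros":
                v = r.ros_pct if not r.excluded_ros else None
            else:
                v = r.no_pct if not r.excluded_no else None
            if v is not None:
                vals[r.extract_id] = v
        return vals

    available = {e: series(e) for e in ("tpc", "frap", "ros", "no")}
    pairs = [
        ("tpc", "frap"),
        ("no", "ros"),
        ("tpc", "ros"),
        ("frap", "ros"),
        ("tpc", "no"),
        ("frap", "no"),
    ]
    out = []
    for a, b in pairs:
        xa, xb = available[a], available[b]
        ids = sorted(set(xa) & set(xb))
        if len(ids) < 3:
            continue
        out.append(
            screen_stats.spearman(
                [xa[i] for i in ids], [xb[i] for i in ids], pair=(a, b)
            )
        )
    return out


def _build_report(
    results, correlations, ros_results, no_results, ros_excluded_wells, curves
) -> dict:
    def count(pred):
        return sum(1 for r in results if pred(r))

    sel_counts: dict[str, int] = {}
    for r in results:
        if r.selectivity:
            sel_counts[r.selectivity] = sel_counts.get(r.selectivity, 0) + 1

    report = {
        "n_extracts": len(results),
        "ros": {
            "n_measured": count(lambda r: r.ros_pct is not None),
            "n_excluded_cytotoxic": count(lambda r: r.excluded_ros is True),
            "n_significant_decrease": count(lambda r: r.sig_ros == "decrease"),
            "n_significant_increase": count(lambda r: r.sig_ros == "increase"),
            "n_reduction30": count(lambda r: r.reduction30_ros is True),
        },
        "no": {
            "n_measured": count(lambda r: r.no_pct is not None),
            "n_excluded_cytotoxic": count(lambda r: r.excluded_no is True),
            "n_significant_decrease": count(lambda r: r.sig_no == "decrease"),
            "n_significant_increase": count(lambda r: r.sig_no == "increase"),
            "n_reduction30": count(lambda r: r.reduction30_no is True),
        },
        "selectivity_counts": sel_counts,
        "correlations": {
            f"{c.pair[0]}_{c.pair[1]}": {"r_s": c.r_s, "p_value": c.p_value, "n": c.n}
            for c in correlations
        },
        "excluded_ros_wells": ros_excluded_wells,
        "calibration": {
            assay: {
                plate: {"slope": cv.slope, "intercept": cv.intercept, "r_squared": cv.r_squared}
                for plate, cv in by_plate.items()
            }
            for assay, by_plate in curves.items()
        },
    }
    if QUERCETIN_ID in ros_results:
        q = ros_results[QUERCETIN_ID]
        report["positive_control_ros"] = {"mean_pct": q.ros_pct, "sd": q.sd, "n": q.n}
    if QUERCETIN_ID in no_results:
        q = no_results[QUERCETIN_ID]
        report["positive_control_no"] = {"mean_pct": q.no_pct, "sd": q.sd, "n": q.n}
    return report
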