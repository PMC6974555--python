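"""Per-patient and cohort-level orchestration.

``run_patient`` composes the per-recording stages in order: nocturnal
extraction -> NN filtering -> tachogram -> flat classification -> CVHR
scoring (non-flat only) -> HRV / HRT / DC / SAF, producing one
JSON-serializable report.  ``run_cohort`` adds the cohort statistics:
group sizes, Kaplan-Meier comparisons of the SDB and flat strata, the
CVHR-threshold mortality scan, the multivariable Cox model, the SAF
cross-tabulation and the CVHR-respiratory-rate correlation.

Per-patient failures quarantine the patient and continue; cohort-level
failures abort.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import cvhr as cvhr_mod
from . import hrt_dc, hrv, survival
from .rr_io import BeatSeries, NocturnalWindow, extract_nocturnal_segment, nn_filter
from .tachogram import build_tachogram, classify_flat

MULTIVARIABLE_COVARIATES = ["flat", "age", "female", "lvef", "grace", "diabetes"]
SAF_MODEL_COVARIATES = ["saf", "flat", "lvef", "grace"]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the per-patient stages, with documented defaults."""

    window: NocturnalWindow = field(default_factory=NocturnalWindow)
    smooth_window_s: float = 5.0
    flat_excursion_limit_bpm: float = 5.0
    flat_rsa_min_bpm: float = 1.0
    arousal_min_delta_bpm: float = cvhr_mod.AROUSAL_MIN_DELTA_BPM
    arousal_min_dur_s: float = cvhr_mod.AROUSAL_MIN_DUR_S
    max_gap_s: float = cvhr_mod.MAX_GAP_S
    min_arousals: int = cvhr_mod.MIN_AROUSALS
    sdb_fraction: float = cvhr_mod.SDB_FRACTION
    hrv_nocturnal_only: bool = False
    dc_min_anchors: int = hrt_dc.MIN_ANCHORS
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def run_patient(series: BeatSeries, config: PipelineConfig | None = None) -> dict:
    """Score one recording; returns the per-patient report dict.

    Non-analyzable nocturnal coverage short-circuits to a report with
    ``status = "non_analyzable"`` (a distinct category from flat).
    """
    config = config or PipelineConfig()
    report: dict = {"patient_id": series.patient_id}
    seg = extract_nocturnal_segment(series, config.window)
    report["nocturnal_coverage"] = seg.coverage
    if not seg.analyzable:
        report["status"] = "non_analyzable"
        return report

    nn_night = nn_filter(seg.series)
    if len(nn_night) < 2:
        report["status"] = "non_analyzable"
        return report
    tach = build_tachogram(nn_night, config.smooth_window_s)
    flat = classify_flat(tach, config.flat_excursion_limit_bpm, config.flat_rsa_min_bpm)
    report["flat"] = {
        "is_flat": flat.is_flat,
        "max_excursion_bpm": flat.max_excursion_bpm,
        "rsa_present": flat.rsa_present,
    }
    segment_min = config.window.length_s / 60.0
    cv = cvhr_mod.score_cvhr(tach, flat, segment_min=segment_min)
    report["cvhr"] = cv.to_dict()
    report["status"] = "flat" if flat.is_flat else "scored"

    nn_panel = nn_night if config.hrv_nocturnal_only else nn_filter(series)
    metrics = hrv.compute_hrv(nn_panel)
    report["hrv"] = {k: (None if not np.isfinite(v) else v) for k, v in metrics.to_dict().items()}

    hrt = hrt_dc.compute_hrt(series)
    dc = hrt_dc.compute_dc(nn_panel, min_anchors=config.dc_min_anchors)
    saf = hrt_dc.classify_saf(hrt, dc)
    report["hrt"] = {
        "turbulence_onset_pct": None if not hrt.defined else hrt.turbulence_onset_pct,
        "turbulence_slope_ms_per_rr": None if not hrt.defined else hrt.turbulence_slope_ms_per_rr,
        "n_valid_vpc": hrt.n_valid_vpc,
        "abnormal": hrt.abnormal,
    }
    report["dc"] = {
        "dc_ms": None if not dc.defined else dc.dc_ms,
        "n_anchors": dc.n_anchors,
        "abnormal": dc.abnormal,
    }
    report["saf"] = saf.saf
    return report


def _design_matrix(table: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    df = pd.DataFrame(index=table.index)
    for cov in covariates:
        if cov == "female":
            df[cov] = (table["sex"] == "female").astype(float)
        else:
            df[cov] = table[cov].astype(float)
    return df


def run_cohort(table: pd.DataFrame, config: PipelineConfig | None = None) -> dict:
    """Cohort statistics bundle from a table of markers + outcomes.

    Expects the CohortTable columns (id, age, sex, lvef, grace,
    diabetes, nrr, flat, cvhr_minutes, sdb_status, saf, time_years,
    event).  Returns a nested dict of group sizes, KM summaries, the
    threshold scan, Cox fits and the CVHR-NRR correlation.
    """
    config = config or PipelineConfig()
    for col in ("time_years", "event"):
        if col not in table.columns:
            raise ValueError(f"missing outcome column {col!r}")
    out: dict = {}
    n = len(table)
    flat = table["flat"].to_numpy(dtype=bool)
    nonflat = table.loc[~flat]
    out["group_sizes"] = {
        "n": n,
        "flat": int(flat.sum()),
        "non_flat": int((~flat).sum()),
        "sdb_present": int((nonflat["sdb_status"] == "present").sum()),
        "sdb_absent": int((nonflat["sdb_status"] == "absent").sum()),
    }

    times = table["time_years"].to_numpy(dtype=float)
    events = table["event"].to_numpy(dtype=bool)

    def km_summary(mask: np.ndarray) -> dict:
        curve = survival.km_estimate(times[mask], events[mask])
        lo, hi = curve.ci_at(survival.HORIZON_YEARS)
        return {
            "n": int(mask.sum()),
            "mortality_5y": curve.mortality_at(),
            "ci": [1.0 - hi, 1.0 - lo],
        }

    # flat vs non-flat stratification
    out["km_flat"] = km_summary(flat)
    out["km_non_flat"] = km_summary(~flat)
    chi2, p = survival.logrank_test(flat.astype(int), times, events)
    out["logrank_flat_vs_nonflat"] = {"chi2": chi2, "p": p}

    # SDB present vs absent among non-flat patients
    sdb_mask = (table["sdb_status"] == "present").to_numpy()
    absent_mask = (table["sdb_status"] == "absent").to_numpy()
    out["km_sdb_present"] = km_summary(sdb_mask)
    out["km_sdb_absent"] = km_summary(absent_mask)
    nf = ~flat
    chi2, p = survival.logrank_test(sdb_mask[nf].astype(int), times[nf], events[nf])
    out["logrank_sdb"] = {"chi2": chi2, "p": p}

    # CVHR-threshold mortality scan (non-flat only)
    scan = survival.threshold_mortality_scan(
        nonflat["cvhr_minutes"].to_numpy(dtype=float),
        times[nf],
        events[nf],
    )
    out["threshold_scan"] = scan

    # multivariable Cox, published covariate set
    events_total = int(events.sum())
    if events_total > len(MULTIVARIABLE_COVARIATES):
        fit = survival.cox_fit(_design_matrix(table, MULTIVARIABLE_COVARIATES), times, events)
        out["cox_multivariable"] = fit.summary
        saf_known = table["saf"].notna().to_numpy()
        fit_saf = survival.cox_fit(
            _design_matrix(table.loc[saf_known], SAF_MODEL_COVARIATES),
            times[saf_known],
            events[saf_known],
        )
        out["cox_saf_model"] = fit_saf.summary
    else:
        out["cox_multivariable"] = None
        out["cox_skipped_reason"] = "too few events"

    # SAF x flat cross-tabulation (the Fig-7-style strata)
    saf = table["saf"].fillna(False).to_numpy(dtype=bool)
    out["saf_cross_tab"] = {
        "saf": int(saf.sum()),
        "flat": int(flat.sum()),
        "both": int((saf & flat).sum()),
        "flat_without_saf": int((flat & ~saf).sum()),
        "neither": int((~saf & ~flat).sum()),
    }

    # CVHR duration vs nocturnal respiratory rate
    cv = nonflat["cvhr_minutes"].to_numpy(dtype=float)
    nrr = nonflat["nrr"].to_numpy(dtype=float)
    ok = np.isfinite(cv) & np.isfinite(nrr)
    out["cvhr_nrr_pearson_r"] = (
        survival.pearson_r(cv[ok], nrr[ok]) if ok.sum() >= 3 else None
    )
    return out


def score_patients(
    series_iter: Iterable[BeatSeries], config: PipelineConfig | None = None
) -> tuple[pd.DataFrame, list[dict]]:
    """Score many recordings; quarantines per-patient failures.

    Returns a tidy marker table (one row per successfully scored
    patient) and the list of raw reports (including failures, which get
    ``status = "error"``).
    """
    config = config or PipelineConfig()
    reports = []
    rows = []
    for series in series_iter:
        try:
            rep = run_patient(series, config)
        except Exception as exc:
            rep = {"patient_id": series.patient_id, "status": "error", "error": str(exc)}
        reports.append(rep)
        if rep["status"] in ("scored", "flat"):
            rows.append(
                {
                    "id": rep["patient_id"],
                    "flat": rep["flat"]["is_flat"],
                    "cvhr_minutes": rep["cvhr"]["cvhr_minutes"],
                    "sdb_status": rep["cvhr"]["sdb_status"],
                    **{k: v for k, v in rep.get("hrv", {}).items()},
                    "saf": rep.get("saf"),
                }
            )
    return pd.DataFrame(rows), reports


def write_bundle(bundle: Mapping, out_dir: str | Path) -> None:
    """Persist a cohort bundle: DataFrames as CSV, the rest as JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scalars: dict = {}
    for key, value in bundle.items():
        if isinstance(value, pd.DataFrame):
            value.to_csv(out_dir / f"{key}.csv", index=True)
        else:
            scalars[key] = value
    (out_dir / "cohort_summary.json").write_text(
        json.dumps(scalars, indent=2, default=_json_default) + "\n"
    )


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")
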