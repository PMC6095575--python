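"""Pipeline orchestration: run the analysis stages over a cohort workspace.

Workspace layout (as produced by :mod:`renal_sabr_mri.cohort` or arranged by
hand for real data)::

    workspace/
      ct_measurements.csv                    # patient_id,timepoint,AP_mm,TR_mm,CC_mm
      patients/<pid>/<scan>/dce.nii          # scan in {baseline, f1, f2}
      patients/<pid>/<scan>/dwi.nii + dwi.bval
      patients/<pid>/<scan>/tumour_mask.nii
      patients/<pid>/<scan>/aorta_mask.nii

Outputs go to ``config.out_dir`` (default ``workspace/derived``): parameter
maps per scan, per-stage summary CSVs, a correlation table and a JSON run
manifest.  A failure in one patient's scan is logged and skipped; it does
not abort the cohort.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as rio
from .adc import AdcMap, DwiStack, fit_adc, roi_histogram_stats
from .config import RunConfig
from .pk import (
    ConcentrationCurve,
    extract_aif,
    fit_tofts_roi,
    iaugc60,
    signal_to_concentration_rows,
    summarise_pk,
)
from .semiquant import (
    CLASS_CODES,
    CLASS_NAMES,
    DynamicSeries,
    classify_voxel,
    fit_piecewise_batch,
    normalise_series,
    summarise_gd,
)
from .volumetrics import analyse_ct_table, load_ct_table

__all__ = ["run_pipeline", "discover_scans"]


def discover_scans(workspace: Path) -> list[tuple[str, str, Path]]:
    """(patient_id, scan, scan_dir) for every scan directory present."""
    scans = []
    pdir = workspace / "patients"
    if not pdir.is_dir():
        return scans
    for patient in sorted(pdir.iterdir(), key=lambda p: (len(p.name), p.name)):
        if not patient.is_dir():
            continue
        for scan in ("baseline", "f1", "f2"):
            d = patient / scan
            if d.is_dir():
                scans.append((patient.name, scan, d))
    return scans


def _frame_interval(header) -> float:
    dt = float(header["pixdim"][4])
    return dt if dt > 0 else 5.2


def _stage_adc(scans, out: Path, log: list[str]) -> pd.DataFrame:
    rows = []
    for pid, scan, d in scans:
        try:
            dwi, _ = rio.read_nifti(d / "dwi.nii")
            b = rio.read_bvals(d / "dwi.bval")
            mask = rio.read_mask(d / "tumour_mask.nii")
            amap = fit_adc(DwiStack(signal=dwi.astype(float), b_values=b))
            stats = roi_histogram_stats(amap, mask)
            rio.write_nifti(out / "maps" / pid / scan / "adc.nii", np.nan_to_num(amap.adc))
            rows.append(
                dict(patient_id=pid, mri_scan=scan, n_voxels=stats.n_voxels,
                     mean=stats.mean, median=stats.median,
                     kurtosis=stats.kurtosis, skewness=stats.skewness)
            )
        except (OSError, ValueError) as err:
            log.append(f"adc: skipped {pid}/{scan}: {err}")
    df = pd.DataFrame(rows)
    rio.write_csv(out / "adc_stats.csv", df)
    return df


def _stage_semiquant(scans, cfg: RunConfig, out: Path, log: list[str]) -> pd.DataFrame:
    rows = []
    for pid, scan, d in scans:
        try:
            dce, hdr = rio.read_nifti(d / "dce.nii")
            mask = rio.read_mask(d / "tumour_mask.nii")
            series = DynamicSeries(signal=dce.astype(float), frame_interval_s=_frame_interval(hdr))
            E, ok = normalise_series(series, mask)
            fits = fit_piecewise_batch(E, series.frame_times, bic_sigma0=cfg.bic_sigma0)
            classes = [
                classify_voxel(f, cfg.enhancement_threshold) if good else "none"
                for f, good in zip(fits, ok)
            ]
            summ = summarise_gd(classes, fits)
            # integer-coded GD map: 0 none, 1 persistent, 2 plateau, 3 washout
            gd = np.zeros(mask.shape, dtype=np.int16)
            gd[mask] = [CLASS_CODES[c] for c in classes]
            mdir = out / "maps" / pid / scan
            rio.write_nifti(mdir / "gd.nii", gd)
            for name, getter in [
                ("tonset", lambda f: f.t_onset), ("ire", lambda f: f.ire),
                ("me", lambda f: f.me), ("twashout", lambda f: f.t_washout),
                ("irw", lambda f: f.irw),
            ]:
                vol = np.zeros(mask.shape)
                vol[mask] = [getter(f) if getter(f) is not None else 0.0 for f in fits]
                rio.write_nifti(mdir / f"{name}.nii", vol)
            row = dict(patient_id=pid, mri_scan=scan,
                       n_voxels=summ.n_voxels, n_enhancing=summ.n_enhancing,
                       mean_me=summ.mean_me, mean_ire=summ.mean_ire,
                       mean_tonset=summ.mean_t_onset, mean_irw=summ.mean_irw,
                       mean_twashout=summ.mean_t_washout)
            for cname in CLASS_NAMES:
                row[f"pct_{cname}"] = summ.pct[cname]
            rows.append(row)
        except (OSError, ValueError) as err:
            log.append(f"dce-semiquant: skipped {pid}/{scan}: {err}")
    df = pd.DataFrame(rows)
    rio.write_csv(out / "gd_summary.csv", df)
    return df


def _stage_pk(scans, cfg: RunConfig, out: Path, log: list[str]) -> pd.DataFrame:
    rows = []
    for pid, scan, d in scans:
        try:
            dce, hdr = rio.read_nifti(d / "dce.nii")
            mask = rio.read_mask(d / "tumour_mask.nii")
            aorta = rio.read_mask(d / "aorta_mask.nii")
            gd_path = out / "maps" / pid / scan / "gd.nii"
            if not gd_path.exists():
                raise ValueError("GD map missing; run the dce-semiquant stage first")
            gd, _ = rio.read_nifti(gd_path)
            dt = _frame_interval(hdr)
            dce = dce.astype(float)
            n_frames = dce.shape[3]
            t_s = np.arange(n_frames) * dt
            aif = extract_aif(dce, aorta, dt, cfg.onset_frame, cfg.pk)
            conc, okv, _ = signal_to_concentration_rows(
                dce[mask], dt, cfg.onset_frame, cfg.pk.t1_tissue_s, cfg.pk
            )
            params = fit_tofts_roi(conc, t_s, aif.c)
            aucs = [
                iaugc60(ConcentrationCurve(c=c, t=t_s, onset_frame=cfg.onset_frame))
                for c in conc
            ]
            enhancing = (gd[mask] != CLASS_CODES["none"]) & okv
            summ = summarise_pk(params, aucs, enhancing)
            mdir = out / "maps" / pid / scan
            for name, vals in [
                ("ktrans", [p.ktrans for p in params]),
                ("ve", [p.ve for p in params]),
                ("vp", [p.vp for p in params]),
                ("kep", [p.kep for p in params]),
                ("iaugc60", [a.iaugc60 for a in aucs]),
            ]:
                vol = np.zeros(mask.shape)
                vol[mask] = vals
                rio.write_nifti(mdir / f"{name}.nii", vol)
            rows.append(
                dict(patient_id=pid, mri_scan=scan, n_voxels=summ.n_voxels,
                     mean_ktrans=summ.mean_ktrans, mean_ve=summ.mean_ve,
                     mean_vp=summ.mean_vp, mean_kep=summ.mean_kep,
                     mean_iaugc60=summ.mean_iaugc60, valid=summ.valid)
            )
        except (OSError, ValueError) as err:
            log.append(f"dce-pk: skipped {pid}/{scan}: {err}")
    df = pd.DataFrame(rows)
    rio.write_csv(out / "pk_summary.csv", df)
    return df


def _stage_volumes(cfg: RunConfig, out: Path, log: list[str]) -> pd.DataFrame:
    path = cfg.workspace / "ct_measurements.csv"
    table = load_ct_table(path if path.exists() else None)
    if not path.exists():
        log.append("volumes: no ct_measurements.csv in workspace; using packaged clinical table")
    df = analyse_ct_table(table)
    rio.write_csv(out / "volumes.csv", df)
    return df


def _mri_long_table(adc_df, gd_df, pk_df) -> pd.DataFrame:
    """Stack stage summaries into (patient_id, mri_scan, parameter, modality, value)."""
    frames = []
    if adc_df is not None and len(adc_df):
        adc_long = adc_df.melt(
            id_vars=["patient_id", "mri_scan"],
            value_vars=[c for c in ("mean", "median", "kurtosis", "skewness") if c in adc_df],
            var_name="parameter", value_name="value",
        )
        adc_long["parameter"] = "adc_" + adc_long["parameter"]
        adc_long["modality"] = "adc"
        frames.append(adc_long)
    for df, cols in (
        (gd_df, ["mean_me", "mean_ire", "mean_irw", "mean_tonset", "mean_twashout",
                 "pct_washout", "pct_plateau", "pct_persistent", "pct_none"]),
        (pk_df, ["mean_ktrans", "mean_iaugc60"]),
    ):
        if df is not None and len(df):
            long = df.melt(
                id_vars=["patient_id", "mri_scan"],
                value_vars=[c for c in cols if c in df],
                var_name="parameter", value_name="value",
            )
            long["modality"] = "dce"
            frames.append(long)
    if not frames:
        return pd.DataFrame(columns=["patient_id", "mri_scan", "parameter", "modality", "value"])
    return pd.concat(frames, ignore_index=True)


def _stage_correlate(cfg: RunConfig, out: Path, adc_df, gd_df, pk_df, vol_df, log) -> pd.DataFrame:
    from .stats import build_change_table, correlate_all, format_correlation_table

    mri = _mri_long_table(adc_df, gd_df, pk_df)
    if not len(mri) or vol_df is None or not len(vol_df):
        log.append("correlate: missing MRI summaries or volume table; stage skipped")
        return pd.DataFrame()
    table = build_change_table(
        mri, vol_df[["patient_id", "timepoint", "pct_change_vs_baseline"]],
        dce_exclusions=tuple(cfg.dce_exclusions),
    )
    corr = correlate_all(table)
    rio.write_csv(out / "correlations.csv", corr)
    (out / "correlations.md").write_text(format_correlation_table(corr) + "\n")
    return corr


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the run manifest."""
    ws = Path(config.workspace)
    if not ws.exists():
        raise FileNotFoundError(f"workspace {ws} does not exist")
    out = Path(config.out_dir) if config.out_dir else ws / "derived"
    out.mkdir(parents=True, exist_ok=True)
    scans = discover_scans(ws)
    log: list[str] = []
    adc_df = gd_df = pk_df = vol_df = None
    stage_summ: dict[str, dict] = {}

    if "simulate" in config.stages:
        from .cohort import CohortSpec, simulate_cohort_workspace

        simulate_cohort_workspace(ws, CohortSpec(seed=config.seed))
        scans = discover_scans(ws)
        stage_summ["simulate"] = {"n_scans": len(scans)}
    if "adc" in config.stages:
        adc_df = _stage_adc(scans, out, log)
        stage_summ["adc"] = {"n_scans": int(len(adc_df))}
    if "dce-semiquant" in config.stages:
        gd_df = _stage_semiquant(scans, config, out, log)
        stage_summ["dce-semiquant"] = {"n_scans": int(len(gd_df))}
    if "dce-pk" in config.stages:
        pk_df = _stage_pk(scans, config, out, log)
        stage_summ["dce-pk"] = {"n_scans": int(len(pk_df))}
    if "volumes" in config.stages:
        vol_df = _stage_volumes(config, out, log)
        stage_summ["volumes"] = {"n_rows": int(len(vol_df))}
    if "correlate" in config.stages:
        corr = _stage_correlate(config, out, adc_df, gd_df, pk_df, vol_df, log)
        stage_summ["correlate"] = {"n_cells": int(len(corr))}

    manifest = {
        "config_hash": config.config_hash(),
        "stages": stage_summ,
        "skipped": log,
        "n_scans_discovered": len(scans),
    }
    rio.write_json(out / "run_manifest.json", manifest)
    return manifest
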