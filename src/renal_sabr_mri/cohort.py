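"""Synthetic longitudinal cohorts on disk.

Builds a pipeline-ready workspace of phantom patients, each with a baseline
and two follow-up MRI sessions (DCE + DWI + masks) and a longitudinal CT
measurement table.  Follow-up phantoms can carry injected monotone trends —
per-patient shifts of the washout-voxel fraction, the Ktrans range and the
ADC range tied to the patient's CT volume-change target — so the full
pipeline's correlation stage has a known signal to recover.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import io as rio
from .synthetic import PhantomConfig, simulate_ct_table, simulate_dce_phantom, simulate_dwi_phantom

__all__ = ["CohortSpec", "simulate_cohort_workspace"]

MRI_SCANS = ("baseline", "f1", "f2")


@dataclass
class CohortSpec:
    """What the cohort generator injects.

    ``washout_span`` is the full baseline-to-follow-up-2 washout-fraction
    change across the cohort: the patient with the largest volume growth
    changes by ``+washout_span/2`` and the strongest responder by the same
    amount downward, split symmetrically between the baseline and the second
    follow-up scan so no fraction needs clipping.  Ktrans and ADC ranges
    shift analogously via ``ktrans_gain`` and ``adc_shift``.
    """

    n_patients: int = 12
    grid_shape: tuple[int, int, int] = (10, 10, 4)
    n_frames: int = 30
    noise_sd: float = 2.0
    volume_targets: Sequence[float] | None = None
    base_fractions: tuple[float, float, float, float] = (0.20, 0.25, 0.25, 0.30)
    washout_span: float = 0.8
    ktrans_gain: float = 0.8
    adc_shift: float = 0.8e-3
    seed: int = 0


# per-scan share of the injected baseline-to-f2 trend
_SCAN_SHARE = {"baseline": -0.5, "f1": 0.0, "f2": 0.5}


def _fractions_for(spec: CohortSpec, rel: float, scan: str) -> tuple[float, float, float, float]:
    """Class fractions with the washout shift applied (plateau compensates).

    ``rel`` in [-0.5, 0.5] is the patient's position in the volume-change
    ordering.
    """
    p, pl, w, n = spec.base_fractions
    dw = spec.washout_span * rel * _SCAN_SHARE[scan]
    w2 = min(max(w + dw, 0.02), 0.9)
    pl2 = pl - (w2 - w)
    if pl2 < 0.02:
        p = p + (pl2 - 0.02)
        pl2 = 0.02
    total = p + pl2 + w2 + n
    return (p / total, pl2 / total, w2 / total, n / total)


def simulate_cohort_workspace(out_dir: str | Path, spec: CohortSpec) -> Path:
    """Write a full phantom cohort workspace; returns its path."""
    out = Path(out_dir)
    rng = np.random.default_rng(spec.seed)
    if spec.volume_targets is None:
        targets = np.linspace(-0.85, 0.9, spec.n_patients)
    else:
        targets = np.asarray(spec.volume_targets, dtype=float)
        if len(targets) != spec.n_patients:
            raise ValueError("one volume target per patient required")

    ct_table, achieved = simulate_ct_table(
        spec.n_patients, volume_change_targets=targets, seed=spec.seed
    )
    rio.write_csv(out / "ct_measurements.csv", ct_table)

    order = np.argsort(np.argsort(targets))  # ranks 0..n-1
    rel = (order - (spec.n_patients - 1) / 2.0) / max(spec.n_patients - 1, 1)

    manifest: dict = {"patients": {}, "spec": {"n_patients": spec.n_patients, "seed": spec.seed}}
    for i in range(spec.n_patients):
        pid = str(i + 1)
        manifest["patients"][pid] = {}
        for scan in MRI_SCANS:
            share = _SCAN_SHARE[scan]
            gain = 1.0 + spec.ktrans_gain * rel[i] * share
            # only the upper bound shifts: the slow-uptake (persistent) corner
            # of parameter space must stay reachable in every scan
            kt_lo, kt_hi = 0.05, 0.8 * gain
            adc_lo = 1.2e-3 + spec.adc_shift * rel[i] * share
            cfg = PhantomConfig(
                grid_shape=spec.grid_shape,
                n_frames=spec.n_frames,
                noise_sd=spec.noise_sd,
                class_fractions=_fractions_for(spec, rel[i], scan),
                ktrans_range=(kt_lo, min(kt_hi, 5.0)),
                adc_range=(max(adc_lo, 0.3e-3), max(adc_lo, 0.3e-3) + 1.2e-3),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            scan_dir = out / "patients" / pid / scan
            dce, roi, aorta, truth = simulate_dce_phantom(cfg)
            dwi, roi_d, truth_d = simulate_dwi_phantom(cfg)
            rio.write_nifti(scan_dir / "dce.nii", dce, frame_interval_s=cfg.frame_interval_s)
            rio.write_nifti(scan_dir / "dwi.nii", dwi)
            rio.write_bvals(scan_dir / "dwi.bval", cfg.b_values)
            rio.write_mask(scan_dir / "tumour_mask.nii", roi)
            rio.write_mask(scan_dir / "aorta_mask.nii", aorta)
            rio.write_nifti(scan_dir / "truth_labels.nii", truth.labels.astype(np.int16))
            rio.write_nifti(scan_dir / "truth_ktrans.nii", truth.ktrans)
            manifest["patients"][pid][scan] = {
                "class_fractions": list(cfg.class_fractions),
                "ktrans_range": list(cfg.ktrans_range),
                "adc_range": list(cfg.adc_range),
                "seed": cfg.seed,
                "n_frames": cfg.n_frames,
                "frame_interval_s": cfg.frame_interval_s,
                "onset_frame": cfg.onset_frame,
            }
    manifest["volume_targets"] = [float(v) for v in targets]
    manifest["achieved"] = achieved
    rio.write_json(out / "cohort_manifest.json", manifest)
    return out
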