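"""Digital phantoms with known ground truth.

Three generators emulate the statistical structure the analysis assumes:

* ``simulate_dce_phantom`` — a 4D DCE series whose tumour-ROI voxels mix the
  four enhancement behaviours (persistent / plateau / washout / none).
  Enhancing voxels receive tissue curves from the extended Tofts forward
  model driven by the population AIF, converted to signal with the fixed-T1
  SPGR equation; an aorta region carries the blood-pool signal so the AIF
  can be re-measured from the images.
* ``simulate_dwi_phantom`` — a multi-b-value stack obeying the
  mono-exponential decay law with a spatially varying ADC.
* ``simulate_ct_table`` — longitudinal tri-axial CT measurement tables with
  configurable per-patient volume-change trajectories, in the same CSV
  dialect as the clinical measurement table.

Noise is additive Gaussian on the magnitude signal (a documented
simplification; at the simulated SNRs the Rician correction is small).
Identical (config, seed) always give identical phantoms.

Label rules.  A voxel's behaviour label must be *earned* by its noiseless
enhancement curve, not just by its kinetic parameters: washout means the
final enhancement sits more than 10% of the maximum below the maximum,
plateau means a maximum is reached with at most a 10% decline, persistent
means near-monotone rise with no maximum before the last frame.  The
generator draws (Ktrans, ve, vp) from the configured global ranges and
rejection-samples each class with margins *stricter* than the 10% label
boundary (washout drop >= 15%, plateau drop <= 5% with a flat late window,
persistent with a clearly sustained late rise) so that sampled curves sit
away from the decision boundary and the labels are unambiguous test oracles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .aif import DEFAULT_AIF, AifModel, make_population_aif
from .config import PkConstants
from .pk import spgr_signal, tofts_forward

__all__ = [
    "PhantomConfig",
    "GroundTruth",
    "simulate_dce_phantom",
    "simulate_dwi_phantom",
    "simulate_ct_table",
    "CLASS_ORDER",
]

CLASS_ORDER = ("persistent", "plateau", "washout", "none")

# sampling margins (stricter than the 10% label boundary; see module docstring)
WASHOUT_MIN_DROP = 0.15
WASHOUT_MIN_ABS_FALL = 0.20  # enhancement units; the fall must dwarf the noise floor
PLATEAU_MAX_DROP = 0.05
PLATEAU_MAX_LATE_RISE = 0.02
PLATEAU_T95_FRACTION = 0.65
PERSISTENT_MAX_DROP = 0.005
PERSISTENT_MIN_LATE_RISE = 0.08
PERSISTENT_MIN_SLOPE_SUSTAIN = 0.9  # late slope >= 90% of the mid-curve slope
ENHANCING_THRESHOLD_MARGIN = 2.0  # enhancing classes peak at >= 2x the "none" cut-off
# generous kinetic pre-filters per class (supersets of what the shape rules
# accept; they only skip hopeless draws, the shape rule always decides)
_PREFILTER = {
    "persistent": lambda kep, vp: (kep <= 0.3) & (vp <= 0.012),
    "plateau": lambda kep, vp: (kep >= 0.1) & (kep <= 5.0),
    "washout": lambda kep, vp: kep >= 0.3,
}


class PhantomConfig(BaseModel):
    """Geometry, acquisition and ground-truth parameter ranges of a phantom."""

    model_config = ConfigDict(extra="forbid")

    grid_shape: tuple[int, int, int] = (16, 16, 8)
    n_frames: int = Field(30, ge=8)
    frame_interval_s: float = Field(5.2, gt=0)
    onset_frame: int = Field(5, ge=0)
    b_values: list[float] = Field(default_factory=lambda: [50.0, 400.0, 800.0])
    # fractions over (persistent, plateau, washout, none); baseline cohort
    # composition puts roughly a third of tumour voxels in the non-enhancing class
    class_fractions: tuple[float, float, float, float] = (0.22, 0.20, 0.20, 0.38)
    ktrans_range: tuple[float, float] = (0.05, 0.8)  # min^-1
    ve_range: tuple[float, float] = (0.08, 0.9)
    vp_range: tuple[float, float] = (0.0, 0.15)
    adc_range: tuple[float, float] = (1.0e-3, 2.5e-3)  # mm^2/s
    noise_sd: float = Field(5.0, ge=0)
    baseline_signal: float = Field(200.0, gt=0)  # DCE tissue baseline, signal units
    blood_baseline_signal: float = Field(250.0, gt=0)
    s0_dwi: float = Field(1000.0, gt=0)
    seed: int = 0
    aif: AifModel = DEFAULT_AIF
    pk_constants: PkConstants = PkConstants()
    enhancement_threshold: float = Field(0.05, ge=0)

    @model_validator(mode="after")
    def _validate(self) -> "PhantomConfig":
        if abs(sum(self.class_fractions) - 1.0) > 1e-9:
            raise ValueError("class_fractions must sum to 1")
        if any(f < 0 for f in self.class_fractions):
            raise ValueError("class_fractions must be non-negative")
        if any(s < 1 for s in self.grid_shape):
            raise ValueError("grid_shape entries must be positive")
        if self.onset_frame >= self.n_frames:
            raise ValueError("onset_frame out of range")
        for name, (lo, hi), (plo, phi) in [
            ("ktrans_range", self.ktrans_range, (0.0, 5.0)),
            ("ve_range", self.ve_range, (0.0, 1.0)),
            ("vp_range", self.vp_range, (0.0, 0.2)),
            ("adc_range", self.adc_range, (0.0, 1.0)),
        ]:
            if not (plo <= lo < hi <= phi):
                raise ValueError(f"{name} must be a non-degenerate interval within bounds, got ({lo}, {hi})")
        if len(self.b_values) < 2 or any(b < 0 for b in self.b_values):
            raise ValueError("need >= 2 non-negative b-values")
        return self


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    labels: np.ndarray  # 3D int codes: -1 outside ROI, else index into CLASS_ORDER
    ktrans: np.ndarray
    ve: np.ndarray
    vp: np.ndarray
    adc: Optional[np.ndarray]
    noiseless_signal: Optional[np.ndarray]  # 4D DCE signal before noise
    aif_plasma: Optional[np.ndarray]  # mM per frame
    onset_frame: int = 0
    ct_table: Optional[pd.DataFrame] = None
    label_names: tuple[str, ...] = CLASS_ORDER

    def label_map(self) -> dict[str, np.ndarray]:
        return {
            name: self.labels == i for i, name in enumerate(self.label_names)
        }


# ---------------------------------------------------------------------------
# geometry helpers


def ellipsoid_mask(grid_shape: Sequence[int], fraction: float = 0.88) -> np.ndarray:
    """Axis-aligned ellipsoid centred in the grid (the tumour ROI)."""
    nx, ny, nz = grid_shape
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    rx, ry, rz = fraction * nx / 2.0, fraction * ny / 2.0, fraction * nz / 2.0
    x, y, z = np.ogrid[:nx, :ny, :nz]
    return ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2 <= 1.0


def aorta_mask_for(grid_shape: Sequence[int], roi: np.ndarray) -> np.ndarray:
    """A small blood-pool region in the corner of the grid, disjoint from the ROI."""
    mask = np.zeros(grid_shape, dtype=bool)
    mask[:2, :2, :] = True
    mask &= ~roi
    if not mask.any():
        raise ValueError("grid too small to place an aorta region outside the ROI")
    return mask


# ---------------------------------------------------------------------------
# curve-shape labelling


def shape_label(
    e: np.ndarray, enhancement_threshold: float = 0.05
) -> str:
    """Behaviour label of a noiseless enhancement curve.

    Washout: the final value sits more than 10% of the maximum below it.
    Persistent: near-monotone rise with no maximum reached — the curve is
    still rising materially (> 4% of the maximum) over the last quarter.
    Plateau: everything else that enhances (a maximum has effectively been
    reached, declining by at most 10%).
    """
    mx = float(e.max())
    if mx < enhancement_threshold:
        return "none"
    drop = (mx - e[-1]) / mx
    if drop > 0.10:
        return "washout"
    q = int(0.75 * len(e))
    late_rise = (e[-1] - e[q]) / mx
    near_mono = bool(np.all(np.diff(e) >= -1e-6 * mx))
    if drop <= 0.005 and near_mono and late_rise > 0.04:
        return "persistent"
    return "plateau"


def _sampling_accept(label: str, e: np.ndarray, threshold: float) -> np.ndarray:
    """Vectorised strict-margin acceptance; ``e`` is (draws, frames)."""
    n = e.shape[1]
    mx = e.max(axis=1)
    enhancing = mx >= ENHANCING_THRESHOLD_MARGIN * threshold
    safe_mx = np.where(mx > 0, mx, 1.0)
    drop = (mx - e[:, -1]) / safe_mx
    if label == "washout":
        return enhancing & (drop >= WASHOUT_MIN_DROP) & (mx - e[:, -1] >= WASHOUT_MIN_ABS_FALL)
    q = int(0.75 * n)
    late_rise = (e[:, -1] - e[:, q]) / safe_mx
    if label == "plateau":
        i95 = np.argmax(e >= 0.95 * mx[:, None], axis=1)
        return (
            enhancing
            & (drop <= PLATEAU_MAX_DROP)
            & (late_rise <= PLATEAU_MAX_LATE_RISE)
            & (i95 <= int(PLATEAU_T95_FRACTION * n))
        )
    if label == "persistent":
        # the literal label rule: monotone non-decreasing (to numerical precision)
        near_mono = np.all(np.diff(e, axis=1) >= -1e-9 * safe_mx[:, None], axis=1)
        # the rate of enhancement must be sustained: no plateau forming yet
        m0, m1 = n // 3, q
        mid_slope = (e[:, m1] - e[:, m0]) / (m1 - m0)
        late_slope = (e[:, -1] - e[:, q]) / (n - 1 - q)
        sustained = (mid_slope > 0) & (late_slope >= PERSISTENT_MIN_SLOPE_SUSTAIN * mid_slope)
        return (
            enhancing
            & (drop <= PERSISTENT_MAX_DROP)
            & near_mono
            & (late_rise >= PERSISTENT_MIN_LATE_RISE)
            & sustained
        )
    raise ValueError(f"unknown enhancing label {label!r}")


def _batch_tofts(kt, ve, vp, cp, t_s) -> np.ndarray:
    """Extended Tofts forward for a batch of parameter draws: (D, n_frames)."""
    kt = np.asarray(kt, float).ravel()
    ve = np.asarray(ve, float).ravel()
    vp = np.asarray(vp, float).ravel()
    kep_s = (kt / ve) / 60.0
    t_s = np.asarray(t_s, float)
    n = len(t_s)
    dtmat = np.maximum(t_s[:, None] - t_s[None, :], 0.0)
    dt = np.diff(t_s)
    trap = np.zeros((n, n))
    for i in range(1, n):
        trap[i, 0] = dt[0] / 2.0
        trap[i, i] = dt[i - 1] / 2.0
        if i > 1:
            trap[i, 1:i] = (dt[: i - 1] + dt[1:i]) / 2.0
    w = np.exp(-kep_s[:, None, None] * dtmat[None]) * trap[None]  # (D, n, n)
    conv = w @ cp  # (D, n)
    return (kt[:, None] / 60.0) * conv + vp[:, None] * cp


def _tissue_enhancement(ct: np.ndarray, cfg: PhantomConfig) -> np.ndarray:
    """Noiseless enhancement curves for tissue concentration rows (D, n)."""
    consts = cfg.pk_constants
    r1_0 = 1.0 / consts.t1_tissue_s
    m0 = cfg.baseline_signal / spgr_signal(1.0, r1_0, consts)
    s = spgr_signal(m0, r1_0 + consts.relaxivity_r1 * ct, consts)
    s_base = s[:, :2].mean(axis=1, keepdims=True)
    return s / s_base - 1.0


def _draw_class_params(
    rng: np.random.Generator,
    cfg: PhantomConfig,
    label: str,
    count: int,
    cp: np.ndarray,
    t_s: np.ndarray,
    chunk: int = 20000,
    max_draws: int = 80_000_000,
):
    """Rejection-sample ``count`` (ktrans, ve, vp) triples whose curves earn ``label``."""
    kts, ves, vps, curves = [], [], [], []
    total = 0
    got = 0
    prefilter = _PREFILTER[label]
    while got < count:
        if total >= max_draws:
            raise RuntimeError(
                f"could not sample {count} '{label}' voxels from the configured "
                f"ranges after {total} draws; ranges likely exclude this behaviour"
            )
        kt = rng.uniform(*cfg.ktrans_range, size=chunk)
        ve = rng.uniform(*cfg.ve_range, size=chunk)
        vp = rng.uniform(*cfg.vp_range, size=chunk)
        total += chunk
        keep = prefilter(kt / ve, vp)
        if not keep.any():
            continue
        kt, ve, vp = kt[keep], ve[keep], vp[keep]
        ct = _batch_tofts(kt, ve, vp, cp, t_s)
        e = _tissue_enhancement(ct, cfg)
        ok = _sampling_accept(label, e, cfg.enhancement_threshold)
        if ok.any():
            kts.append(kt[ok])
            ves.append(ve[ok])
            vps.append(vp[ok])
            curves.append(ct[ok])
            got += int(ok.sum())
    kt = np.concatenate(kts)[:count]
    ve = np.concatenate(ves)[:count]
    vp = np.concatenate(vps)[:count]
    ct = np.concatenate(curves)[:count]
    return kt, ve, vp, ct


# ---------------------------------------------------------------------------
# generators


def simulate_dce_phantom(config: PhantomConfig):
    """Generate a 4D DCE phantom.

    Returns ``(signal, roi_mask, aorta_mask, truth)`` where ``signal`` is the
    noisy 4D series, masks are boolean 3D arrays and ``truth`` carries labels,
    kinetic parameter maps, the noiseless signal and the plasma AIF.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    consts = cfg.pk_constants
    roi = ellipsoid_mask(cfg.grid_shape)
    if not roi.any():
        raise ValueError("empty ROI for this grid shape")
    aorta = aorta_mask_for(cfg.grid_shape, roi)
    t_s = np.arange(cfg.n_frames, dtype=float) * cfg.frame_interval_s
    cp = make_population_aif(cfg.n_frames, cfg.frame_interval_s, cfg.onset_frame, cfg.aif)

    n_roi = int(roi.sum())
    labels_flat = rng.choice(4, size=n_roi, p=np.asarray(cfg.class_fractions))

    kt_map = np.zeros(cfg.grid_shape)
    ve_map = np.zeros(cfg.grid_shape)
    vp_map = np.zeros(cfg.grid_shape)
    ct_rows = np.zeros((n_roi, cfg.n_frames))
    roi_idx = np.argwhere(roi)

    for li, label in enumerate(CLASS_ORDER):
        sel = labels_flat == li
        cnt = int(sel.sum())
        if cnt == 0 or label == "none":
            continue  # "none" voxels keep Ktrans = vp = 0 and a flat curve
        kt, ve, vp, ct = _draw_class_params(rng, cfg, label, cnt, cp, t_s)
        rows = roi_idx[sel]
        kt_map[rows[:, 0], rows[:, 1], rows[:, 2]] = kt
        ve_map[rows[:, 0], rows[:, 1], rows[:, 2]] = ve
        vp_map[rows[:, 0], rows[:, 1], rows[:, 2]] = vp
        ct_rows[sel] = ct

    # forward signal: tissue SPGR anchored at baseline_signal
    r1_0 = 1.0 / consts.t1_tissue_s
    m0 = cfg.baseline_signal / spgr_signal(1.0, r1_0, consts)
    noiseless = np.full((*cfg.grid_shape, cfg.n_frames), cfg.baseline_signal, dtype=float)
    sig_rows = spgr_signal(m0, r1_0 + consts.relaxivity_r1 * ct_rows, consts)
    noiseless[roi] = sig_rows

    # aorta: whole-blood concentration drives the blood-pool signal
    cb = cp * (1.0 - consts.hematocrit) if consts.apply_hematocrit else cp
    r1b_0 = 1.0 / consts.t1_blood_s
    m0_b = cfg.blood_baseline_signal / spgr_signal(1.0, r1b_0, consts)
    blood_sig = spgr_signal(m0_b, r1b_0 + consts.relaxivity_r1 * cb, consts)
    noiseless[aorta] = blood_sig

    signal = noiseless.copy()
    if cfg.noise_sd > 0:
        signal = signal + rng.normal(0.0, cfg.noise_sd, size=signal.shape)

    labels = np.full(cfg.grid_shape, -1, dtype=int)
    labels[roi] = labels_flat
    truth = GroundTruth(
        labels=labels,
        ktrans=kt_map,
        ve=ve_map,
        vp=vp_map,
        adc=None,
        noiseless_signal=noiseless,
        aif_plasma=cp,
        onset_frame=cfg.onset_frame,
    )
    return signal, roi, aorta, truth


def simulate_dwi_phantom(config: PhantomConfig):
    """Generate a multi-b-value DWI phantom.

    Returns ``(signal, roi_mask, truth)``; ``signal`` has shape
    (x, y, z, n_b).  Noiseless signals obey S(b) = S0 exp(-b ADC) exactly.
    """
    cfg = config
    if len(cfg.b_values) < 2:
        raise ValueError("need at least 2 b-values")
    rng = np.random.default_rng(cfg.seed + 1)  # independent stream from the DCE phantom
    roi = ellipsoid_mask(cfg.grid_shape)
    adc = np.full(cfg.grid_shape, 0.8e-3)
    adc[roi] = rng.uniform(*cfg.adc_range, size=int(roi.sum()))
    b = np.asarray(cfg.b_values, dtype=float)
    noiseless = cfg.s0_dwi * np.exp(-adc[..., None] * b[None, None, None, :])
    signal = noiseless.copy()
    if cfg.noise_sd > 0:
        signal = signal + rng.normal(0.0, cfg.noise_sd, size=signal.shape)
    truth = GroundTruth(
        labels=np.where(roi, 0, -1),
        ktrans=np.zeros(cfg.grid_shape),
        ve=np.zeros(cfg.grid_shape),
        vp=np.zeros(cfg.grid_shape),
        adc=adc,
        noiseless_signal=noiseless,
        aif_plasma=None,
    )
    return signal, roi, truth


def simulate_ct_table(
    n_patients: int,
    timepoints: Sequence[str] = ("baseline", "m6", "m12", "m24", "last"),
    volume_change_targets: Optional[Sequence[float]] = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[dict]]:
    """Longitudinal tri-axial CT measurement table with known volume changes.

    ``volume_change_targets`` gives each patient's fractional volume change at
    the final timepoint (e.g. -0.899 for a 89.9% shrinkage); intermediate
    follow-ups interpolate linearly in volume change.  Axes are integers in
    millimetres (matching the clinical table's dialect), baseline axes uniform
    in 15-75 mm.  Returns the table and a per-(patient, timepoint) list of
    achieved changes, flagging entries where integer rounding pushed the
    achieved change more than 5 percentage points from the target.
    """
    if volume_change_targets is None:
        rng0 = np.random.default_rng(seed)
        volume_change_targets = rng0.uniform(-0.8, 0.8, size=n_patients)
    targets = np.asarray(volume_change_targets, dtype=float)
    if len(targets) != n_patients:
        raise ValueError("one volume-change target per patient required")
    if np.any(targets <= -1):
        raise ValueError("volume-change targets must be > -1")
    if timepoints[0] != "baseline":
        raise ValueError("first timepoint must be 'baseline'")
    rng = np.random.default_rng(seed)
    rows = []
    achieved: list[dict] = []
    n_follow = len(timepoints) - 1
    for i in range(n_patients):
        pid = str(i + 1)
        base = rng.integers(15, 76, size=3)
        rows.append(dict(patient_id=pid, timepoint="baseline",
                         AP_mm=int(base[0]), TR_mm=int(base[1]), CC_mm=int(base[2])))
        v_base = float(np.prod(base))
        for j, tp in enumerate(timepoints[1:], start=1):
            frac = targets[i] * j / n_follow
            scale = (1.0 + frac) ** (1.0 / 3.0)
            axes = np.maximum(np.rint(base * scale).astype(int), 1)
            got = float(np.prod(axes)) / v_base - 1.0
            flagged = abs(got - frac) > 0.05
            achieved.append(dict(patient_id=pid, timepoint=tp, target=frac,
                                 achieved=got, flagged=flagged))
            rows.append(dict(patient_id=pid, timepoint=tp,
                             AP_mm=int(axes[0]), TR_mm=int(axes[1]), CC_mm=int(axes[2])))
    return pd.DataFrame(rows), achieved
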