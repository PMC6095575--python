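"""DCE-MRI pharmacokinetics: SPGR signal conversion, extended Tofts model,
voxelwise fitting and iAUGC60.

The extended Tofts model describes the tissue contrast-agent concentration as

    Ct(t) = Ktrans * int_0^t Cp(tau) exp(-kep (t - tau)) dtau + vp * Cp(t)

with Ktrans the plasma-to-EES transfer constant (min^-1), ve the EES volume
fraction, vp the plasma volume fraction and kep = Ktrans/ve the efflux
constant.  Concentration is obtained from the spoiled-gradient-echo signal
equation anchored at a fixed native T1 (1142 ms for kidney tissue, 1664 ms
for arterial blood), as used in the fixed-T1 analysis this package
reproduces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .config import PkConstants

__all__ = [
    "ConcentrationCurve",
    "ToftsParams",
    "IaugcValue",
    "PkRoiSummary",
    "spgr_signal",
    "signal_to_concentration",
    "extract_aif",
    "tofts_forward",
    "fit_tofts",
    "fit_tofts_roi",
    "iaugc60",
    "summarise_pk",
]

# Fit bounds (min^-1, fraction, fraction) and the fixed multi-start grid.
KTRANS_BOUNDS = (0.0, 5.0)
VE_BOUNDS = (1e-6, 1.0)
VP_BOUNDS = (0.0, 0.5)
FIT_STARTS: tuple[tuple[float, float, float], ...] = (
    (0.1, 0.8, 0.02),
    (0.2, 0.4, 0.05),
    (0.5, 0.2, 0.05),
    (0.05, 0.6, 0.10),
)


@dataclass
class ConcentrationCurve:
    """Tissue (or blood) contrast concentration sampled on the frame grid."""

    c: np.ndarray  # mM, per frame
    t: np.ndarray  # seconds, per frame
    onset_frame: int
    invalid_frames: np.ndarray = field(default=None)  # bool per frame, inversion failures

    def __post_init__(self) -> None:
        if self.invalid_frames is None:
            self.invalid_frames = np.zeros(len(self.c), dtype=bool)


@dataclass
class ToftsParams:
    ktrans: float  # min^-1
    ve: float
    vp: float
    fit_rss: float
    converged: bool

    @property
    def kep(self) -> float:
        return self.ktrans / self.ve


@dataclass
class IaugcValue:
    iaugc60: float  # mM s
    truncated: bool = False


@dataclass
class PkRoiSummary:
    """ROI means over enhancing, converged voxels (the Table-3 style rows)."""

    mean_ktrans: Optional[float]
    mean_ve: Optional[float]
    mean_vp: Optional[float]
    mean_kep: Optional[float]
    mean_iaugc60: Optional[float]
    n_voxels: int
    valid: bool


# ---------------------------------------------------------------------------
# SPGR signal model


def spgr_signal(m0, r1, constants: PkConstants) -> np.ndarray:
    """Spoiled gradient-echo steady-state signal for longitudinal rate R1 (s^-1)."""
    a = np.deg2rad(constants.flip_angle_deg)
    e1 = np.exp(-constants.tr_repetition_s * np.asarray(r1, dtype=float))
    return m0 * np.sin(a) * (1.0 - e1) / (1.0 - np.cos(a) * e1)


def _invert_spgr(signal: np.ndarray, s_base: float, r1_0: float, constants: PkConstants):
    """Invert the SPGR equation for R1(t), anchored so that s_base <-> r1_0.

    Returns (r1, invalid) where invalid flags frames whose signal implies a
    non-physical E1 (outside (0, 1)).
    """
    a = np.deg2rad(constants.flip_angle_deg)
    cos_a = np.cos(a)
    tr = constants.tr_repetition_s
    e1_0 = np.exp(-tr * r1_0)
    # k = M0 sin(alpha), recovered from the baseline anchor
    k = s_base * (1.0 - cos_a * e1_0) / (1.0 - e1_0)
    e1 = (k - signal) / (k - signal * cos_a)
    invalid = ~((e1 > 0.0) & (e1 < 1.0))
    e1_safe = np.clip(e1, 1e-12, 1.0 - 1e-12)
    r1 = -np.log(e1_safe) / tr
    return r1, invalid


def check_inversion_conditioning(constants: PkConstants) -> None:
    """Reject flip-angle/TR combinations that make the inversion ill-conditioned."""
    a = np.deg2rad(constants.flip_angle_deg)
    e1 = np.exp(-constants.tr_repetition_s / constants.t1_tissue_s)
    denom = 1.0 - np.cos(a) * e1
    if denom < 1e-6 or np.sin(a) < 1e-6:
        raise ValueError(
            "flip angle / TR combination makes SPGR inversion ill-conditioned "
            f"(flip={constants.flip_angle_deg} deg, TR={constants.tr_repetition_s} s)"
        )


def signal_to_concentration(
    signal: np.ndarray,
    frame_interval_s: float,
    onset_frame: int,
    t1_native_s: float,
    constants: PkConstants,
) -> ConcentrationCurve:
    """Convert one voxel's (or an ROI-mean) dynamic signal to concentration (mM).

    The mean of the first two frames anchors the SPGR equation at
    R1 = 1/t1_native; each frame's signal is inverted for R1(t) and
    C(t) = (R1(t) - 1/t1_native) / r1.  Frames before ``onset_frame`` are set
    to zero.  With ``constants.linear_concentration`` the linearised relation
    dS proportional to dR1 (slope taken at baseline) is used instead of the
    exact inversion.
    """
    check_inversion_conditioning(constants)
    signal = np.asarray(signal, dtype=float)
    n = len(signal)
    if n < 3:
        raise ValueError("dynamic signal needs at least 3 frames")
    s_base = signal[:2].mean()
    if s_base <= 0:
        raise ValueError("non-positive baseline signal; voxel unanalysable")
    r1_0 = 1.0 / t1_native_s
    if constants.linear_concentration:
        # dS/dR1 at baseline
        eps = 1e-6
        ds = spgr_signal(1.0, r1_0 + eps, constants) - spgr_signal(1.0, r1_0, constants)
        slope = ds / eps * (s_base / spgr_signal(1.0, r1_0, constants))
        r1 = r1_0 + (signal - s_base) / slope
        invalid = np.zeros(n, dtype=bool)
    else:
        r1, invalid = _invert_spgr(signal, s_base, r1_0, constants)
    c = (r1 - r1_0) / constants.relaxivity_r1
    c[:onset_frame] = 0.0
    invalid = invalid.copy()
    invalid[:onset_frame] = False
    t = np.arange(n, dtype=float) * frame_interval_s
    return ConcentrationCurve(c=c, t=t, onset_frame=onset_frame, invalid_frames=invalid)


def signal_to_concentration_rows(
    sig_rows: np.ndarray,
    frame_interval_s: float,
    onset_frame: int,
    t1_native_s: float,
    constants: PkConstants,
):
    """Vectorised conversion of (n_voxels, n_frames) signal rows to mM.

    Returns ``(conc, ok, invalid_frames)``: concentration rows, a per-voxel
    validity flag (positive baseline) and a per-frame inversion-failure mask.
    """
    check_inversion_conditioning(constants)
    sig = np.asarray(sig_rows, dtype=float)
    s_base = sig[:, :2].mean(axis=1)
    ok = s_base > 0
    r1_0 = 1.0 / t1_native_s
    a = np.deg2rad(constants.flip_angle_deg)
    cos_a = np.cos(a)
    tr = constants.tr_repetition_s
    e1_0 = np.exp(-tr * r1_0)
    sb = np.where(ok, s_base, 1.0)[:, None]
    k = sb * (1.0 - cos_a * e1_0) / (1.0 - e1_0)
    e1 = (k - sig) / (k - sig * cos_a)
    invalid = ~((e1 > 0.0) & (e1 < 1.0))
    r1 = -np.log(np.clip(e1, 1e-12, 1.0 - 1e-12)) / tr
    conc = (r1 - r1_0) / constants.relaxivity_r1
    conc[:, :onset_frame] = 0.0
    invalid[:, :onset_frame] = False
    conc[~ok] = 0.0
    return conc, ok, invalid


def extract_aif(
    series: np.ndarray,
    aorta_mask: np.ndarray,
    frame_interval_s: float,
    onset_frame: int,
    constants: PkConstants,
) -> ConcentrationCurve:
    """Plasma concentration curve from an aorta ROI of a 4D series.

    The ROI-mean signal is converted with the blood T1; the blood
    concentration is divided by (1 - hematocrit) to give plasma
    concentration (skipped if ``apply_hematocrit`` is off).
    """
    aorta_mask = np.asarray(aorta_mask, dtype=bool)
    if not aorta_mask.any():
        raise ValueError("empty aorta mask")
    mean_signal = series[aorta_mask].mean(axis=0)
    curve = signal_to_concentration(
        mean_signal, frame_interval_s, onset_frame, constants.t1_blood_s, constants
    )
    if constants.apply_hematocrit:
        curve.c = curve.c / (1.0 - constants.hematocrit)
    return curve


# ---------------------------------------------------------------------------
# Extended Tofts model


def tofts_forward(
    ktrans: float,
    ve: float,
    vp: float,
    cp: np.ndarray,
    t_s: np.ndarray,
) -> np.ndarray:
    """Tissue concentration from the extended Tofts model (trapezoidal convolution).

    ``ktrans`` in min^-1, ``t_s`` in seconds, ``cp`` in mM on the same grid.
    """
    if ve <= 0:
        if ktrans > 0:
            raise ValueError("ve = 0 with ktrans > 0 is not a valid parameter set")
        return vp * np.asarray(cp, dtype=float)
    cp = np.asarray(cp, dtype=float)
    t_s = np.asarray(t_s, dtype=float)
    kep_s = (ktrans / ve) / 60.0
    n = len(t_s)
    # W[i, j] = exp(-kep (t_i - t_j)) for j <= i, with trapezoid weights
    dtmat = t_s[:, None] - t_s[None, :]
    w = np.exp(-kep_s * np.maximum(dtmat, 0.0))
    w = np.tril(w)
    # trapezoid: weight dt for interior samples, dt/2 at both ends of each row
    if n > 1:
        dt = np.diff(t_s)
        trap = np.zeros((n, n))
        for i in range(1, n):
            trap[i, : i + 1] = 0.0
            trap[i, 0] = dt[0] / 2.0
            trap[i, i] = dt[i - 1] / 2.0
            if i > 1:
                trap[i, 1:i] = (dt[:i-1] + dt[1:i]) / 2.0
        conv = (w * trap) @ cp
    else:
        conv = np.zeros(1)
    return (ktrans / 60.0) * conv + vp * cp


class _ToftsKernel:
    """Precomputed grid quantities for fast repeated forward evaluations."""

    def __init__(self, cp: np.ndarray, t_s: np.ndarray):
        self.cp = np.asarray(cp, dtype=float)
        self.t = np.asarray(t_s, dtype=float)
        n = len(self.t)
        self.dtmat = np.maximum(self.t[:, None] - self.t[None, :], 0.0)
        trap = np.zeros((n, n))
        if n > 1:
            dt = np.diff(self.t)
            for i in range(1, n):
                trap[i, 0] = dt[0] / 2.0
                trap[i, i] = dt[i - 1] / 2.0
                if i > 1:
                    trap[i, 1:i] = (dt[:i-1] + dt[1:i]) / 2.0
        self.trap = np.tril(trap)

    def __call__(self, ktrans: float, ve: float, vp: float) -> np.ndarray:
        kep_s = (ktrans / max(ve, 1e-12)) / 60.0
        w = np.exp(-kep_s * self.dtmat)
        conv = (w * self.trap) @ self.cp
        return (ktrans / 60.0) * conv + vp * self.cp


def fit_tofts(
    ct: ConcentrationCurve | np.ndarray,
    cp: np.ndarray,
    t_s: Optional[np.ndarray] = None,
    kernel: Optional[_ToftsKernel] = None,
) -> ToftsParams:
    """Bounded nonlinear least-squares fit of (ktrans, ve, vp) to one voxel.

    Deterministic: multi-start from the fixed grid ``FIT_STARTS``; the start
    with the lowest residual wins.  ``converged`` reports the winning
    optimiser status.
    """
    if isinstance(ct, ConcentrationCurve):
        y = ct.c
        t_s = ct.t
    else:
        y = np.asarray(ct, dtype=float)
        if t_s is None:
            raise ValueError("t_s required when ct is a bare array")
    if kernel is None:
        kernel = _ToftsKernel(cp, t_s)

    def resid(x: np.ndarray) -> np.ndarray:
        return kernel(x[0], x[1], x[2]) - y

    lo = [KTRANS_BOUNDS[0], VE_BOUNDS[0], VP_BOUNDS[0]]
    hi = [KTRANS_BOUNDS[1], VE_BOUNDS[1], VP_BOUNDS[1]]
    best = None
    for x0 in FIT_STARTS:
        sol = least_squares(resid, x0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if best is None or sol.cost < best.cost:
            best = sol
        if best.cost < 1e-24:  # exact fit found; further starts cannot improve
            break
    rss = 2.0 * best.cost
    return ToftsParams(
        ktrans=float(best.x[0]),
        ve=float(best.x[1]),
        vp=float(best.x[2]),
        fit_rss=float(rss),
        converged=bool(best.status > 0),
    )


def fit_tofts_roi(
    series_conc: np.ndarray,
    t_s: np.ndarray,
    cp: np.ndarray,
) -> list[ToftsParams]:
    """Fit every row of an (n_voxels, n_frames) concentration array."""
    kernel = _ToftsKernel(cp, t_s)
    return [fit_tofts(row, cp, t_s, kernel=kernel) for row in series_conc]


def iaugc60(ct: ConcentrationCurve, window_s: float = 60.0) -> IaugcValue:
    """Initial area under the concentration curve over the first 60 s post-onset.

    Trapezoidal integration from the onset time to onset + 60 s, with linear
    interpolation at the window endpoint.  If fewer than 60 s of post-onset
    samples exist the integral runs to the last frame and is flagged truncated.
    """
    t0 = ct.t[ct.onset_frame]
    t_end = t0 + window_s
    truncated = t_end > ct.t[-1] + 1e-12
    if truncated:
        t_end = ct.t[-1]
    # dense-enough grid: frame times within the window plus the interpolated endpoint
    sel = (ct.t >= t0) & (ct.t <= t_end + 1e-12)
    tt = ct.t[sel]
    cc = ct.c[sel]
    if len(tt) == 0 or tt[-1] < t_end - 1e-12:
        c_end = np.interp(t_end, ct.t, ct.c)
        tt = np.append(tt, t_end)
        cc = np.append(cc, c_end)
    value = float(np.trapezoid(cc, tt))
    return IaugcValue(iaugc60=value, truncated=bool(truncated))


def summarise_pk(
    params: Sequence[ToftsParams],
    iaugc: Sequence[IaugcValue],
    enhancing: np.ndarray,
) -> PkRoiSummary:
    """ROI means over enhancing, converged voxels only.

    ``enhancing`` is a boolean array aligned with ``params`` marking voxels
    whose GD class is not "none" (non-enhancing voxels are excluded from mean
    parametric values).
    """
    enhancing = np.asarray(enhancing, dtype=bool)
    if len(params) != len(enhancing) or len(iaugc) != len(enhancing):
        raise ValueError("params/iaugc/enhancing lengths differ")
    eligible = [
        (p, a) for p, a, e in zip(params, iaugc, enhancing) if e and p.converged
    ]
    if not eligible:
        return PkRoiSummary(None, None, None, None, None, 0, valid=False)
    kt = np.array([p.ktrans for p, _ in eligible])
    ve = np.array([p.ve for p, _ in eligible])
    vp = np.array([p.vp for p, _ in eligible])
    au = np.array([a.iaugc60 for _, a in eligible])
    return PkRoiSummary(
        mean_ktrans=float(kt.mean()),
        mean_ve=float(ve.mean()),
        mean_vp=float(vp.mean()),
        mean_kep=float((kt / ve).mean()),
        mean_iaugc60=float(au.mean()),
        n_voxels=len(eligible),
        valid=True,
    )
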