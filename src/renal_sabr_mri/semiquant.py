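"""Semi-quantitative DCE curve analysis: the four-phase continuous
piecewise-linear enhancement model and the GD (gadolinium behaviour) map.

Each voxel's signal is normalised to the mean of the first two (baseline)
frames, then four nested continuous piecewise-linear candidates are fitted
by exhaustive search over breakpoint frames with per-segment least squares:

    M0  constant                      (non-enhancing)
    M1  constant -> rising            (persistent)
    M2  constant -> rising -> flat    (plateau)
    M3  constant -> rising -> flat -> falling   (washout)

The winner minimises a BIC-style criterion with a residual-variance floor
(see ``bic_sigma0`` below); its parameters give Tonset (first breakpoint),
IRE (uptake slope), ME (fitted maximum enhancement), and for washout voxels
Twashout (final breakpoint) and IRW (magnitude of the falling slope).
Voxels whose fitted maximum enhancement is below the non-enhancement
threshold are classified "none" regardless of the winning model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "CLASS_NAMES",
    "CLASS_CODES",
    "DynamicSeries",
    "EnhancementCurve",
    "PiecewiseFit",
    "GdSummary",
    "normalise_curve",
    "normalise_series",
    "fit_piecewise",
    "fit_piecewise_batch",
    "classify_voxel",
    "summarise_gd",
]

CLASS_NAMES = ("none", "persistent", "plateau", "washout")
CLASS_CODES = {name: i for i, name in enumerate(CLASS_NAMES)}
_N_PARAMS = np.array([1, 3, 4, 6])  # free parameters of M0..M3
MIN_SEGMENT_FRAMES = 2

DEFAULT_ENHANCEMENT_THRESHOLD = 0.05
DEFAULT_BIC_SIGMA0 = 0.05


@dataclass
class DynamicSeries:
    """A 4D DCE acquisition: signal (x, y, z, t) with uniform frame spacing."""

    signal: np.ndarray
    frame_interval_s: float

    def __post_init__(self) -> None:
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4D (x, y, z, t)")
        if self.n_frames < 4:
            raise ValueError("need at least 4 frames (2 baseline + 2 post-baseline)")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.signal.shape[3]

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames, dtype=float) * self.frame_interval_s


@dataclass
class EnhancementCurve:
    """Baseline-normalised enhancement e(t) = S(t)/S_base - 1 for one voxel."""

    e: np.ndarray
    t: np.ndarray


@dataclass
class PiecewiseFit:
    """The winning piecewise-linear model for one voxel.

    Fields that do not exist for the winning class (e.g. ``t_washout`` for a
    plateau voxel) are ``None``, never zero.
    """

    model_class: str
    sse: float
    me: Optional[float] = None
    t_onset: Optional[float] = None
    ire: Optional[float] = None
    t_washout: Optional[float] = None
    irw: Optional[float] = None


@dataclass
class GdSummary:
    """ROI-level GD-map composition and mean semi-quantitative parameters.

    Percentages are over all ROI voxels; means are over enhancing voxels only
    (Twashout/IRW over washout voxels only).  ``means_valid`` is False when
    the ROI has no enhancing voxel at all — then every mean is ``None``.
    """

    pct: dict[str, float]
    mean_me: Optional[float]
    mean_ire: Optional[float]
    mean_t_onset: Optional[float]
    mean_irw: Optional[float]
    mean_t_washout: Optional[float]
    n_voxels: int
    n_enhancing: int
    means_valid: bool


# ---------------------------------------------------------------------------
# Normalisation


def normalise_curve(signal: np.ndarray, frame_interval_s: float) -> EnhancementCurve:
    """Normalise one voxel's dynamic signal to its two-frame baseline."""
    signal = np.asarray(signal, dtype=float)
    s_base = signal[:2].mean()
    if s_base <= 0:
        raise ValueError("non-positive baseline mean; voxel unanalysable")
    t = np.arange(len(signal), dtype=float) * frame_interval_s
    return EnhancementCurve(e=signal / s_base - 1.0, t=t)


def normalise_series(series: DynamicSeries, mask: np.ndarray):
    """Normalise every masked voxel.

    Returns ``(E, ok)``: an (n_voxels, n_frames) enhancement array in mask
    order and a boolean vector marking voxels with a positive baseline
    (others are unanalysable and left as zero rows).
    """
    mask = np.asarray(mask, dtype=bool)
    sig = series.signal[mask].astype(float)  # (V, T)
    s_base = sig[:, :2].mean(axis=1)
    ok = s_base > 0
    e = np.zeros_like(sig)
    e[ok] = sig[ok] / s_base[ok, None] - 1.0
    return e, ok


# ---------------------------------------------------------------------------
# Breakpoint enumeration and batch fitting


def _breakpoint_combos(n: int):
    """Yield (model, breakpoints, basis) for every admissible breakpoint set.

    Breakpoints lie on frame indices; every segment spans at least
    ``MIN_SEGMENT_FRAMES`` frame intervals.
    """
    m = MIN_SEGMENT_FRAMES
    yield 0, (), None
    for b1 in range(1, n - m):
        yield 1, (b1,), None
        for b2 in range(b1 + m, n - m):
            yield 2, (b1, b2), None
            for b3 in range(b2 + m, n - m):
                yield 3, (b1, b2, b3), None


def _basis(model: int, bps: tuple[int, ...], t: np.ndarray) -> np.ndarray:
    n = len(t)
    cols = [np.ones(n)]
    if model >= 1:
        b1 = bps[0]
        if model == 1:
            cols.append(np.maximum(t - t[b1], 0.0))
        else:
            b2 = bps[1]
            cols.append(np.clip(t - t[b1], 0.0, t[b2] - t[b1]))
    if model == 3:
        b3 = bps[2]
        cols.append(np.maximum(t - t[b3], 0.0))
    return np.column_stack(cols)


def fit_piecewise_batch(
    E: np.ndarray,
    t: np.ndarray,
    bic_sigma0: float = DEFAULT_BIC_SIGMA0,
) -> list[PiecewiseFit]:
    """Fit the four-phase model to every row of ``E`` ((n_voxels, n_frames)).

    For each candidate breakpoint set the per-segment least-squares problem is
    linear in (level, uptake slope, washout slope) and is solved for all
    voxels at once.  Candidates whose uptake slope is negative or whose
    washout slope is positive are rejected for that voxel.  Model selection
    uses

        BIC_m = n * ln((sse_m + n * sigma0^2) / n) + k_m * ln(n)

    where ``sigma0`` is a residual floor on the enhancement scale; ties are
    broken toward the simpler model.
    """
    E = np.atleast_2d(np.asarray(E, dtype=float))
    V, n = E.shape
    t = np.asarray(t, dtype=float)
    if n != len(t):
        raise ValueError("E and t frame counts differ")
    if n < 2 * MIN_SEGMENT_FRAMES:
        raise ValueError(f"curve too short for segment support (n={n})")
    Et = E.T  # (n, V)

    best_sse = np.full((4, V), np.inf)
    # per model: best coefficients and breakpoints per voxel
    best_coef = [np.zeros((p, V)) for p in (1, 2, 2, 3)]
    best_bps = [np.zeros((nb, V), dtype=int) for nb in (0, 1, 2, 3)]

    for model, bps, _ in _breakpoint_combos(n):
        X = _basis(model, bps, t)
        P = np.linalg.pinv(X)
        B = P @ Et  # (p, V)
        resid = Et - X @ B
        sse = np.einsum("ij,ij->j", resid, resid)
        valid = np.ones(V, dtype=bool)
        if model >= 1:
            valid &= B[1] >= 0.0
        if model == 3:
            valid &= B[2] <= 0.0
        sse = np.where(valid, sse, np.inf)
        better = sse < best_sse[model]
        if better.any():
            best_sse[model][better] = sse[better]
            best_coef[model][:, better] = B[:, better]
            for j, bp in enumerate(bps):
                best_bps[model][j, better] = bp

    floor = n * bic_sigma0**2
    bic = n * np.log((best_sse + floor) / n) + _N_PARAMS[:, None] * np.log(n)
    # deterministic tie-break toward the simpler model
    winner = np.argmin(bic + 1e-12 * np.arange(4)[:, None], axis=0)

    fits: list[PiecewiseFit] = []
    for v in range(V):
        m = int(winner[v])
        sse = float(best_sse[m, v])
        if m == 0:
            c = float(best_coef[0][0, v])
            fits.append(PiecewiseFit(model_class="none", sse=sse, me=max(c, 0.0)))
            continue
        bps = best_bps[m][:, v]
        coef = best_coef[m][:, v]
        c, a = float(coef[0]), float(coef[1])
        b1 = int(bps[0])
        t_onset = float(t[b1])
        if m == 1:
            me = c + a * (t[-1] - t[b1])
            fits.append(
                PiecewiseFit("persistent", sse, me=max(float(me), 0.0), t_onset=t_onset, ire=a)
            )
        elif m == 2:
            b2 = int(bps[1])
            me = c + a * (t[b2] - t[b1])
            fits.append(
                PiecewiseFit("plateau", sse, me=max(float(me), 0.0), t_onset=t_onset, ire=a)
            )
        else:
            b2, b3 = int(bps[1]), int(bps[2])
            d = float(coef[2])
            me = c + a * (t[b2] - t[b1])
            fits.append(
                PiecewiseFit(
                    "washout",
                    sse,
                    me=max(float(me), 0.0),
                    t_onset=t_onset,
                    ire=a,
                    t_washout=float(t[b3]),
                    irw=abs(d),
                )
            )
    return fits


def fit_piecewise(curve: EnhancementCurve, bic_sigma0: float = DEFAULT_BIC_SIGMA0) -> PiecewiseFit:
    """Fit the four-phase piecewise-linear model to a single enhancement curve."""
    return fit_piecewise_batch(curve.e[None, :], curve.t, bic_sigma0=bic_sigma0)[0]


def classify_voxel(
    fit: PiecewiseFit,
    enhancement_threshold: float = DEFAULT_ENHANCEMENT_THRESHOLD,
) -> str:
    """Final GD class: the model class, overridden to "none" when the fitted
    maximum enhancement is below the non-enhancement threshold."""
    if fit.me is not None and fit.me < enhancement_threshold:
        return "none"
    return fit.model_class


def summarise_gd(
    classes: Sequence[str],
    fits: Sequence[PiecewiseFit],
) -> GdSummary:
    """ROI composition percentages and mean semi-quantitative parameters.

    Percentages are over all voxels; ME/IRE/Tonset means over enhancing
    voxels; Twashout/IRW means over washout voxels only.
    """
    if len(classes) != len(fits):
        raise ValueError("classes and fits lengths differ")
    n = len(classes)
    if n == 0:
        raise ValueError("empty ROI")
    counts = {name: 0 for name in CLASS_NAMES}
    for c in classes:
        counts[c] += 1
    pct = {name: 100.0 * counts[name] / n for name in CLASS_NAMES}

    enh = [(c, f) for c, f in zip(classes, fits) if c != "none"]
    if not enh:
        return GdSummary(pct, None, None, None, None, None, n, 0, means_valid=False)
    me = np.array([f.me for _, f in enh], dtype=float)
    ire = np.array([f.ire for _, f in enh], dtype=float)
    t_on = np.array([f.t_onset for _, f in enh], dtype=float)
    wash = [f for c, f in enh if c == "washout"]
    mean_irw = float(np.mean([f.irw for f in wash])) if wash else None
    mean_tw = float(np.mean([f.t_washout for f in wash])) if wash else None
    return GdSummary(
        pct=pct,
        mean_me=float(me.mean()),
        mean_ire=float(ire.mean()),
        mean_t_onset=float(t_on.mean()),
        mean_irw=mean_irw,
        mean_t_washout=mean_tw,
        n_voxels=n,
        n_enhancing=len(enh),
        means_valid=True,
    )
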