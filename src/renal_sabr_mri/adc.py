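"""ADC mapping from multi-b-value DWI and ROI histogram statistics.

The apparent diffusion coefficient is the decay constant of the
mono-exponential model S(b) = S0 exp(-b * ADC); per voxel it is estimated by
ordinary least squares of ln S on b.  ROI statistics use the conventions of
the numerical environment the original analysis was run in: skewness is the
biased third standardised moment and kurtosis is the biased Pearson fourth
standardised moment (normal = 3).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as sps

__all__ = [
    "DwiStack",
    "AdcMap",
    "RoiHistogramStats",
    "fit_adc",
    "roi_histogram_stats",
    "adc_change",
]


@dataclass
class DwiStack:
    """Multi-b-value DWI: signal (x, y, z, b) aligned with ``b_values``."""

    signal: np.ndarray
    b_values: np.ndarray  # s/mm^2, strictly increasing
    voxel_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.b_values = np.asarray(self.b_values, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4D (x, y, z, b)")
        if len(self.b_values) < 2:
            raise ValueError("need at least 2 b-values")
        if not np.all(np.diff(self.b_values) > 0):
            raise ValueError("b_values must be strictly increasing")
        if self.signal.shape[3] != len(self.b_values):
            raise ValueError("4th dimension must match number of b-values")


@dataclass
class AdcMap:
    adc: np.ndarray  # mm^2/s
    s0: np.ndarray  # extrapolated b=0 signal
    fit_valid: np.ndarray  # bool


@dataclass
class RoiHistogramStats:
    """ADC histogram measures over one tumour ROI.

    ``skewness``/``kurtosis`` are ``None`` (with ``moments_valid`` False) for
    zero-variance ROIs, where the standardised moments are undefined.
    """

    mean: float
    median: float
    skewness: Optional[float]
    kurtosis: Optional[float]
    n_voxels: int
    moments_valid: bool = True


def fit_adc(stack: DwiStack) -> AdcMap:
    """Voxelwise mono-exponential fit: OLS of ln S on b.

    ADC = -slope, S0 = exp(intercept).  Voxels with any non-positive signal
    are flagged invalid; negative fitted ADC (supra-exponential noise) is
    clamped to zero and flagged.
    """
    sig = stack.signal.astype(float)
    b = stack.b_values
    valid = np.all(sig > 0, axis=3)
    logs = np.where(sig > 0, np.log(np.where(sig > 0, sig, 1.0)), 0.0)
    # closed-form OLS over the b axis
    bc = b - b.mean()
    denom = float((bc**2).sum())
    slope = np.tensordot(logs, bc, axes=([3], [0])) / denom
    intercept = logs.mean(axis=3) - slope * b.mean()
    adc = -slope
    s0 = np.exp(intercept)
    negative = adc < 0
    valid = valid & ~negative
    adc = np.where(negative, 0.0, adc)
    adc = np.where(np.all(sig > 0, axis=3), adc, np.nan)
    s0 = np.where(np.all(sig > 0, axis=3), s0, np.nan)
    return AdcMap(adc=adc, s0=s0, fit_valid=valid)


def roi_histogram_stats(adc_map: AdcMap, mask: np.ndarray) -> RoiHistogramStats:
    """Mean, median, skewness and kurtosis of ADC over fit-valid ROI voxels."""
    mask = np.asarray(mask, dtype=bool)
    eff = mask & adc_map.fit_valid
    values = adc_map.adc[eff]
    if values.size == 0:
        raise ValueError("empty effective ROI (no valid voxels under the mask)")
    mean = float(values.mean())
    median = float(np.median(values))
    if values.size < 2 or np.allclose(values, values[0]):
        return RoiHistogramStats(mean, median, None, None, int(values.size), moments_valid=False)
    skew = float(sps.skew(values, bias=True))
    kurt = float(sps.kurtosis(values, fisher=False, bias=True))
    return RoiHistogramStats(mean, median, skew, kurt, int(values.size))


def adc_change(baseline: RoiHistogramStats, followup: RoiHistogramStats) -> dict[str, Optional[float]]:
    """Follow-up minus baseline for each histogram statistic (absolute change)."""

    def diff(a: Optional[float], b: Optional[float]) -> Optional[float]:
        return None if a is None or b is None else b - a

    return {
        "mean": followup.mean - baseline.mean,
        "median": followup.median - baseline.median,
        "skewness": diff(baseline.skewness, followup.skewness),
        "kurtosis": diff(baseline.kurtosis, followup.kurtosis),
    }
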