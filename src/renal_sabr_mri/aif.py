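"""Population arterial input function.

Clinical DCE analyses of the kidney typically measure the AIF in an aorta
ROI.  A digital phantom has no aorta to measure, so the generator drives the
kinetic model with a parametric population curve instead: a gamma-variate
first pass plus a dispersed bi-exponential equilibrium tail.  The tail decay
constants sit on the contrast-agent redistribution / renal-excretion
timescales (minutes to hours), so the plasma level is nearly flat over a
2.6-minute acquisition — which is what makes slow-uptake tissue enhance as a
steady ramp rather than a bolus-shaped transient.

The curve returned is the *plasma* concentration Cp(t) in mM.  Whole-blood
concentration (what an aorta voxel's signal reflects) is Cp * (1 - Hct).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AifModel", "DEFAULT_AIF", "make_population_aif", "population_aif"]


@dataclass(frozen=True)
class AifModel:
    """Constants of the parametric population AIF.

    First pass: ``a_bolus * (t/t_peak)^sharpness * exp(sharpness*(1 - t/t_peak))``
    (gamma variate, peaking at ``a_bolus`` mM at ``t_peak`` seconds after onset).
    Tail: ``a_tail * (1 - exp(-t/tau_rise)) * (f_fast*exp(-t/tau_fast)
    + (1-f_fast)*exp(-t/tau_slow))``.
    """

    a_bolus_mM: float = 1.2
    t_peak_s: float = 12.0
    sharpness: float = 2.0
    a_tail_mM: float = 1.0
    tau_rise_s: float = 5.0
    tau_fast_s: float = 900.0
    tau_slow_s: float = 5400.0
    f_fast: float = 0.4


DEFAULT_AIF = AifModel()


def population_aif(t_s: np.ndarray, onset_s: float, model: AifModel = DEFAULT_AIF) -> np.ndarray:
    """Evaluate the population plasma concentration Cp(t) in mM.

    Parameters
    ----------
    t_s:
        Sample times in seconds (any shape).
    onset_s:
        Contrast-arrival time in seconds; Cp is exactly zero for t <= onset_s.
    """
    t_s = np.asarray(t_s, dtype=float)
    tt = t_s - onset_s
    pos = tt > 0
    ttp = np.where(pos, tt, 1.0)  # dummy positive value where curve is zero
    first_pass = (
        model.a_bolus_mM
        * (ttp / model.t_peak_s) ** model.sharpness
        * np.exp(model.sharpness * (1.0 - ttp / model.t_peak_s))
    )
    tail = (
        model.a_tail_mM
        * (1.0 - np.exp(-ttp / model.tau_rise_s))
        * (
            model.f_fast * np.exp(-ttp / model.tau_fast_s)
            + (1.0 - model.f_fast) * np.exp(-ttp / model.tau_slow_s)
        )
    )
    return np.where(pos, first_pass + tail, 0.0)


def make_population_aif(
    n_frames: int,
    frame_interval_s: float,
    onset_frame: int,
    model: AifModel = DEFAULT_AIF,
) -> np.ndarray:
    """Population AIF sampled on the dynamic frame grid.

    Returns the plasma concentration (mM) at frame times ``k * frame_interval_s``
    for k = 0..n_frames-1.  Frames strictly before ``onset_frame`` are zero.
    Deterministic for fixed arguments.

    Raises
    ------
    ValueError
        If ``onset_frame`` is not a valid frame index.
    """
    if n_frames < 1:
        raise ValueError(f"n_frames must be positive, got {n_frames}")
    if frame_interval_s <= 0:
        raise ValueError(f"frame_interval_s must be positive, got {frame_interval_s}")
    if not 0 <= onset_frame < n_frames:
        raise ValueError(
            f"onset_frame {onset_frame} out of range for {n_frames} frames"
        )
    t = np.arange(n_frames, dtype=float) * frame_interval_s
    return population_aif(t, onset_frame * frame_interval_s, model)
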