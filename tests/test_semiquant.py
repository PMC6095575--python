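"""Piecewise-linear enhancement model, classification and GD summaries."""

import numpy as np
import pytest

from renal_sabr_mri.semiquant import (
    DynamicSeries,
    EnhancementCurve,
    PiecewiseFit,
    classify_voxel,
    fit_piecewise,
    fit_piecewise_batch,
    normalise_curve,
    normalise_series,
    summarise_gd,
)

DT = 5.2
T30 = np.arange(30) * DT


def _curve(e: np.ndarray) -> EnhancementCurve:
    return EnhancementCurve(e=np.asarray(e, dtype=float), t=np.arange(len(e)) * DT)


def test_normalise_constant_signal_is_zero():
    c = normalise_curve(np.full(10, 100.0), DT)
    np.testing.assert_allclose(c.e, 0.0, atol=1e-15)


def test_normalise_arithmetic():
    sig = np.array([100.0, 100.0, 200.0, 150.0])
    c = normalise_curve(sig, DT)
    assert c.e[2] == pytest.approx(1.0)
    assert c.e[:2].mean() == pytest.approx(0.0)


def test_normalise_rejects_nonpositive_baseline():
    with pytest.raises(ValueError, match="baseline"):
        normalise_curve(np.array([0.0, 0.0, 5.0, 5.0]), DT)


def test_series_invariants():
    with pytest.raises(ValueError, match="4 frames"):
        DynamicSeries(signal=np.zeros((2, 2, 2, 3)), frame_interval_s=DT)
    with pytest.raises(ValueError, match="positive"):
        DynamicSeries(signal=np.zeros((2, 2, 2, 5)), frame_interval_s=0.0)


def test_flat_zero_curve_is_none_with_zero_sse():
    fit = fit_piecewise(_curve(np.zeros(30)))
    assert fit.model_class == "none"
    assert fit.sse == pytest.approx(0.0, abs=1e-20)
    assert fit.t_onset is None and fit.ire is None
    assert fit.t_washout is None and fit.irw is None


def test_noiseless_trapezoid_classified_washout_with_parameters():
    """Flat 0 to frame 4, rise to 1.0 by frame 10, plateau to frame 20, fall
    to 0.5 at frame 29: the washout model must recover the breakpoints and
    slopes of the generating trapezoid."""
    e = np.zeros(30)
    e[4:10] = (np.arange(4, 10) - 4) / 6.0
    e[10:20] = 1.0
    e[20:] = 1.0 - 0.5 * (np.arange(20, 30) - 20) / 9.0
    # make the segments exactly linear between breakpoints
    e[4:11] = np.interp(np.arange(4, 11), [4, 10], [0.0, 1.0])
    e[20:30] = np.interp(np.arange(20, 30), [20, 29], [1.0, 0.5])
    fit = fit_piecewise(_curve(e))
    assert fit.model_class == "washout"
    assert abs(fit.t_onset - 4 * DT) <= DT
    assert fit.me == pytest.approx(1.0, abs=0.01)
    assert fit.irw == pytest.approx(0.5 / (9 * DT), rel=0.05)
    assert fit.t_washout == pytest.approx(20 * DT, abs=DT)


def test_monotone_ramp_is_persistent_without_washout_fields():
    e = np.concatenate([np.zeros(5), np.linspace(0.0, 1.0, 25)])
    fit = fit_piecewise(_curve(e))
    assert fit.model_class == "persistent"
    assert fit.t_washout is None and fit.irw is None
    assert fit.ire >= 0


def test_winner_sse_never_exceeds_constant_model_sse():
    rng = np.random.default_rng(0)
    for _ in range(10):
        e = rng.normal(0.2, 0.1, size=30).cumsum() / 10
        fit = fit_piecewise(_curve(e))
        sse0 = float(((e - e.mean()) ** 2).sum())
        assert fit.sse <= sse0 + 1e-9


def test_scale_invariance_of_class_and_fit():
    """Multiplying the raw signal by any c > 0 leaves e(t), the fit and the
    class unchanged."""
    sig = 100.0 + np.concatenate([np.zeros(5), np.linspace(0, 80, 25)])
    for c in (0.5, 3.0, 117.0):
        c1 = normalise_curve(sig, DT)
        c2 = normalise_curve(c * sig, DT)
        np.testing.assert_allclose(c1.e, c2.e, rtol=1e-12)
        f1, f2 = fit_piecewise(c1), fit_piecewise(c2)
        assert f1.model_class == f2.model_class
        assert f1.me == pytest.approx(f2.me, rel=1e-9)


def test_too_short_curve_rejected():
    with pytest.raises(ValueError, match="too short"):
        fit_piecewise_batch(np.zeros((1, 3)), np.arange(3) * DT)


def test_threshold_override_to_none():
    weak = PiecewiseFit(model_class="washout", sse=0.0, me=0.01, t_onset=10.0, ire=0.001)
    assert classify_voxel(weak, enhancement_threshold=0.05) == "none"
    strong = PiecewiseFit(model_class="washout", sse=0.0, me=0.5, t_onset=10.0, ire=0.01)
    assert classify_voxel(strong) == "washout"


# ---------------------------------------------------------------------------
# summaries


def test_summary_all_none_has_absent_means():
    fits = [PiecewiseFit("none", 0.0, me=0.0) for _ in range(5)]
    s = summarise_gd(["none"] * 5, fits)
    assert s.pct == {"none": 100.0, "persistent": 0.0, "plateau": 0.0, "washout": 0.0}
    assert not s.means_valid
    assert s.mean_me is None and s.mean_ire is None


def test_summary_percentage_arithmetic():
    fits = []
    classes = []
    for _ in range(4):
        fits.append(PiecewiseFit("washout", 0.0, me=1.0, t_onset=20.0, ire=0.01,
                                 t_washout=100.0, irw=0.005))
        classes.append("washout")
    for _ in range(6):
        fits.append(PiecewiseFit("plateau", 0.0, me=0.5, t_onset=25.0, ire=0.02))
        classes.append("plateau")
    s = summarise_gd(classes, fits)
    assert s.pct["washout"] == pytest.approx(40.0)
    assert sum(s.pct.values()) == pytest.approx(100.0, abs=1e-6)
    assert s.mean_me == pytest.approx((4 * 1.0 + 6 * 0.5) / 10)
    # washout-only means
    assert s.mean_irw == pytest.approx(0.005)
    assert s.mean_t_washout == pytest.approx(100.0)


def test_percentages_sum_to_100_on_phantom(noiseless_mix_phantom):
    cfg, signal, roi, _, _ = noiseless_mix_phantom
    series = DynamicSeries(signal=signal, frame_interval_s=cfg.frame_interval_s)
    E, ok = normalise_series(series, roi)
    fits = fit_piecewise_batch(E[:200], series.frame_times)
    classes = [classify_voxel(f) for f in fits]
    s = summarise_gd(classes, fits)
    assert sum(s.pct.values()) == pytest.approx(100.0, abs=1e-6)


def test_noiseless_phantom_round_trip_enhancement(noiseless_mix_phantom):
    """Normalisation of the noiseless phantom signal reproduces the
    generator's enhancement curves to numerical precision."""
    cfg, signal, roi, _, truth = noiseless_mix_phantom
    series = DynamicSeries(signal=signal, frame_interval_s=cfg.frame_interval_s)
    E, ok = normalise_series(series, roi)
    assert ok.all()
    raw = truth.noiseless_signal[roi]
    expected = raw / raw[:, :2].mean(axis=1, keepdims=True) - 1.0
    np.testing.assert_allclose(E, expected, atol=1e-12)
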