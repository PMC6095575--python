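"""Signal-concentration conversion, extended Tofts model, fitting, iAUGC60."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from renal_sabr_mri.aif import make_population_aif
from renal_sabr_mri.config import PkConstants
from renal_sabr_mri.pk import (
    ConcentrationCurve,
    IaugcValue,
    ToftsParams,
    extract_aif,
    fit_tofts,
    iaugc60,
    signal_to_concentration,
    spgr_signal,
    summarise_pk,
    tofts_forward,
)

CONSTS = PkConstants()
DT = 5.2
T30 = np.arange(30) * DT


def _signal_from_conc(c: np.ndarray, t1_s: float, base_signal: float = 200.0) -> np.ndarray:
    r1_0 = 1.0 / t1_s
    m0 = base_signal / spgr_signal(1.0, r1_0, CONSTS)
    return spgr_signal(m0, r1_0 + CONSTS.relaxivity_r1 * c, CONSTS)


def test_constant_signal_gives_zero_concentration():
    sig = np.full(30, 180.0)
    curve = signal_to_concentration(sig, DT, 5, CONSTS.t1_tissue_s, CONSTS)
    np.testing.assert_allclose(curve.c, 0.0, atol=1e-12)


def test_spgr_forward_inverse_round_trip():
    """Forward SPGR then inversion returns the concentration to 1e-9 over the
    physiological range."""
    c = np.concatenate([np.zeros(5), np.linspace(0.0, 6.0, 25)])
    sig = _signal_from_conc(c, CONSTS.t1_tissue_s)
    curve = signal_to_concentration(sig, DT, 5, CONSTS.t1_tissue_s, CONSTS)
    np.testing.assert_allclose(curve.c, c, atol=1e-9)


def test_concentration_linear_in_delta_r1():
    """Doubling the R1 increment doubles the reported concentration."""
    r1_0 = 1.0 / CONSTS.t1_tissue_s
    m0 = 200.0 / spgr_signal(1.0, r1_0, CONSTS)
    for dr1 in (0.5, 1.0):
        sig = np.full(30, 200.0)
        sig[5:] = spgr_signal(m0, r1_0 + dr1, CONSTS)
        c1 = signal_to_concentration(sig, DT, 5, CONSTS.t1_tissue_s, CONSTS).c[-1]
        sig[5:] = spgr_signal(m0, r1_0 + 2 * dr1, CONSTS)
        c2 = signal_to_concentration(sig, DT, 5, CONSTS.t1_tissue_s, CONSTS).c[-1]
        assert c2 == pytest.approx(2 * c1, rel=1e-9)


def test_linear_approximation_mode_close_to_exact_at_low_concentration():
    lin = PkConstants(linear_concentration=True)
    c = np.concatenate([np.zeros(5), np.full(25, 0.2)])
    sig = _signal_from_conc(c, CONSTS.t1_tissue_s)
    exact = signal_to_concentration(sig, DT, 5, CONSTS.t1_tissue_s, CONSTS).c[-1]
    approx = signal_to_concentration(sig, DT, 5, lin.t1_tissue_s, lin).c[-1]
    assert approx == pytest.approx(exact, rel=0.05)


def test_ill_conditioned_setup_rejected_at_configuration():
    bad = PkConstants(flip_angle_deg=1e-7)
    with pytest.raises(ValueError, match="ill-conditioned"):
        signal_to_concentration(np.full(30, 100.0), DT, 5, bad.t1_tissue_s, bad)


# ---------------------------------------------------------------------------
# AIF extraction


def _aorta_series(cp: np.ndarray, n_vox: int = 4) -> np.ndarray:
    cb = cp * (1.0 - CONSTS.hematocrit)
    sig = _signal_from_conc(cb, CONSTS.t1_blood_s, base_signal=250.0)
    vol = np.tile(sig, (n_vox, 1, 1, 1))
    return vol.reshape(n_vox, 1, 1, -1)


def test_extract_aif_single_voxel_and_hematocrit():
    cp = make_population_aif(30, DT, 5)
    series = _aorta_series(cp, n_vox=1)
    mask = np.ones((1, 1, 1), dtype=bool)
    curve = extract_aif(series, mask, DT, 5, CONSTS)
    np.testing.assert_allclose(curve.c, cp, atol=1e-6)
    # hematocrit 0: plasma equals blood
    no_hct = PkConstants(hematocrit=0.0)
    series0 = _signal_from_conc(cp, CONSTS.t1_blood_s, 250.0).reshape(1, 1, 1, -1)
    curve0 = extract_aif(series0, mask, DT, 5, no_hct)
    np.testing.assert_allclose(curve0.c, cp, atol=1e-6)


def test_extract_aif_empty_mask_rejected():
    with pytest.raises(ValueError, match="empty aorta mask"):
        extract_aif(np.zeros((2, 2, 2, 30)), np.zeros((2, 2, 2), dtype=bool), DT, 5, CONSTS)


def test_phantom_aif_recovery(noiseless_mix_phantom):
    cfg, signal, roi, aorta, truth = noiseless_mix_phantom
    curve = extract_aif(signal, aorta, cfg.frame_interval_s, cfg.onset_frame, cfg.pk_constants)
    post = slice(cfg.onset_frame + 1, None)
    rel = np.abs(curve.c[post] - truth.aif_plasma[post]) / truth.aif_plasma[post]
    assert rel.max() < 0.01


# ---------------------------------------------------------------------------
# Tofts forward model


def test_tofts_trivial_zero_and_plasma_only():
    cp = make_population_aif(30, DT, 5)
    np.testing.assert_allclose(tofts_forward(0.0, 0.3, 0.0, cp, T30), 0.0, atol=1e-15)
    np.testing.assert_allclose(tofts_forward(0.0, 0.3, 0.1, cp, T30), 0.1 * cp, atol=1e-15)


def test_tofts_invalid_parameters():
    cp = make_population_aif(30, DT, 5)
    with pytest.raises(ValueError, match="ve = 0"):
        tofts_forward(0.2, 0.0, 0.0, cp, T30)


def test_tofts_constant_input_matches_closed_form():
    """For Cp = C0 from t = 0, Ct = ve C0 (1 - exp(-kep t)) + vp C0; the
    trapezoidal convolution on a dt = 0.1 s grid matches within 1e-4."""
    ktrans, ve, vp, c0 = 0.3, 0.4, 0.05, 2.0
    t = np.arange(0.0, 120.0, 0.1)
    cp = np.full_like(t, c0)
    ct = tofts_forward(ktrans, ve, vp, cp, t)
    kep_s = (ktrans / ve) / 60.0
    closed = ve * c0 * (1.0 - np.exp(-kep_s * t)) + vp * c0
    assert np.abs(ct - closed).max() < 1e-4


def test_tofts_linear_in_cp():
    cp = make_population_aif(30, DT, 5)
    ct1 = tofts_forward(0.25, 0.3, 0.05, cp, T30)
    ct3 = tofts_forward(0.25, 0.3, 0.05, 3.0 * cp, T30)
    np.testing.assert_allclose(ct3, 3.0 * ct1, rtol=1e-12)


def test_tofts_nonnegative_for_nonnegative_input():
    cp = make_population_aif(30, DT, 5)
    ct = tofts_forward(0.8, 0.2, 0.1, cp, T30)
    assert ct.min() >= 0.0


# ---------------------------------------------------------------------------
# fitting


def test_fit_recovers_reference_parameters():
    cp = make_population_aif(30, DT, 5)
    ct = tofts_forward(0.25, 0.3, 0.05, cp, T30)
    p = fit_tofts(ct, cp, T30)
    assert p.converged
    assert p.ktrans == pytest.approx(0.25, rel=0.05)
    assert p.ve == pytest.approx(0.3, rel=0.05)
    assert p.vp == pytest.approx(0.05, rel=0.05)
    # derived kep consistency
    assert p.kep * p.ve == pytest.approx(p.ktrans, abs=1e-9)


def test_fit_recovery_grid_within_5pct():
    """3x3x3 grid spanning the physiological ranges, noiseless."""
    cp = make_population_aif(30, DT, 5)
    for kt in (0.05, 0.3, 0.8):
        for ve in (0.1, 0.4, 0.9):
            for vp in (0.03, 0.08, 0.15):
                ct = tofts_forward(kt, ve, vp, cp, T30)
                p = fit_tofts(ct, cp, T30)
                assert p.ktrans == pytest.approx(kt, rel=0.05), (kt, ve, vp)
                assert p.ve == pytest.approx(ve, rel=0.05), (kt, ve, vp)
                assert p.vp == pytest.approx(vp, rel=0.05), (kt, ve, vp)


def test_fit_zero_curve_gives_zero_transfer():
    cp = make_population_aif(30, DT, 5)
    p = fit_tofts(np.zeros(30), cp, T30)
    assert p.ktrans == pytest.approx(0.0, abs=1e-6)
    assert p.vp == pytest.approx(0.0, abs=1e-6)


# ---------------------------------------------------------------------------
# iAUGC60


def _cc(c: np.ndarray, onset: int = 0, dt: float = DT) -> ConcentrationCurve:
    return ConcentrationCurve(c=np.asarray(c, float), t=np.arange(len(c)) * dt, onset_frame=onset)


def test_iaugc_constant_curve():
    n = 20
    val = iaugc60(_cc(np.ones(n), onset=0, dt=5.0))
    assert val.iaugc60 == pytest.approx(60.0)
    assert not val.truncated


def test_iaugc_zero_curve():
    assert iaugc60(_cc(np.zeros(30))).iaugc60 == 0.0


def test_iaugc_linear_ramp_triangle_area():
    t = np.arange(0, 61, 5.0)
    c = t / 60.0
    val = iaugc60(ConcentrationCurve(c=c, t=t, onset_frame=0))
    assert val.iaugc60 == pytest.approx(30.0)


def test_iaugc_truncation_flagged():
    val = iaugc60(_cc(np.ones(8), onset=0, dt=5.0))  # only 35 s of samples
    assert val.truncated
    assert val.iaugc60 == pytest.approx(35.0)


@settings(derandomize=True, max_examples=20)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_iaugc_monotone_in_pointwise_increase(seed):
    r = np.random.default_rng(seed)
    c = np.abs(r.normal(1.0, 0.5, size=30))
    bump = np.abs(r.normal(0.0, 0.2, size=30))
    lo = iaugc60(_cc(c, onset=2))
    hi = iaugc60(_cc(c + bump, onset=2))
    assert hi.iaugc60 >= lo.iaugc60 - 1e-12


# ---------------------------------------------------------------------------
# ROI summary


def _params(kt: float, conv: bool = True) -> ToftsParams:
    return ToftsParams(ktrans=kt, ve=0.4, vp=0.05, fit_rss=0.0, converged=conv)


def test_summarise_pk_means_over_enhancing_converged_only():
    params = [_params(0.2), _params(0.4), _params(9.9, conv=False), _params(7.7)]
    aucs = [IaugcValue(10.0), IaugcValue(20.0), IaugcValue(99.0), IaugcValue(50.0)]
    enhancing = np.array([True, True, True, False])
    s = summarise_pk(params, aucs, enhancing)
    assert s.valid
    assert s.n_voxels == 2
    assert s.mean_ktrans == pytest.approx(0.3)
    assert s.mean_iaugc60 == pytest.approx(15.0)


def test_summarise_pk_all_nonenhancing_absent():
    s = summarise_pk([_params(0.2)], [IaugcValue(1.0)], np.array([False]))
    assert not s.valid
    assert s.mean_ktrans is None
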