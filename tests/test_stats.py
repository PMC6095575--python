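"""Spearman correlation (exact and approximate p-values) and change tables."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from renal_sabr_mri.stats import build_change_table, correlate_all, spearman


def test_perfect_monotone_rho_one():
    x = np.arange(10.0)
    y = x**3 + 2
    res = spearman(x, y)
    assert res.rho == pytest.approx(1.0)
    assert res.p_value < 0.01
    assert res.significant


def test_perfect_antitone_rho_minus_one():
    x = np.arange(8.0)
    assert spearman(x, -np.exp(x)).rho == pytest.approx(-1.0)


def test_constant_input_rejected():
    with pytest.raises(ValueError, match="constant"):
        spearman(np.ones(6), np.arange(6.0))


def test_minimum_pairs_enforced():
    with pytest.raises(ValueError, match="at least 4"):
        spearman([1, 2, 3], [3, 2, 1])


def test_fixed_pairs_match_rank_pearson_and_permutation_oracle():
    """n = 6 fixed pairs: rho equals rank-then-Pearson computed from scratch;
    the exact p equals enumeration over all 720 permutations."""
    x = np.array([0.3, -1.2, 2.5, 0.7, -0.4, 1.9])
    y = np.array([10.0, 4.0, 12.0, 9.0, 6.0, 8.0])
    res = spearman(x, y)
    assert res.method == "exact"
    # oracle 1: rank then Pearson
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho_oracle = np.corrcoef(rx, ry)[0, 1]
    assert res.rho == pytest.approx(rho_oracle, abs=1e-12)
    # oracle 2: enumerate all permutations, Pearson of ranks each time
    count = 0
    for perm in permutations(ry):
        r = np.corrcoef(rx, np.array(perm))[0, 1]
        if abs(r) >= abs(rho_oracle) - 1e-12:
            count += 1
    assert res.p_value == pytest.approx(count / 720, abs=1e-12)
    # scipy agreement on the statistic
    assert res.rho == pytest.approx(sps.spearmanr(x, y).statistic, abs=1e-12)


def test_ties_fall_back_to_t_approximation_with_midranks():
    x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0])
    y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
    res = spearman(x, y)
    assert res.method == "t-approx"
    assert res.rho == pytest.approx(sps.spearmanr(x, y).statistic, abs=1e-12)


def test_monotone_transform_invariance():
    rng = np.random.default_rng(5)
    x = rng.normal(size=12)
    y = rng.normal(size=12)
    base = spearman(x, y).rho
    assert spearman(np.exp(x), y).rho == pytest.approx(base, abs=1e-12)
    assert spearman(x, y**3).rho == pytest.approx(base, abs=1e-12)
    assert spearman(-1 / (1 + np.exp(-x)), -y).rho == pytest.approx(base, abs=1e-12)


def test_exact_and_t_approx_agree_for_moderate_rho_at_n9():
    """|rho| <= 0.5 at n = 9: the two p-value routes agree within 0.02."""
    rng = np.random.default_rng(17)
    checked = 0
    while checked < 3:
        x = rng.permutation(9).astype(float)
        y = rng.permutation(9).astype(float)
        res = spearman(x, y)
        if abs(res.rho) > 0.5:
            continue
        denom = max(1.0 - res.rho**2, 1e-15)
        t = res.rho * np.sqrt((res.n - 2) / denom)
        p_t = 2 * sps.t.sf(abs(t), df=res.n - 2)
        assert res.method == "exact"
        assert abs(res.p_value - p_t) < 0.02
        checked += 1


# ---------------------------------------------------------------------------
# change tables


def _mri_long(rows):
    return pd.DataFrame(rows, columns=["patient_id", "mri_scan", "parameter", "modality", "value"])


def _vols(rows):
    return pd.DataFrame(rows, columns=["patient_id", "timepoint", "pct_change_vs_baseline"])


def test_identical_summaries_give_zero_change():
    mri = _mri_long([
        ("1", "baseline", "adc_mean", "adc", 1.2e-3),
        ("1", "f1", "adc_mean", "adc", 1.2e-3),
    ])
    vols = _vols([("1", "last", -20.0)])
    table = build_change_table(mri, vols)
    assert len(table) == 1
    assert table.iloc[0]["change"] == 0.0


def test_dce_exclusion_keeps_adc_rows():
    mri = _mri_long([
        ("5", "baseline", "adc_mean", "adc", 1.0), ("5", "f1", "adc_mean", "adc", 1.1),
        ("5", "baseline", "mean_ktrans", "dce", 0.2), ("5", "f1", "mean_ktrans", "dce", 0.3),
        ("6", "baseline", "mean_ktrans", "dce", 0.2), ("6", "f1", "mean_ktrans", "dce", 0.1),
    ])
    vols = _vols([("5", "last", -10.0), ("6", "last", 5.0)])
    table = build_change_table(mri, vols, dce_exclusions=("5",))
    params_p5 = set(table[table.patient_id == "5"].parameter)
    assert params_p5 == {"adc_mean"}
    assert set(table[table.patient_id == "6"].parameter) == {"mean_ktrans"}


def test_missing_baseline_drops_patient():
    mri = _mri_long([("1", "f1", "adc_mean", "adc", 1.0)])
    table = build_change_table(mri, _vols([("1", "last", 0.0)]))
    assert len(table) == 0


def test_correlate_all_reports_small_cells_as_absent():
    mri = _mri_long([
        (pid, scan, "mean_ktrans", "dce", v)
        for pid, scan, v in [("1", "baseline", 0.1), ("1", "f1", 0.2),
                             ("2", "baseline", 0.1), ("2", "f1", 0.3)]
    ])
    vols = _vols([("1", "last", 1.0), ("2", "last", 2.0)])
    corr = correlate_all(build_change_table(mri, vols))
    assert len(corr) == 1
    assert not corr.iloc[0]["significant"]
    assert "absent" in corr.iloc[0]["method"]


def test_correlate_all_perfect_monotone_cell():
    rows = []
    vols = []
    for i in range(6):
        pid = str(i)
        rows += [(pid, "baseline", "mean_ktrans", "dce", 0.1),
                 (pid, "f1", "mean_ktrans", "dce", 0.1 + 0.05 * i)]
        vols.append((pid, "last", float(10 * i)))
    corr = correlate_all(build_change_table(_mri_long(rows), _vols(vols)))
    cell = corr.iloc[0]
    assert cell["rho"] == pytest.approx(1.0)
    assert cell["significant"]


def test_null_type_one_error_near_nominal(rng):
    """Independent columns, 1000 replicate tables at n = 10: the p <= 0.05
    rejection rate stays within 3 Monte-Carlo sd of 0.05."""
    n_rep, n = 1000, 10
    hits = 0
    for _ in range(n_rep):
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        if spearman(x, y).p_value <= 0.05:
            hits += 1
    rate = hits / n_rep
    sd = np.sqrt(0.05 * 0.95 / n_rep)
    assert abs(rate - 0.05) <= 3 * sd
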