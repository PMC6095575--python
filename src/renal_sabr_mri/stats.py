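"""Spearman rank correlation of MRI-parameter changes against CT volume
changes, mirroring the per-patient change-table analysis.

The p-value policy follows the convention of R's correlation test as applied
in the original analysis: for small samples (n <= 9) without ties the exact
permutation distribution of the statistic is enumerated; otherwise the
t approximation t = rho * sqrt((n-2)/(1-rho^2)) with n-2 degrees of freedom
is used.  Two-sided throughout; p <= 0.05 flags significance.  No
multiple-comparison adjustment is applied by default (a Benjamini-Hochberg
switch is available for users who want one).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "spearman",
    "build_change_table",
    "correlate_all",
    "format_correlation_table",
]

SIGNIFICANCE_LEVEL = 0.05
EXACT_P_MAX_N = 9


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    significant: bool
    method: str  # "exact" | "t-approx"


def _rank_average(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _rho_from_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        raise ValueError("constant input; Spearman rho undefined")
    return float((rx * ry).sum() / denom)


def _exact_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact p by full enumeration of rank permutations.

    Without ties, rho is a linear function of S = sum (rx - perm(ry))^2, so
    the permutation distribution of S gives the distribution of rho.
    """
    n = len(rx)
    s_obs = ((rx - ry) ** 2).sum()
    # rho = 1 - 6 S / (n^3 - n); |rho| >= |rho_obs|  <=>  |S - mu| >= |S_obs - mu|
    mu = (n**3 - n) / 6.0  # S value at rho = 0
    count = 0
    total = 0
    ry_sorted = np.sort(ry)
    for perm in permutations(ry_sorted):
        s = ((rx - np.array(perm)) ** 2).sum()
        if abs(s - mu) >= abs(s_obs - mu) - 1e-9:
            count += 1
        total += 1
    return count / total


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with the hybrid exact/approximate p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 4:
        raise ValueError(f"need at least 4 complete pairs, got {n}")
    rx, ry = _rank_average(x), _rank_average(y)
    rho = _rho_from_ranks(rx, ry)
    has_ties = len(np.unique(x)) < n or len(np.unique(y)) < n
    if n <= EXACT_P_MAX_N and not has_ties:
        p = _exact_p(rx, ry, rho)
        method = "exact"
    else:
        denom = max(1.0 - rho**2, 1e-15)
        tstat = rho * np.sqrt((n - 2) / denom)
        p = float(2.0 * sps.t.sf(abs(tstat), df=n - 2))
        method = "t-approx"
    p = min(p, 1.0)
    return CorrelationResult(rho=rho, p_value=p, n=n, significant=p <= SIGNIFICANCE_LEVEL, method=method)


# ---------------------------------------------------------------------------
# Change tables


def build_change_table(
    mri_values: pd.DataFrame,
    volume_changes: pd.DataFrame,
    dce_exclusions: tuple[str, ...] | list[str] = (),
) -> pd.DataFrame:
    """Per-patient changes of each MRI parameter versus baseline, joined with
    CT volume changes.

    Parameters
    ----------
    mri_values:
        Long format: columns ``patient_id, mri_scan, parameter, modality, value``
        where ``mri_scan`` is "baseline", "f1" or "f2" and ``modality`` is
        "adc" or "dce".
    volume_changes:
        Columns ``patient_id, timepoint, pct_change_vs_baseline``.
    dce_exclusions:
        Patients removed from all DCE-modality rows (e.g. divergent histology
        or scans in which no voxel fitted); their ADC rows are kept.

    Returns a long table ``patient_id, mri_scan, parameter, modality, change,
    ct_timepoint, ct_pct_change`` with one row per correlation-ready pair.
    Patients without a baseline value for a parameter are dropped from that
    parameter's rows.
    """
    mri = mri_values.copy()
    mri["patient_id"] = mri["patient_id"].astype(str)
    excl = {str(p) for p in dce_exclusions}
    mri = mri[~((mri["modality"] == "dce") & (mri["patient_id"].isin(excl)))]

    base = mri[mri["mri_scan"] == "baseline"].rename(columns={"value": "baseline_value"})
    fu = mri[mri["mri_scan"] != "baseline"]
    merged = fu.merge(
        base[["patient_id", "parameter", "baseline_value"]],
        on=["patient_id", "parameter"],
        how="inner",
    )
    merged["change"] = merged["value"] - merged["baseline_value"]

    vol = volume_changes.copy()
    vol["patient_id"] = vol["patient_id"].astype(str)
    vol = vol[vol["timepoint"] != "baseline"]
    vol = vol.rename(columns={"timepoint": "ct_timepoint", "pct_change_vs_baseline": "ct_pct_change"})
    out = merged.merge(vol[["patient_id", "ct_timepoint", "ct_pct_change"]], on="patient_id")
    return out[
        ["patient_id", "mri_scan", "parameter", "modality", "change", "ct_timepoint", "ct_pct_change"]
    ]


def correlate_all(
    change_table: pd.DataFrame,
    min_n: int = 4,
    fdr: bool = False,
) -> pd.DataFrame:
    """One Spearman correlation per (parameter, MRI scan, CT time point) cell.

    Cells with fewer than ``min_n`` complete pairs are reported with NaN rho
    and a reason.  With ``fdr`` the p-values are Benjamini-Hochberg adjusted
    across all computed cells before flagging significance.
    """
    rows = []
    group_cols = ["parameter", "mri_scan", "ct_timepoint"]
    for (param, scan, ct_tp), grp in change_table.groupby(group_cols, sort=True):
        grp = grp.dropna(subset=["change", "ct_pct_change"])
        n = len(grp)
        if n < min_n:
            rows.append(
                dict(parameter=param, mri_scan=scan, ct_timepoint=ct_tp, rho=np.nan,
                     p_value=np.nan, n=n, significant=False, method=f"absent (n={n} < {min_n})")
            )
            continue
        try:
            res = spearman(grp["change"].to_numpy(), grp["ct_pct_change"].to_numpy())
        except ValueError as err:
            rows.append(
                dict(parameter=param, mri_scan=scan, ct_timepoint=ct_tp, rho=np.nan,
                     p_value=np.nan, n=n, significant=False, method=f"absent ({err})")
            )
            continue
        rows.append(
            dict(parameter=param, mri_scan=scan, ct_timepoint=ct_tp, rho=res.rho,
                 p_value=res.p_value, n=res.n, significant=res.significant, method=res.method)
        )
    out = pd.DataFrame(rows)
    if fdr and len(out):
        ok = out["p_value"].notna()
        p = out.loc[ok, "p_value"].to_numpy()
        order = np.argsort(p)
        m = len(p)
        adj = np.empty(m)
        running = 1.0
        for rank_idx in range(m - 1, -1, -1):
            i = order[rank_idx]
            running = min(running, p[i] * m / (rank_idx + 1))
            adj[i] = running
        out.loc[ok, "p_adjusted"] = adj
        out.loc[ok, "significant"] = adj <= SIGNIFICANCE_LEVEL
    return out


def format_correlation_table(corr: pd.DataFrame) -> str:
    """Markdown table of "rho (p)" cells, rows = parameters, columns =
    (MRI scan, CT time point); significant cells are bolded."""
    corr = corr.dropna(subset=["rho"])
    cols = sorted(
        {(s, c) for s, c in zip(corr["mri_scan"], corr["ct_timepoint"])}
    )
    header = "| parameter | " + " | ".join(f"{s}/{c}" for s, c in cols) + " |"
    sep = "|" + "---|" * (len(cols) + 1)
    lines = [header, sep]
    for param in sorted(corr["parameter"].unique()):
        cells = []
        sub = corr[corr["parameter"] == param]
        for s, c in cols:
            row = sub[(sub["mri_scan"] == s) & (sub["ct_timepoint"] == c)]
            if len(row) == 0:
                cells.append("-")
            else:
                r = row.iloc[0]
                cell = f"{r['rho']:.2f} ({r['p_value']:.2f})"
                cells.append(f"**{cell}**" if r["significant"] else cell)
        lines.append(f"| {param} | " + " | ".join(cells) + " |")
    return "\n".join(lines)
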