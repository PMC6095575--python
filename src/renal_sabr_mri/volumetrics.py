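"""CT tumour volumetry and RECIST 1.1 response categories.

Tumour volume is computed from tri-axial CT measurements under an ellipsoid
assumption, V = pi/6 * AP * TR * CC (all axes in mm), and the percentage
volume change of each follow-up scan is taken relative to the baseline CT.
RECIST 1.1 categories are assigned from the longest of the three reported
axes: partial response (PR) for a >= 30% decrease, progressive disease (PD)
for a >= 20% increase that is also >= 5 mm absolute, stable disease (SD)
otherwise.  Complete response is not modelled (no such case arises in the
cohort this package mirrors).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd

__all__ = [
    "TIMEPOINTS",
    "TriAxialMeasurement",
    "VolumeChangeRecord",
    "RecistCategory",
    "ellipsoid_volume",
    "pct_volume_change",
    "classify_recist",
    "load_ct_table",
    "packaged_table1",
    "analyse_ct_table",
]

TIMEPOINTS = ("baseline", "m6", "m12", "m24", "last")


@dataclass(frozen=True)
class TriAxialMeasurement:
    """One tumour's AP/TR/CC extents (mm) at one CT time point."""

    patient_id: str
    timepoint: str
    ap_mm: float
    tr_mm: float
    cc_mm: float

    def __post_init__(self) -> None:
        for axis in (self.ap_mm, self.tr_mm, self.cc_mm):
            if not axis > 0:
                raise ValueError(f"non-positive axis in {self}")

    @property
    def longest_diameter_mm(self) -> float:
        return max(self.ap_mm, self.tr_mm, self.cc_mm)


@dataclass
class VolumeChangeRecord:
    patient_id: str
    timepoint: str
    volume_mm3: float
    pct_change_vs_baseline: float


@dataclass
class RecistCategory:
    label: str  # PR | SD | PD
    longest_diameter_baseline_mm: float
    longest_diameter_followup_mm: float


def ellipsoid_volume(m: TriAxialMeasurement) -> float:
    """Ellipsoid volume in mm^3: pi/6 * AP * TR * CC."""
    return math.pi / 6.0 * m.ap_mm * m.tr_mm * m.cc_mm


def pct_volume_change(baseline: TriAxialMeasurement, followup: TriAxialMeasurement) -> float:
    """100 * (V_followup - V_baseline) / V_baseline (the pi/6 factor cancels)."""
    prod_b = baseline.ap_mm * baseline.tr_mm * baseline.cc_mm
    prod_f = followup.ap_mm * followup.tr_mm * followup.cc_mm
    return 100.0 * (prod_f / prod_b - 1.0)


def classify_recist(baseline: TriAxialMeasurement, followup: TriAxialMeasurement) -> RecistCategory:
    """RECIST 1.1 category from the longest of the three axes."""
    d0 = baseline.longest_diameter_mm
    d1 = followup.longest_diameter_mm
    change = (d1 - d0) / d0
    if change <= -0.30:
        label = "PR"
    elif change >= 0.20 and (d1 - d0) >= 5.0:
        label = "PD"
    else:
        label = "SD"
    return RecistCategory(label, d0, d1)


# ---------------------------------------------------------------------------
# Table IO and cohort-level analysis


def load_ct_table(path: str | Path | None = None) -> dict[str, dict[str, TriAxialMeasurement]]:
    """Read a tri-axial CT measurement CSV.

    Columns: patient_id, timepoint, AP_mm, TR_mm, CC_mm.  Cells with "-"
    denote a missing scan and yield no record (never a zero measurement).
    Returns ``{patient_id: {timepoint: TriAxialMeasurement}}``.
    """
    if path is None:
        df = packaged_table1()
    else:
        df = pd.read_csv(path, dtype=str)
    table: dict[str, dict[str, TriAxialMeasurement]] = {}
    for _, row in df.iterrows():
        pid = str(row["patient_id"])
        vals = [str(row[c]).strip() for c in ("AP_mm", "TR_mm", "CC_mm")]
        if any(v in {"-", "", "nan", "None"} for v in vals):
            table.setdefault(pid, {})
            continue
        m = TriAxialMeasurement(
            patient_id=pid,
            timepoint=str(row["timepoint"]),
            ap_mm=float(vals[0]),
            tr_mm=float(vals[1]),
            cc_mm=float(vals[2]),
        )
        table.setdefault(pid, {})[m.timepoint] = m
    return table


def packaged_table1() -> pd.DataFrame:
    """The packaged transcription of the cohort's tri-axial CT measurements."""
    with resources.files("renal_sabr_mri.data").joinpath("table1.csv").open() as fh:
        return pd.read_csv(fh, dtype=str)


def analyse_ct_table(
    table: dict[str, dict[str, TriAxialMeasurement]],
) -> pd.DataFrame:
    """Long-format volume/percentage-change/RECIST table for a cohort.

    One row per (patient, available timepoint) with the ellipsoid volume and
    percentage change versus baseline; the RECIST label (computed baseline vs
    last follow-up) is repeated on each of the patient's rows.  Missing
    timepoints are simply absent.
    """
    rows = []
    for pid, tps in table.items():
        base = tps.get("baseline")
        if base is None:
            continue
        recist: Optional[str] = None
        if "last" in tps:
            recist = classify_recist(base, tps["last"]).label
        for tp in TIMEPOINTS:
            m = tps.get(tp)
            if m is None:
                continue
            rows.append(
                {
                    "patient_id": pid,
                    "timepoint": tp,
                    "volume_mm3": ellipsoid_volume(m),
                    "pct_change_vs_baseline": 0.0 if tp == "baseline" else pct_volume_change(base, m),
                    "recist_last": recist,
                }
            )
    return pd.DataFrame(rows)
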