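#!/usr/bin/env python
"""ADC mapping validation on DWI phantoms.

Fits the mono-exponential model to (a) noiseless signals, confirming exact
recovery, and (b) a noisy phantom (sd 5 on S0 = 1000), measuring the
ROI-mean error and the histogram statistics the response analysis uses.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from renal_sabr_mri.adc import DwiStack, fit_adc, roi_histogram_stats
from renal_sabr_mri.io import write_csv
from renal_sabr_mri.synthetic import PhantomConfig, simulate_dwi_phantom

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 4


def main() -> None:
    rows = []
    b = np.array([50.0, 400.0, 800.0])
    for adc_true in (0.8e-3, 1.5e-3, 2.4e-3):
        s = 1000.0 * np.exp(-b * adc_true)
        amap = fit_adc(DwiStack(signal=s[None, None, None, :], b_values=b))
        rows.append(dict(case=f"noiseless_{adc_true:.1e}", true_mean=adc_true,
                         est_mean=float(amap.adc[0, 0, 0]),
                         rel_err=float(abs(amap.adc[0, 0, 0] - adc_true) / adc_true)))

    cfg = PhantomConfig(grid_shape=(22, 22, 8), noise_sd=5.0, s0_dwi=1000.0, seed=SEED)
    signal, roi, truth = simulate_dwi_phantom(cfg)
    stats = roi_histogram_stats(fit_adc(DwiStack(signal=signal, b_values=cfg.b_values)), roi)
    true_mean = float(truth.adc[roi].mean())
    rows.append(dict(case="noisy_sd5", true_mean=true_mean, est_mean=stats.mean,
                     rel_err=abs(stats.mean - true_mean) / true_mean))
    df = pd.DataFrame(rows)
    write_csv(RESULTS / "adc_validation.csv", df)
    print(df.to_string(index=False))
    print(f"\nNoisy ROI (n={stats.n_voxels}): median {stats.median:.2e} mm^2/s, "
          f"skewness {stats.skewness:.3f}, kurtosis {stats.kurtosis:.3f}")
    print(f"Wrote {RESULTS / 'adc_validation.csv'}")


if __name__ == "__main__":
    main()
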