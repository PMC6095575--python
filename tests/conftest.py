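"""Shared phantom fixtures.

Heavy phantoms are session-scoped so the classification, recovery and
pipeline tests reuse one generation pass each.
"""

from __future__ import annotations

import numpy as np
import pytest

from renal_sabr_mri.cohort import CohortSpec, simulate_cohort_workspace
from renal_sabr_mri.config import RunConfig
from renal_sabr_mri.pipeline import run_pipeline
from renal_sabr_mri.synthetic import PhantomConfig, simulate_dce_phantom, simulate_dwi_phantom


@pytest.fixture(scope="session")
def noiseless_mix_phantom():
    """Noiseless DCE phantom with an equal four-class mix (~700 ROI voxels)."""
    cfg = PhantomConfig(
        grid_shape=(16, 16, 8),
        noise_sd=0.0,
        seed=1,
        class_fractions=(0.25, 0.25, 0.25, 0.25),
    )
    signal, roi, aorta, truth = simulate_dce_phantom(cfg)
    return cfg, signal, roi, aorta, truth


@pytest.fixture(scope="session")
def noisy_dwi_phantom():
    """DWI phantom at the reference noise level (sd 5 on S0 = 1000)."""
    cfg = PhantomConfig(grid_shape=(16, 16, 8), noise_sd=5.0, seed=4)
    signal, roi, truth = simulate_dwi_phantom(cfg)
    return cfg, signal, roi, truth


@pytest.fixture(scope="session")
def cohort_run(tmp_path_factory):
    """A 12-patient phantom cohort with injected monotone response trends,
    processed end-to-end; returns (workspace, derived_dir)."""
    ws = tmp_path_factory.mktemp("cohort")
    spec = CohortSpec(n_patients=12, grid_shape=(10, 10, 5), noise_sd=2.0, seed=1)
    simulate_cohort_workspace(ws, spec)
    run_pipeline(RunConfig(workspace=ws, seed=1))
    return ws, ws / "derived"


@pytest.fixture
def rng():
    return np.random.default_rng(123)
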