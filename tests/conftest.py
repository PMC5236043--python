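"""Shared fixtures.

The heavy session fixtures run the full simulate→reconstruct→measure chain
once on the reduced study phantom (one sphere per diameter) and are shared
by the acceptance-level tests; unit tests use tiny ad-hoc grids instead.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from psfrc import (
    AcquisitionConfig,
    ExperimentConfig,
    ReconParams,
    study_phantom,
    with_unit_frame_contrast,
)
from psfrc.pipeline import run_contrast_sweep, run_iteration_sweep, run_reproducibility

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")

#: Seed for every stochastic suite fixture.
SUITE_SEED = 7


@pytest.fixture(scope="session")
def study():
    phantom, grid = study_phantom()
    return phantom, grid


@pytest.fixture(scope="session")
def study_cfg(study):
    phantom, grid = study
    return ExperimentConfig(phantom=phantom, grid=grid, seed=SUITE_SEED)


@pytest.fixture(scope="session")
def unit_contrast_table(study):
    """Frame-1 RCs at exactly unit frame-mean contrast, both recon modes."""
    phantom, grid = study
    cfg = ExperimentConfig(
        phantom=with_unit_frame_contrast(phantom),
        grid=grid,
        seed=SUITE_SEED,
    )
    return run_contrast_sweep(cfg, frame_indices=[0])


@pytest.fixture(scope="session")
def unit_contrast_table_noiseless(study):
    phantom, grid = study
    cfg = ExperimentConfig(
        phantom=with_unit_frame_contrast(phantom),
        grid=grid,
        acquisition=AcquisitionConfig(noiseless=True),
        seed=SUITE_SEED,
    )
    return run_contrast_sweep(cfg, frame_indices=[0])


@pytest.fixture(scope="session")
def iteration_sweep(study_cfg):
    """Iterations 1–12 × post-filters {2,3,4,6} mm × both PSF modes at the
    frame nearest true ratio 8:1 — shared by the convergence, boundedness
    and filter-restoration checks."""
    return run_iteration_sweep(
        study_cfg, iterations=12, postfilters=(2.0, 3.0, 4.0, 6.0)
    )


@pytest.fixture(scope="session")
def reproducibility_25(study_cfg):
    """N=25 noise replicates at high contrast, both recon modes."""
    table, summary = run_reproducibility(study_cfg, n_replicates=25, target_ratio=13.0)
    return table, summary


def per_diameter(table, value="rc_50bg", **filters):
    """Mean RC per diameter after row filtering — curve helper for tests."""
    sel = table
    for col, val in filters.items():
        sel = sel[sel[col] == val]
    assert len(sel), f"no rows match {filters}"
    return sel.groupby("diameter")[value].mean()
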