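"""Shared fixtures: small synthetic scenes and the full-scale recovery runs."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from tensiledic import RunConfig, dic, studies
from tensiledic import synthetic as syn

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def pattern() -> syn.SpecklePattern:
    """Reference speckle raster: 256 px wide, 512 px tall, 0.05 mm/px."""
    return syn.gen_speckle(256, 512, dot_density=0.02, dot_radius_range=(2, 4), seed=7)


@pytest.fixture(scope="session")
def small_pattern() -> syn.SpecklePattern:
    return syn.gen_speckle(192, 256, dot_density=0.02, dot_radius_range=(2, 4), seed=3)


def make_fields(
    grid: dic.SubsetGrid,
    pattern: syn.SpecklePattern,
    schedule: syn.DeformationSchedule,
    times: np.ndarray,
) -> dic.DisplacementFieldSeries:
    """Analytic displacement-field series from the generator's closed form.

    Lets extensometry be tested in isolation from the correlation engine.
    """
    n = len(times)
    cy = grid.centers[:, 0]
    cx = grid.centers[:, 1]
    u = np.zeros((n, len(cy)))
    v = np.zeros((n, len(cy)))
    for i, t in enumerate(times):
        gt = syn.displacement_field(pattern, schedule, float(t))
        u[i] = gt[cy, cx, 0]
        v[i] = gt[cy, cx, 1]
    return dic.DisplacementFieldSeries(
        grid=grid,
        frame_times=np.asarray(times, dtype=float),
        u=u,
        v=v,
        correlation=np.ones((n, len(cy))),
        valid=np.ones((n, len(cy)), dtype=bool),
        config=dic.DicConfig(),
    )


@pytest.fixture(scope="session")
def aniso_study() -> studies.PoissonStudyResult:
    """Full DIC pipeline on the anisotropic Poisson-endpoint specimen."""
    return studies.run_poisson_study("anisotropic", seed=1)


@pytest.fixture(scope="session")
def iso_study() -> studies.PoissonStudyResult:
    """Full DIC pipeline on the isotropic Poisson-endpoint specimen."""
    return studies.run_poisson_study("isotropic", seed=1)


@pytest.fixture()
def default_config() -> RunConfig:
    return RunConfig()
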