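"""Shared fixtures: the default synthetic phantom and a completed design.

Session scope keeps the expensive artefacts (STA matrix, MLS design) shared
across test modules; everything is generated from fixed seeds.
"""

import numpy as np
import pytest

from ptxh import ktpulse, phantom


@pytest.fixture(scope="session")
def spec():
    return phantom.PhantomSpec(seed=0)


@pytest.fixture(scope="session")
def head_mask(spec):
    return phantom.make_head_mask(spec)


@pytest.fixture(scope="session")
def b0_true(spec, head_mask):
    return phantom.make_b0_map(spec, head_mask)


@pytest.fixture(scope="session")
def b1_true(spec, head_mask):
    return phantom.make_b1_maps(spec, head_mask)


@pytest.fixture(scope="session")
def trajectory():
    return ktpulse.make_ktpoints_trajectory()


@pytest.fixture(scope="session")
def sta_system(b1_true, b0_true, trajectory, head_mask):
    return ktpulse.build_sta_system(b1_true, b0_true, trajectory, head_mask)


@pytest.fixture(scope="session")
def design_weights(sta_system):
    """Region-growing MLS design at the 15-degree workflow target."""
    return ktpulse.region_growing_solve(sta_system, 15.0, seed=0)


@pytest.fixture(scope="session")
def small_spec():
    """A coarse phantom for tests that only need plumbing, not resolution."""
    return phantom.PhantomSpec(
        grid_shape=(22, 22, 18),
        voxel_size_mm=(9.0, 9.0, 9.0),
        ellipsoid_semi_axes_mm=(70.0, 85.0, 62.0),
        n_channels=8,
        seed=3,
    )


@pytest.fixture(scope="session")
def small_mask(small_spec):
    return phantom.make_head_mask(small_spec)
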