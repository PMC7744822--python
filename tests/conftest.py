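"""Shared fixtures: small phantoms are generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

import muskstrain3d as m


@pytest.fixture(scope="session")
def grid():
    return m.VoxelGrid(shape=(64, 48, 3), spacing=(2.0, 2.0, 5.0))


@pytest.fixture(scope="session")
def model():
    return m.DeformationModel()


@pytest.fixture(scope="session")
def truth(grid, model):
    return m.make_deformation(model, grid)


@pytest.fixture(scope="session")
def small_grid():
    return m.VoxelGrid(shape=(32, 24, 3), spacing=(4.0, 4.0, 5.0))


@pytest.fixture(scope="session")
def small_truth(small_grid):
    model = m.DeformationModel(
        n_frames=9,
        regions=(
            m.MuscleRegion("MG", center_mm=(15.0, 2.0), semi_axes_mm=(14.0, 11.0)),
            m.MuscleRegion("Sol", center_mm=(-15.0, -2.0), semi_axes_mm=(14.0, 11.0)),
        ),
    )
    return m.make_deformation(model, m.VoxelGrid(shape=(32, 24, 3), spacing=(4.0, 4.0, 5.0)))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def uniform_model(amplitude=-0.1, ratio=0.95, angle=0.0, n_frames=9):
    """Model whose envelope plateau covers the whole FOV, so the deformation
    is the spatially uniform linear field u = A (X - c) everywhere."""
    return m.DeformationModel(
        amplitude_fiber=amplitude,
        anisotropy_ratio=ratio,
        fiber_angle_deg=angle,
        n_frames=n_frames,
        regions=(
            m.MuscleRegion("MG", center_mm=(0.0, 0.0),
                           semi_axes_mm=(1000.0, 1000.0)),
        ),
    )
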