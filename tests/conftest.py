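"""Shared fixtures: small grids, sources and synthetic stacks."""

import numpy as np
import pytest

from fiberlight.fiber_geometry import FiberConfig, make_source
from fiberlight.ioi_synth import AcquisitionProtocol, GroundTruthActivation
from fiberlight.optics import OpticalProperties, SourceSpec, VoxelGrid


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def brain_optics():
    """Brain-tissue optics at 473 nm (reduced μs′ = 4.37 mm⁻¹, g = 0.9)."""
    return OpticalProperties.from_reduced(mu_a=0.48, mu_s_reduced=4.37, g=0.9, n=1.37)


@pytest.fixture
def small_grid():
    """Coarse 1 mm cube for fast transport tests."""
    return VoxelGrid.centered((0.0, 0.0, 0.0), 1.0, 0.025)


@pytest.fixture
def fiber_source():
    """Default 200 µm NA 0.37 side-firing source at the origin."""
    return make_source(FiberConfig(tip=(0.0, 0.0, 0.0)))


@pytest.fixture
def axial_source():
    return SourceSpec(center=(0.0, 0.0, 0.4), normal=(0.0, 0.0, -1.0),
                      radius=0.1, half_angle=0.2737)


@pytest.fixture
def small_protocol():
    """64×64 field with the standard trial structure."""
    return AcquisitionProtocol(image_shape=(64, 64))


@pytest.fixture
def centered_truth():
    return GroundTruthActivation(center=(32.0, 32.0), spatial_sigma=8.0)
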