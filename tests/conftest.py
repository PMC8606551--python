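import numpy as np
import pytest

from reentryforge import (IschemiaSpec, assign_aha_segments, assign_fibers,
                          generate_slab)
from reentryforge.ischemia import GradingConfig, assign_layers, grade_layers


@pytest.fixture(scope="session")
def disc_slab():
    """100x100 sheet (0.25 mm) with a centred 5 mm ischemic disc."""
    spec = IschemiaSpec(center=(12.5, 12.5), radius=5.0, n_layers=5)
    return generate_slab(100, 100, 0.25, spec, seed=0)


@pytest.fixture(scope="session")
def layered_slab(disc_slab):
    geom, layers = assign_layers(disc_slab, 5)
    return geom, layers


@pytest.fixture(scope="session")
def full_slab(layered_slab):
    """Layered disc slab with AHA tiling and fibers assigned."""
    geom, layers = layered_slab
    geom = assign_aha_segments(geom)
    geom = assign_fibers(geom, 60.0, -60.0)
    return geom, layers


@pytest.fixture(scope="session")
def grading_table(layered_slab):
    _, layers = layered_slab
    return grade_layers(layers, GradingConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
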