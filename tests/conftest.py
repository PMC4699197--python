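"""Shared fixtures: reduced phantom profiles for fast tests.

The small profiles keep the default geometry's proportions (the surface
fractions scale with depth) so the protocol behaves the same; tests that
need tight sub-pixel recovery on a reduced profile use a flat (pit-free)
spec, because at a sixth of the native depth the foveal inner retina pinches
to under 3 px and the INL/OPL transition is no longer resolvable.
"""

import numpy as np
import pytest

from octenface import PhantomSpec, ScanMetadata, generate_phantom


@pytest.fixture(scope="session")
def small_meta() -> ScanMetadata:
    return ScanMetadata(n_bscans=12, n_depth=300, n_ascans=120)


@pytest.fixture(scope="session")
def small_spec(small_meta) -> PhantomSpec:
    return PhantomSpec(meta=small_meta, seed=7, speckle_sigma=0.0)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    """Noiseless small phantom: (volume, ground-truth boundaries)."""
    return generate_phantom(small_spec)


@pytest.fixture(scope="session")
def flat_spec(small_meta) -> PhantomSpec:
    """Small phantom with flat layers (no foveal pit)."""
    return PhantomSpec(meta=small_meta, seed=7, speckle_sigma=0.0,
                       pit_amp_px=(0.0, 0.0, 0.0), ise_thicken_px=0.0)


@pytest.fixture(scope="session")
def flat_phantom(flat_spec):
    return generate_phantom(flat_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
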