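"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

import airwayaf as af
from airwayaf.synthgen import SceneGeometry

#: a small mixed population covering all seven types
SMALL_COUNTS = {
    "basal": 3,
    "ciliated": 3,
    "secretory": 3,
    "hillock": 2,
    "ionocyte": 2,
    "tuft": 2,
    "neuroendocrine": 2,
}


@pytest.fixture(scope="session")
def small_scene():
    """A 17-cell scene with the default (noisy, curved) geometry."""
    return af.render_scene(n_per_type=SMALL_COUNTS, seed=7)


@pytest.fixture(scope="session")
def clean_flat_scene():
    """Noise-free scene on a flat membrane: feature-extraction oracle."""
    geom = SceneGeometry(curvature_amplitude=0.0, poisson_noise=False, read_noise_sd=0.0)
    return af.render_scene(n_per_type=SMALL_COUNTS, geometry=geom, seed=2)


@pytest.fixture(scope="session")
def table206():
    """Sampled feature table at the reference per-type counts (206 cells)."""
    return af.sample_feature_table(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
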