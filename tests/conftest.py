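"""Shared fixtures: small phantoms with known ground truth.

Everything is generated programmatically at test time; session scope keeps
the more expensive phantom builds to one per run.
"""

import numpy as np
import pytest

from dceradiomics import phantom as ph


@pytest.fixture(scope="session")
def sphere_spec_05mm():
    """Ideal digital sphere, radius 10 mm at 0.5 mm isotropic."""
    return ph.PhantomSpec(
        grid_shape=(48, 48, 48),
        spacing_mm=(0.5, 0.5, 0.5),
        radius_mm=10.0,
        irregularity_amp=0.0,
        texture_amp=0.0,
        noise_sigma=0.0,
        rng_seed=0,
    )


@pytest.fixture(scope="session")
def sphere_truth_05mm(sphere_spec_05mm):
    return ph.make_tumor_mask(sphere_spec_05mm)


@pytest.fixture(scope="session")
def default_phantom():
    """Noiseless default-geometry phantom: (spec, truth, series)."""
    spec = ph.PhantomSpec(rng_seed=11, noise_sigma=0.0)
    truth = ph.make_tumor_mask(spec)
    series = ph.make_dce_series(truth, spec)
    return spec, truth, series


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
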