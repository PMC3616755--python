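"""Shared fixtures: phantoms at several scales, generated once per session."""

import numpy as np
import pytest

from longbrain.phantom import PhantomSpec, generate_phantom


def small_spec(**overrides) -> PhantomSpec:
    """64-cube static-friendly profile used by most unit tests."""
    kwargs = dict(
        shape=(64, 64, 64),
        radius_scalp=29.0, radius_skull=26.0, radius_csf=23.0,
        radius_gm=21.0, radius_wm=18.0,
        cerebellum_center=(0.0, -8.0, -11.0), cerebellum_radius=6.0,
        jitter_translation=0.0, jitter_rotation=0.0,
        gm_thinning_rate=0.0, seed=0,
    )
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


@pytest.fixture(scope="session")
def small_phantom():
    """Static 2-timepoint 64-cube phantom with ground truth and atlas."""
    return generate_phantom(small_spec(timepoints=(0.0, 6.0)))


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, bias-free single-timepoint phantom (separable classes)."""
    return generate_phantom(small_spec(
        timepoints=(0.0,), noise_sigma=0.0, bias_amplitude=0.0,
        texture_amplitude=0.0, pv_smoothing_mm=0.0))


@pytest.fixture(scope="session")
def default_phantom():
    """The default 96-cube 4-timepoint study profile."""
    return generate_phantom(PhantomSpec())


@pytest.fixture
def rng():
    return np.random.default_rng(42)
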