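"""Shared fixtures: small synthetic recordings sized for fast tests."""

import numpy as np
import pytest

from sparkline import DetectionParams, SynthParams, generate_image


@pytest.fixture(scope="session")
def small_synth_params() -> SynthParams:
    """Generator settings on a reduced canvas (512 x 256 px) keeping the
    full structural repertoire (bands, couplets, repetitive bands)."""
    return SynthParams(
        image_shape=(512, 256),
        n_sparks_range=(8, 15),
        n_couplets_range=(1, 2),
        n_repetitive_bands_range=(0, 1),
        seed=0,
    )


@pytest.fixture(scope="session")
def synth_image(small_synth_params):
    """One generated image + mask + placement list (seed 0)."""
    return generate_image(small_synth_params, seed=0)


@pytest.fixture()
def default_params() -> DetectionParams:
    return DetectionParams()


@pytest.fixture()
def flat_image_factory():
    """Factory for constant-background images with optional inserted
    ΔF/F0 structures (multiplicative, like real fluorescence)."""
    from sparkline import LineScanImage

    def make(dff=None, level=500.0, shape=(256, 128), noise_sd=0.0, seed=0,
             time_step=1.92, pixel_size=0.1):
        rng = np.random.default_rng(seed)
        img = np.full(shape, level, dtype=np.float64)
        if dff is not None:
            img = level * (1.0 + dff)
        if noise_sd > 0:
            img = img + rng.normal(0, noise_sd, size=shape)
        img = np.clip(img, 0, 4095)
        return LineScanImage(pixels=img, time_step=time_step,
                             pixel_size=pixel_size, bit_depth=12)

    return make
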