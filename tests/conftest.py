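import numpy as np
import pytest

import plimap as pl


@pytest.fixture
def rng():
    return np.random.default_rng(20240521)


@pytest.fixture
def single_fiber_scene():
    """Noise-free horizontal negative-birefringence fiber at one wavelength."""
    scene = pl.preset_phantom(
        "crossing", overlap_mode="top", wavelengths=(532,), size=(64, 64)
    )
    # keep only the bottom fiber to get a single straight fiber
    scene.fibers = [scene.fibers[0]]
    scene.overlap_mode = None
    return scene


def random_triple(rng, n):
    """Random (depolarizer, retarder, diattenuator) factor batches."""
    a, b, c = rng.uniform(0.05, 1.0, (3, n))
    delta = rng.uniform(0.05, np.pi - 0.05, n)
    theta = rng.uniform(0.0, 180.0, n)
    d = rng.uniform(0.0, 0.9, n)
    phi = rng.uniform(0.0, 180.0, n)
    Md = np.stack([pl.make_depolarizer(ai, bi, ci) for ai, bi, ci in zip(a, b, c)])
    MR = pl.make_linear_retarder(delta, theta)
    MD = pl.make_linear_diattenuator(d, phi)
    return Md, MR, MD
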