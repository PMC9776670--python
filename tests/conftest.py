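import numpy as np
import pytest

from glomopipe import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def phantom_noise0():
    """Desk-scale zero-noise phantom: every stage is analytically exact on it."""
    spec = PhantomSpec(
        wsi_extent_um=(4000.0, 3000.0),
        microns_per_pixel=2.0,
        n_glomeruli=6,
        noise_sd=0.0,
        seed=11,
    )
    return generate_phantom(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
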