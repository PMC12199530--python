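"""Shared fixtures: small, fast phantoms reused across test modules."""

import numpy as np
import pytest

from podoquant import synthdata


@pytest.fixture(scope="session")
def small_section():
    """A compact noiseless section phantom (5 glomeruli)."""
    spec = synthdata.SectionPhantomSpec(
        image_size_px=(600, 600),
        n_glomeruli=5,
        glomerulus_radius_um=(20.0, 25.0),
        noise_cv=0.0,
        seed=11,
    )
    return synthdata.gen_section_phantom(spec)


@pytest.fixture(scope="session")
def slit_phantom():
    """A noiseless slit phantom at moderate effacement."""
    spec = synthdata.SlitPhantomSpec(effacement=0.4, seed=7)
    return synthdata.gen_slit_phantom(spec)


@pytest.fixture(scope="session")
def vessel_movie():
    """A default vessel movie phantom."""
    spec = synthdata.MoviePhantomSpec(seed=5)
    return synthdata.gen_vessel_movie(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
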