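import numpy as np
import pytest

from chromacomm.spectra import SpectrumSet, leaf_background
from chromacomm.synthetic import gen_leaf_spectrum
from chromacomm.vision import bee_receptors, bird_receptors, d65_illuminant

GRID = np.arange(300.0, 701.0, 1.0)


@pytest.fixture(scope="session")
def grid():
    return GRID


@pytest.fixture(scope="session")
def background(grid):
    rng = np.random.default_rng(0)
    ss = SpectrumSet()
    for i in range(20):
        ss.add("leafsp", "leaf", str(i), gen_leaf_spectrum(rng, noise_sd=0.0))
    return leaf_background(ss)


@pytest.fixture(scope="session")
def illuminant(grid):
    return d65_illuminant(grid)


@pytest.fixture(scope="session")
def bee_rec(grid):
    return bee_receptors(grid)


@pytest.fixture(scope="session")
def bird_rec(grid):
    return bird_receptors(grid)


@pytest.fixture(scope="session")
def locus_table(background, bee_rec, illuminant):
    from chromacomm.bee import spectrum_locus_table
    return spectrum_locus_table(background, bee_rec, illuminant)
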