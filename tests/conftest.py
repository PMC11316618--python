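import numpy as np
import pytest

import archdiag as ad
from archdiag.config import log


@pytest.fixture(autouse=True, scope="session")
def _quiet_logging():
    import logging
    log.setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def band_a():
    """Binary ordered band table at package defaults (100 x 120, w=20)."""
    return ad.generate_band_a(ad.BandSpec())


@pytest.fixture(scope="session")
def band_b():
    """Count band with tapered Poisson means and 2% off-band noise."""
    return ad.generate_band_b(ad.BandSpec(
        value_model=ad.ValueModel.COUNTS, noise_rate=0.02, seed=0))


@pytest.fixture(scope="session")
def blocks():
    """Three disjoint cell types, 30 cells x 30 marker genes each."""
    return ad.generate_block_diagonal(3, 30, 30, seed=0)


@pytest.fixture(scope="session")
def nosat10():
    return ad.generate_no_saturation(10)


@pytest.fixture(scope="session")
def nosat20():
    return ad.generate_no_saturation(20)


@pytest.fixture(scope="session")
def band_a_embedding(band_a):
    return ad.pca_embed(band_a, k=2)


@pytest.fixture(scope="session")
def identity_order():
    return lambda ds: np.arange(ds.n_cells)
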