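import numpy as np
import pytest

from discradiomics import make_geometry, render_disc, sample_phenotype


@pytest.fixture(scope="session")
def geometry():
    # compact crop geometry with the clinical in-plane spacing (70 mm / 128)
    return make_geometry(70.0, 128)


@pytest.fixture(scope="session")
def disc_g2(geometry):
    rng = np.random.default_rng(11)
    return render_disc(sample_phenotype(2, rng), geometry, rng)


@pytest.fixture(scope="session")
def disc_g5(geometry):
    rng = np.random.default_rng(12)
    return render_disc(sample_phenotype(5, rng), geometry, rng)
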