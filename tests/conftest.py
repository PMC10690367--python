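import numpy as np
import pytest

from dscradiomics import kinetics, synth

DT = 1.87  # s, default temporal resolution
TE = 0.040  # s


@pytest.fixture(scope="session")
def time_grid():
    return np.arange(60) * DT


@pytest.fixture(scope="session")
def aif(time_grid):
    return synth.make_aif(synth.GammaBolusParams(), time_grid)


@pytest.fixture(scope="session")
def reference_curve(aif, time_grid):
    """Clean normal-tissue concentration curve (the leakage reference)."""
    return kinetics.simulate_tissue_curve(aif, time_grid, 0.05, 2.0, 1.5, 3.0)


@pytest.fixture(scope="session")
def small_phantom():
    spec = synth.PhantomSpec(
        tissue_classes=synth.default_tissue_classes(0.1, 0.02, 0.08, 0.05),
        seed=7,
    )
    return synth.build_phantom(spec, label=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
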