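import numpy as np
import pytest

import phytoplex as px


@pytest.fixture
def trolox_curve() -> px.CalibrationCurve:
    """Exact linear Trolox curve: A = 0.05 + 0.5 c (mM)."""
    levels = [(c, 0.05 + 0.5 * c) for c in (0.0, 0.0625, 0.125, 0.25, 0.5, 1.0)]
    return px.fit_standard_curve(levels, analyte="trolox", wavelength=593.0)


@pytest.fixture
def protocol() -> px.ExtractionProtocol:
    return px.ExtractionProtocol()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def small_table():
    cfg = px.SimulationConfig(n_cultivars=4, seed=3)
    return px.generate_metabolite_table(cfg)
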