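import numpy as np
import pytest

import frostspec as fs
from frostspec.design import records_to_frame


@pytest.fixture(scope="session")
def default_records():
    """Full 2 x 6 x 16 design with simulated biochemistry (study conditions)."""
    gen = fs.GeneratorConfig(seed=11)
    return fs.simulate_biochemistry(fs.generate_design(16), gen), gen


@pytest.fixture(scope="session")
def default_spectra(default_records):
    records, gen = default_records
    return fs.simulate_spectra(records, gen)


@pytest.fixture(scope="session")
def default_panel(default_records):
    records, _ = default_records
    return records_to_frame(records)


@pytest.fixture(scope="session")
def small_dataset():
    """Reduced design (60 samples x 40 bands) for expensive model fits."""
    gen = fs.GeneratorConfig(seed=7, n_bands=40)
    records = fs.simulate_biochemistry(fs.generate_design(5), gen)
    spectra = fs.simulate_spectra(records, gen)
    panel = records_to_frame(records)
    panel["LTRI"] = fs.LTRIModel(panel).fit().scores
    return spectra, panel


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
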