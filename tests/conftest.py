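import numpy as np
import pytest

from bowcoord.synthetic_data import GeneratorConfig, generate_pattern
from bowcoord.transition_features import extract_features


@pytest.fixture(scope="session")
def cw_config():
    """Headline recovery configuration: CW, 92 bpm, 24 cycles, noise-free."""
    return GeneratorConfig(
        pattern="CW", tempo_bpm=92.0, sample_rate_hz=240.0, n_bars=4,
        delta_phi_deg=15.0, r_norm=0.32, seed=1,
    )


@pytest.fixture(scope="session")
def cw_series(cw_config):
    return generate_pattern(cw_config)


@pytest.fixture(scope="session")
def cw_features(cw_series):
    return extract_features(cw_series)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
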