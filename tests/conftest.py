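import numpy as np
import pytest

from seasonfuse import synthetic


@pytest.fixture(scope="session")
def design():
    """3 replicates per season over 2 years: 24 samples, 6 per season."""
    return synthetic.generate_design(3, 2, seed=42)


@pytest.fixture(scope="session")
def ms_study(design):
    """Feature matrix with planted seasonal effects and blank features."""
    return synthetic.generate_ms_features(design, n_features=200, n_planted=10,
                                          n_blank=10, effect_size=3.0, seed=44)


@pytest.fixture(scope="session")
def nmr_study(design):
    """Synthetic spectra with planted seasonal peaks."""
    return synthetic.generate_nmr_spectra(design, n_peaks=30, n_planted=5,
                                          effect_size=3.0, seed=45)


@pytest.fixture(scope="session")
def library():
    return synthetic.generate_reference_library(0)
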