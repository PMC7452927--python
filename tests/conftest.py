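import warnings

import numpy as np
import pandas as pd
import pytest

import ipssirt as ip
from ipssirt import reference as ref

warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def uni_bank():
    return ref.unidimensional_bank()


@pytest.fixture(scope="session")
def bi_bank():
    return ref.bidimensional_bank()


@pytest.fixture(scope="session")
def uni_shift():
    return ref.unidimensional_shift()


@pytest.fixture(scope="session")
def bi_shift():
    return ref.bidimensional_shift()


@pytest.fixture(scope="session")
def idvis_small(uni_bank, uni_shift):
    """Small IDVIS simulation: 60 patients x 4 visits = 240 pseudo-individuals."""
    return ip.simulate_idvis_dataset(
        uni_bank, uni_shift, n_patients=60,
        visit_times=(0.0, 1.0, 3.0, 6.0), seed=101,
    )


@pytest.fixture(scope="session")
def idvis_full(uni_bank, uni_shift):
    """Full-design IDVIS simulation: 403 patients x 8 visits, with true psi."""
    return ip.simulate_idvis_dataset(
        uni_bank, uni_shift, n_patients=403, seed=7, return_psi=True
    )


@pytest.fixture(scope="session")
def idvis_full_ebe(uni_bank, uni_shift, idvis_full):
    pseudo = ip.reshape_idvis(idvis_full)
    return pseudo, ip.estimate_disability(uni_bank, uni_shift, pseudo)
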