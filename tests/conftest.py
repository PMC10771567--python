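import numpy as np
import pytest

import ramanpe as rp


@pytest.fixture(scope="session")
def peak_table():
    return rp.load_peak_table()


@pytest.fixture(scope="session")
def small_cohort():
    """One small rendered cohort shared across tests (6 patients/cell, 5 scans)."""
    cfg = rp.SyntheticConfig(seed=11, n_patients_per_cell=6, n_replicates=5)
    return cfg, rp.generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def flat_spectrum():
    wn = np.arange(600.0, 1801.0)
    return rp.Spectrum(wavenumbers=wn, intensities=np.zeros_like(wn), scan_id="flat")
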