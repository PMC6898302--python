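import numpy as np
import pytest

import nflmd


@pytest.fixture(scope="session")
def model():
    return nflmd.load_default_model()


@pytest.fixture(scope="session")
def weights():
    return nflmd.load_default_weights()


@pytest.fixture(scope="session")
def small_cohort():
    """Deterministic 60-eye cohort shared by tests that only read it."""
    cfg = nflmd.CohortConfig(n_normal=20, n_ppg=20, n_pg=20, seed=424242)
    return nflmd.simulate_cohort(cfg)


@pytest.fixture()
def reference_profile(model):
    """An eye sitting exactly on its normative reference in every sector."""
    age, axlen = 57.0, 24.2
    thickness = {s: nflmd.reference_thickness(s, age, axlen, model)
                 for s in nflmd.SECTOR_ORDER}
    return nflmd.SectorProfile("ref-eye", thickness, age=age, axial_length=axlen)


def rng(seed=0):
    return np.random.default_rng(seed)
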