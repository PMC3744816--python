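import numpy as np
import pytest

from ensemblefit import fixtures as fx


@pytest.fixture(scope="session")
def strepto_template():
    return fx.streptomycin_template()


@pytest.fixture(scope="session")
def truth_model():
    return fx.ground_truth_model()


@pytest.fixture(scope="session")
def table_mean_torsions():
    """Primary-mode mean torsions of the final fitted model."""
    return {
        "phi12": -75.0, "psi12": -134.0, "phi23": -103.0, "psi23": -81.0,
        "chi1_S1": 78.0, "chi3_S1": 128.0, "chi3_R2": 180.0,
        "chi2_G3": -103.0, "chi5_G3": -45.0,
    }


@pytest.fixture(scope="session")
def strepto_synthetic():
    """Small synthetic restraint set shared across fitting tests."""
    return fx.streptomycin_restraints(seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
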