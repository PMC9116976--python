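import numpy as np
import pytest

from esm_abeta import (
    EpicentreSet,
    ParameterGrid,
    make_synthetic_connectome,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def dkt_connectome():
    """Default 78-region bilateral synthetic connectome."""
    return make_synthetic_connectome(seed=0)


@pytest.fixture(scope="session")
def small_connectome():
    """10-region bilateral connectome with generic labels."""
    return make_synthetic_connectome(n_regions=10, seed=1)


@pytest.fixture(scope="session")
def reduced_grid():
    return ParameterGrid.reduced()


@pytest.fixture(scope="session")
def cac_pc_epicentre(dkt_connectome):
    return EpicentreSet(
        [
            "L_caudal_anterior_cingulate",
            "R_caudal_anterior_cingulate",
            "L_posterior_cingulate",
            "R_posterior_cingulate",
        ]
    )


@pytest.fixture(scope="session")
def noiseless_cohort(dkt_connectome):
    """12 DMN/striatal subjects, no observation noise."""
    return simulate_cohort(
        dkt_connectome, n_subjects=12, mixing=(0.7, 0.3, 0.0),
        noise_sd=0.0, seed=5,
    )


@pytest.fixture(scope="session")
def noisy_cohort(dkt_connectome):
    """20 subjects including the false-positive class, noise sd 0.02."""
    return simulate_cohort(
        dkt_connectome, n_subjects=20, mixing=(0.55, 0.20, 0.25),
        noise_sd=0.02, seed=6,
    )
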