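"""Shared fixtures: the expensive crypt simulations are run once per
session and reused by the acceptance tests."""

import numpy as np
import pytest

from cryptdyn.experiments import (internal_wnt_summary,
                                  wildtype_ci_comparison)

ACCEPTANCE_SEED = 1


@pytest.fixture(scope="session")
def wildtype_comparison():
    """M_E1 wild-type crypts, (theta_W x theta_CI) grid, one seed."""
    return wildtype_ci_comparison(ACCEPTANCE_SEED, n_seeds=1)


@pytest.fixture(scope="session")
def internal_wnt_runs():
    """Division-based Wnt crypts: noiseless 10%/20% reservoirs and a
    noisy 10% reservoir."""
    return {
        (0.1, 0.0): internal_wnt_summary(ACCEPTANCE_SEED, rho=0.1,
                                         sigma=0.0),
        (0.2, 0.0): internal_wnt_summary(ACCEPTANCE_SEED, rho=0.2,
                                         sigma=0.0),
        (0.1, 0.1): internal_wnt_summary(ACCEPTANCE_SEED, rho=0.1,
                                         sigma=0.1),
    }
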