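"""Shared fixtures: small synthetic systems and cached expensive fits."""
from __future__ import annotations

import logging

import numpy as np
import pytest

from specdcm import (
    SimulationConfig,
    default_template,
    simulate_bold,
)
from specdcm.model import DcmParameterLayout, default_priors, variational_laplace
from specdcm.spectra import estimate_csd

logging.getLogger("specdcm").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def template3():
    return default_template(3)


@pytest.fixture(scope="session")
def template5():
    return default_template(5)


@pytest.fixture(scope="session")
def layout3():
    return DcmParameterLayout(3)


@pytest.fixture(scope="session")
def three_region_recovery(template3, layout3):
    """One subject with known 3-region coupling, 10 min of data, fitted.

    Returns (truth graph, fitted posterior, layout); reused wherever a
    realistic fitted posterior is needed.
    """
    cfg = SimulationConfig(n_regions=3, n_subjects=1, duration_s=600.0)
    ts = simulate_bold(template3, np.zeros(cfg.n_samples), cfg, seed=11)
    csd = estimate_csd(ts)
    post = variational_laplace(csd, default_priors(layout3), layout3)
    return template3, post, layout3


def true_off_diagonals(graph, layout):
    return np.array([graph.off_diagonal[i, j] for i, j in layout.off_diagonal_pairs])
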