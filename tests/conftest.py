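"""Shared fixtures: small simulated batteries and hand-built matrices."""

import numpy as np
import pytest

import stratsem as st
from stratsem._linalg import diag_positions


@pytest.fixture(scope="session")
def trio_config():
    """Three continuous traits with distinct generating correlations."""
    traits = [
        st.SimTraitSpec("a", "continuous", h2=0.2, n_total=10000),
        st.SimTraitSpec("b", "continuous", h2=0.2, n_total=10000),
        st.SimTraitSpec("x", "continuous", h2=0.3, n_total=20000),
    ]
    Rg = np.array([[1.0, 0.6, 0.1], [0.6, 1.0, 0.5], [0.1, 0.5, 1.0]])
    return st.SimBatteryConfig(traits=traits, Rg=Rg, M=2000, seed=42)


@pytest.fixture(scope="session")
def trio_battery(trio_config):
    return st.simulate_battery(trio_config)


@pytest.fixture(scope="session")
def trio_gc(trio_config, trio_battery):
    tables, ld, _ = trio_battery
    return st.multivariable_ldsc(tables, ld, trio_config.trait_metas(),
                                 n_blocks=200)


@pytest.fixture(scope="session")
def trio_corr(trio_gc):
    return trio_gc.standardize()


def fixed_diag_vr(k, var=1e-4):
    """Sampling covariance with equal variance on every off-diagonal
    element and zero rows/columns for the fixed unit diagonal."""
    p = k * (k + 1) // 2
    v = np.eye(p) * var
    for pos in diag_positions(k):
        v[pos, :] = 0.0
        v[:, pos] = 0.0
    return v


@pytest.fixture
def equal_weight_vr():
    return fixed_diag_vr
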