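import numpy as np
import pytest

from butyflux import build_core_model, build_stoich_matrix


@pytest.fixture(scope="session")
def core():
    """Default core network: (model, manifest, role map). Treat as read-only."""
    return build_core_model()


@pytest.fixture(scope="session")
def core_model(core):
    return core[0]


@pytest.fixture(scope="session")
def core_manifest(core):
    return core[1]


@pytest.fixture(scope="session")
def core_roles(core):
    return core[2]


@pytest.fixture()
def fresh_core(core_model):
    """A mutable copy of the core model for tests that edit bounds."""
    return core_model.copy()


def lp_arrays(model):
    """(S, lb, ub, c) in model order, for the vertex oracle."""
    S, _, rxn_index = build_stoich_matrix(model)
    lb = np.array([r.lower_bound for r in model.reactions.values()])
    ub = np.array([r.upper_bound for r in model.reactions.values()])
    c = np.zeros(len(rxn_index))
    c[rxn_index[model.objective_reaction_id]] = 1.0
    return S, lb, ub, c, rxn_index


def assert_nondecreasing(values, tol=1e-9, label=""):
    values = list(values)
    for a, b in zip(values, values[1:]):
        assert b >= a - tol, f"{label} not non-decreasing: {values}"


def assert_nonincreasing(values, tol=1e-9, label=""):
    assert_nondecreasing([-v for v in values], tol, label or "negated series")
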