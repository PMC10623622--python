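import numpy as np
import pytest

import itemfx as fx

SEED_PANEL = 20260926


@pytest.fixture(scope="session")
def spec3() -> fx.LSTSpec:
    return fx.build_spec("item_effects", reference_item=3)


@pytest.fixture(scope="session")
def spec5() -> fx.LSTSpec:
    return fx.build_spec("item_effects", reference_item=5)


@pytest.fixture(scope="session")
def spec_states() -> fx.LSTSpec:
    return fx.build_spec("states_only", reference_item=3)


@pytest.fixture(scope="session")
def truth() -> fx.ParameterVector:
    return fx.default_true_parameters()


@pytest.fixture(scope="session")
def panel2000(spec3, truth):
    """One seeded N=2000 panel with an outcome composite, shared across
    tests that only read it."""
    config = fx.SimConfig(
        spec=spec3, params=truth, n=2000,
        outcomes=(fx.mhi_outcome(),), seed=SEED_PANEL,
    )
    return fx.simulate_panel(config)


@pytest.fixture(scope="session")
def fit3(spec3, panel2000) -> fx.FittedModel:
    fitted = fx.fit(spec3, panel2000)
    assert fitted.converged
    return fitted


@pytest.fixture(scope="session")
def fit5(spec5, panel2000) -> fx.FittedModel:
    fitted = fx.fit(spec5, panel2000)
    assert fitted.converged
    return fitted


@pytest.fixture(scope="session")
def fit_states(spec_states, panel2000) -> fx.FittedModel:
    fitted = fx.fit(spec_states, panel2000)
    assert fitted.converged
    return fitted


def random_admissible_params(spec, rng) -> fx.ParameterVector:
    """Draw a random admissible parameter vector for property tests."""
    m = spec.m
    A = rng.standard_normal((m, m)) * 0.3
    Phi = A @ A.T + np.eye(m) * (0.5 + rng.random())
    I = spec.design.n_items
    lam = np.ones(I)
    alpha = np.zeros(I)
    if spec.variant == "states_only":
        lam += 0.3 * rng.standard_normal(I)
        alpha += rng.standard_normal(I)
        lam[spec.reference_item - 1] = 1.0
        alpha[spec.reference_item - 1] = 0.0
    return fx.ParameterVector(
        kappa=rng.standard_normal(m) * 2.0,
        Phi=Phi,
        lam=lam,
        alpha=alpha,
        theta=0.2 + rng.random(spec.design.p),
    )
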