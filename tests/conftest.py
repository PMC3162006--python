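"""Shared fixtures: the toy pathway, its reference transient, and a DAE/
conservation test model.  Session-scoped where simulation cost matters."""

import numpy as np
import pytest

import phasereduce as pr

TOY_PROTOCOL = pr.StimulusProtocol(
    parameter="k1", on_value=100.0, off_value=0.0,
    t_on=0.0, t_off=10.0, t_end=20.0, n_out=2000,
)


@pytest.fixture(scope="session")
def toy():
    return pr.make_toy_model()


@pytest.fixture(scope="session")
def toy_protocol():
    return TOY_PROTOCOL


@pytest.fixture(scope="session")
def toy_tc(toy):
    return pr.simulate_transient(toy, TOY_PROTOCOL)


@pytest.fixture(scope="session")
def toy_ntc(toy_tc):
    return pr.normalize(toy_tc)


@pytest.fixture(scope="session")
def toy_am(toy_ntc):
    return pr.pairwise_area_matrix(toy_ntc)


@pytest.fixture(scope="session")
def toy_ss_on(toy):
    return pr.find_steady_state(toy, {"k1": 100.0})


@pytest.fixture(scope="session")
def toy_clamp_fit(toy, toy_tc):
    """Linear steady-state relation B(A) from the concentration clamp."""
    sweep = pr.default_sweep(toy_tc, "A")
    curve = pr.concentration_clamp(toy, "A", sweep, "B", {"k1": 100.0})
    return curve, pr.fit_relation(curve)


@pytest.fixture()
def dae_toy():
    """Toy chain with B defined by its quasi-steady residual (index-1 DAE)."""
    return pr.build_model(
        "toy_dae",
        odes={"A": "k1 - k2*A", "C": "k3*B - k4*C"},
        algebraic={"B": "k2*A - k3*B"},
        params={"k1": 0.0, "k2": 1.0, "k3": 10.0, "k4": 1.0},
    )


@pytest.fixture()
def binding_model():
    """Reversible binding with a conserved total: E + C = Etot."""
    return pr.build_model(
        "binding",
        odes={"C": "kon*E*S - koff*C"},
        explicit={"E": "Etot - C"},
        parameterized=["S"],
        params={"kon": 1.0, "koff": 0.1, "Etot": 1.0, "S": 0.0},
        conserved=[("Etot", ["E", "C"])],
    )


def cascade_protocol(spec: pr.SyntheticCascadeSpec, n_out: int = 600):
    """Transient protocol scaled to a cascade's slowest relaxation time."""
    t_off = max(5.0 / min(spec.rate_ladder), 5.0)
    return pr.StimulusProtocol(parameter="u", on_value=spec.input_magnitude,
                               off_value=0.0, t_on=0.0, t_off=t_off,
                               t_end=2.0 * t_off, n_out=n_out)
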