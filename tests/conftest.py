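"""Shared fixtures: reference models, small synthetic datasets, oracles."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import cestfit as cf
from cestfit.models import ModelSpec, Topology

#: Best-fit triangular kinetics of the E/B/I system at 11.5 C.
TRIANGULAR_VALUES = {
    "p_B": 0.015,
    "p_I": 0.0022,
    "kex_EB": 297.0,
    "kex_EI": 170.0,
    "kex_BI": 1667.0,
}


@pytest.fixture(scope="session")
def triangular_model():
    spec = ModelSpec(topology=Topology.TRIANGULAR, states=("E", "B", "I"))
    return cf.build_model(spec, TRIANGULAR_VALUES)


@pytest.fixture(scope="session")
def two_state_model():
    return cf.ExchangeModel(
        states=("A", "B"),
        populations=(0.975, 0.025),
        kex={("A", "B"): 300.0},
        topology=Topology.TWO_STATE,
    )


@pytest.fixture
def simple_spin():
    return cf.SpinSystem(
        nucleus="N15",
        shifts={"A": 0.0, "B": 3.0},
        r1={"A": 1.0, "B": 1.0},
        r2={"A": 10.0, "B": 10.0},
    )


def ode_propagate(matrix, duration, initial):
    """Adaptive-ODE reference for the matrix-exponential propagator."""
    matrix = np.asarray(matrix)
    initial = np.asarray(initial, dtype=complex)
    n = len(initial)

    def rhs(_, y):
        m = y[:n] + 1j * y[n:]
        dm = matrix @ m
        return np.concatenate([dm.real, dm.imag])

    y0 = np.concatenate([initial.real, initial.imag])
    sol = solve_ivp(rhs, (0.0, duration), y0, rtol=1e-12, atol=1e-14, method="DOP853")
    return sol.y[:n, -1] + 1j * sol.y[n:, -1]


def make_two_state_cest_dataset(
    n_sites=4,
    noise=0.005,
    seed=0,
    b1_list=(18.1, 51.8),
    kex=300.0,
    p_b=0.025,
    step=0.25,
):
    """Small two-state CEST dataset with known generating parameters."""
    model = cf.ExchangeModel(
        states=("E", "B"),
        populations=(1.0 - p_b, p_b),
        kex={("E", "B"): kex},
        topology=Topology.TWO_STATE,
    )
    rng = np.random.default_rng(seed)
    data = cf.Dataset(nuclei={})
    guesses = {}
    exps = [
        cf.CESTExperiment.from_ppm(16.4, b1, 0.4, np.arange(-7, 7.01, step), "N15")
        for b1 in b1_list
    ]
    for i in range(n_sites):
        dw = float(rng.uniform(1.5, 5.0) * rng.choice([-1, 1]))
        spin = cf.SpinSystem(
            "N15", {"E": 0.0, "B": dw}, {"E": 1.0, "B": 1.0}, {"E": 10.0, "B": 10.0}
        )
        sid = f"s{i}"
        data.nuclei[sid] = "N15"
        for exp in exps:
            p = cf.simulate_cest_profile(model, spin, exp)
            y = p.intensity_ratio + rng.normal(0.0, noise, len(p.intensity_ratio))
            sigma = np.full(len(y), noise if noise > 0 else 0.005)
            data.cest.append(
                replace(p, site_id=sid, intensity_ratio=y, sigma=sigma)
            )
        guesses[sid] = {"w": 0.0, "dw1": dw, "r2": 10.0, "r1": 1.0}
    return model, data, guesses


def truth_signs(config):
    """Sign map of the minor-minor shift difference from a scenario's truth."""
    states = config.model.states
    return {
        sid: (1 if spin.shifts[states[2]] >= spin.shifts[states[1]] else -1)
        for sid, spin in config.sites
    }


def truth_init(config):
    """Kinetic initial values equal to a scenario's generating parameters."""
    m = config.model
    init = {f"p_{s}": m.population(s) for s in m.states[1:]}
    for (a, b), kex in m.kex.items():
        init[f"kex_{a}{b}"] = kex
    return init
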