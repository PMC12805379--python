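"""Reference simulation studies built on the synthetic scenarios.

Each function regenerates a benchmark dataset from scratch and runs the
corresponding analysis, returning the fit (or derived observables).  They
are thin, deterministic compositions of the generator and the fitting
layer, used by the acceptance script and the test suite, and convenient as
worked examples:

* the three-state CPMG study fit with a two-state model (tied R2),
* the matching CEST study fit with a two-state model (minor-state R2 free),
* the indirect-flux fraction from the reported triangular parameters,
* CPMG dispersions synthesized from the triangular parameters, re-fit
  two-state,
* a urea titration analyzed with reference-anchored chemical shifts.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Dict, Optional, Tuple

import numpy as np

from .constants import DEFAULT_TEMPERATURE_K, R_GAS
from .fitting import FitResult, StartConfig, fit_global
from .models import ModelSpec, Topology, apply_sign_constraints, build_model
from .spin_dynamics import CPMGExperiment
from .synthetic import (
    _t4l_experiments,
    _UREA_CONCENTRATIONS,
    _UREA_M_VALUES,
    builtin_scenarios,
    generate_scenario,
    scenario_guesses,
)
from .thermo import (
    MValueResult,
    UreaPoint,
    UreaSeries,
    m_value_regression,
    phi_indirect,
)

__all__ = [
    "REPORTED_TRIANGULAR",
    "phi_from_reported_parameters",
    "abc_cpmg_two_state",
    "abc_cest_two_state",
    "cpmg_from_triangular",
    "urea_mvalue_study",
]

#: Reported best-fit triangular exchange parameters of the E/B/I system
#: (11.5 C): minor-state populations and pairwise exchange rate constants.
REPORTED_TRIANGULAR: Dict[str, float] = {
    "p_B": 0.015,
    "p_I": 0.0022,
    "kex_EB": 297.0,
    "kex_EI": 170.0,
    "kex_BI": 1667.0,
}

_GENERIC_2STATE_INIT = {"p_B": 0.02, "kex": 500.0}


def _two_state_init(spec: ModelSpec) -> Dict[str, float]:
    a, b = spec.edges[0]
    return {f"p_{spec.states[1]}": 0.02, f"kex_{a}{b}": 500.0}


def phi_from_reported_parameters() -> float:
    """phi_I (fraction) from the reported triangular best-fit parameters."""
    spec = ModelSpec(topology=Topology.TRIANGULAR, states=("E", "B", "I"))
    return phi_indirect(build_model(spec, REPORTED_TRIANGULAR))


def abc_cpmg_two_state(
    seed: int, n_sites: int = 58, n_starts: int = 3
) -> FitResult:
    """Three-state CPMG study fit with a two-state model (R2 tied).

    Generates the 58-site linear A-B-C CPMG datasets at 11.7 and 18.8 T and
    fits them with the simple A-B exchange model; the fitted kex and p_B
    barely feel the sparse fast-exchanging C state.
    """
    cfg = builtin_scenarios("abc_cpmg", seed=seed, n_sites=n_sites)
    data = generate_scenario(cfg)
    guesses = scenario_guesses(cfg)
    spec = ModelSpec(
        topology=Topology.TWO_STATE, states=("A", "B"), r2_mode="tied",
        r1_mode="fixed", r1_value=1.0,
    )
    return fit_global(
        data,
        spec,
        starts=StartConfig(n_starts=n_starts, init=_two_state_init(spec)),
        seed=seed,
        guesses=guesses,
    )


def abc_cest_two_state(
    seed: int,
    n_sites: int = 20,
    r2_mode: str = "free_minor",
    n_starts: int = 3,
) -> FitResult:
    """Three-state CEST study fit with a two-state model.

    With ``r2_mode="free_minor"`` the fit absorbs the hidden C state into an
    inflated minor-state R2 -- the telltale signature; with ``"tied"`` the
    same data are poorly reproduced.
    """
    cfg = builtin_scenarios("abc_cest", seed=seed, n_sites=n_sites)
    data = generate_scenario(cfg)
    guesses = scenario_guesses(cfg)
    spec = ModelSpec(
        topology=Topology.TWO_STATE, states=("A", "B"), r2_mode=r2_mode,
        r1_mode="fit",
    )
    return fit_global(
        data,
        spec,
        starts=StartConfig(n_starts=n_starts, init=_two_state_init(spec)),
        seed=seed,
        guesses=guesses,
    )


def cpmg_from_triangular(
    seed: int, n_sites: Optional[int] = None, n_starts: int = 3
) -> FitResult:
    """CPMG dispersions synthesized from the triangular parameters, fit
    two-state.

    Emulates the consistency check that the rapidly exchanging sparse I
    state is subsumed into B in CPMG data: 15N and 13C dispersions at 11.7
    and 18.8 T generated from the reported E/B/I model are well fit by a
    two-state model with tied R2.
    """
    cfg = builtin_scenarios("t4l_cest_11p5C", seed=seed, n_sites=n_sites)
    nu = np.arange(50.0, 1001.0, 50.0)
    exps = [
        (nucleus, CPMGExperiment(b0=b0, t_relax=0.02, nu_cpmg=nu))
        for nucleus in ("N15", "C13")
        for b0 in (11.7, 18.8)
    ]
    cfg = replace(cfg, name="t4l_cpmg_from_cest", experiments=exps)
    data = generate_scenario(cfg)
    guesses = scenario_guesses(cfg)
    spec = ModelSpec(
        topology=Topology.TWO_STATE, states=("E", "B"), r2_mode="tied",
        r1_mode="fixed", r1_value=1.0,
    )
    return fit_global(
        data,
        spec,
        starts=StartConfig(n_starts=n_starts, init=_two_state_init(spec)),
        seed=seed,
        guesses=guesses,
    )


def _triangular_spec_for(cfg) -> ModelSpec:
    signs = {
        sid: (1 if spin.shifts["I"] >= spin.shifts["B"] else -1)
        for sid, spin in cfg.sites
    }
    spec = ModelSpec(
        topology=Topology.TRIANGULAR, states=("E", "B", "I"), r2_mode="tied",
        r1_mode="fit",
    )
    return apply_sign_constraints(spec, signs)


def urea_mvalue_study(
    seed: int,
    n_sites: int = 10,
    b1_subset: int = 4,
    temperature: float = DEFAULT_TEMPERATURE_K,
) -> Tuple[MValueResult, Dict[object, float]]:
    """Full urea-titration pipeline: generate, fit, regress.

    The reference (0 M) dataset is fit with free per-site shifts; the
    titration points are then fit with every chemical shift fixed at its
    reference assignment (denaturant-independent shifts), which removes the
    population/kinetics exchange-degeneracy between the two minor states.
    Returns the m-value regression and the generating m-values keyed the
    same way.
    """
    configs = builtin_scenarios("urea_series", seed=seed, n_sites=n_sites)
    rt = R_GAS * temperature / 1000.0
    points = []
    shift_anchor: Optional[Dict[str, float]] = None
    kin_warm: Optional[Dict[str, float]] = None
    for conc, cfg in zip(_UREA_CONCENTRATIONS, configs):
        cfg = replace(
            cfg, experiments=_t4l_experiments(c13=False, b1_subset=b1_subset)
        )
        data = generate_scenario(cfg)
        guesses = scenario_guesses(cfg)
        spec = _triangular_spec_for(cfg)
        init = kin_warm or {
            "p_B": 0.02, "p_I": 0.005,
            "kex_EB": 400.0, "kex_EI": 300.0, "kex_BI": 2500.0,
        }
        fit = fit_global(
            data,
            spec,
            starts=StartConfig(n_starts=1, init=init),
            seed=seed,
            guesses=guesses,
            dw1_window=0.5 if shift_anchor is None else None,
            fixed=shift_anchor,
        )
        if shift_anchor is None:
            shift_anchor = {
                name: value
                for name, value in fit.best_values.items()
                if name.startswith("dw_") or name.startswith("w@")
            }
        kin_warm = {
            k: v for k, v in fit.best_values.items()
            if k in ("p_B", "p_I", "kex_EB", "kex_EI", "kex_BI")
        }
        sigma_states = {
            s: rt * fit.uncertainties[f"p_{s}"] / fit.best_values[f"p_{s}"]
            for s in ("B", "I")
        }
        # delta method on dG_TS(a,b) = -RT [ln(p_a/p_E) + ln kex
        #                                    + ln p_b - ln(p_a+p_b) - ln C]
        sigma_ts = {}
        pops = {s: fit.best_values[f"p_{s}"] for s in ("E", "B", "I")}
        rels = {
            s: fit.uncertainties.get(f"p_{s}", 0.0) / pops[s] for s in ("B", "I")
        }
        rels["E"] = 0.0
        for a, b in (("E", "B"), ("E", "I"), ("B", "I")):
            rel_k = (
                fit.uncertainties[f"kex_{a}{b}"] / fit.best_values[f"kex_{a}{b}"]
            )
            fa = pops[b] / (pops[a] + pops[b])  # dlnG/dln p_a coefficient
            fb = pops[a] / (pops[a] + pops[b])
            sigma_ts[(a, b)] = rt * np.sqrt(
                rel_k**2 + (fa * rels[a]) ** 2 + (fb * rels[b]) ** 2
            )
        points.append(
            UreaPoint(
                conc,
                fit.model,
                sigma_dg_states=sigma_states,
                sigma_dg_ts=sigma_ts,
            )
        )
    result = m_value_regression(UreaSeries(points), temperature)
    truth: Dict[object, float] = {"B": -0.4, "I": 0.4}
    for key in result.m_ts:
        truth[key] = _UREA_M_VALUES[frozenset(key)]
    return result, truth
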