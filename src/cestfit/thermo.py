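"""Free-energy-surface observables from fitted exchange parameters.

Converts populations and microscopic rates into:

* the indirect-flux fraction ``phi_I`` -- the fraction of major-to-minor
  (E -> B) conversions that route through the intermediate I in the
  triangular scheme, from the steady-state branching expression

      phi_I = (k_EI k_IB / (k_IE + k_IB)) / (k_EB + k_EI k_IB / (k_IE + k_IB)),

  which equals the first-passage probability that a molecule starting in E
  enters B from I (the jump-chain identity bc / (1 - b(1 - c)));
* state free energies relative to the major state,
  ``dG_EK = -RT ln(p_K / p_E)``;
* transition-state free energies
  ``dG_E,TS(L,M) = -RT ln(p_L / p_E) - RT ln(k_LM / C)`` with a reference
  prefactor C (default 1e7 s^-1).  C shifts all barriers uniformly and
  cancels exactly in urea m-values;
* urea m-values ``m = -d(dG)/d[urea]`` from weighted linear regression of
  dG against denaturant concentration.

Energies are in kJ/mol; concentrations in M; temperatures in K.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np

from .constants import DEFAULT_C_REF, DEFAULT_TEMPERATURE_K, R_GAS
from .spin_dynamics import ExchangeModel, Topology

__all__ = [
    "LandscapeResult",
    "UreaPoint",
    "UreaSeries",
    "MValueResult",
    "phi_indirect",
    "free_energy_offsets",
    "transition_state_energies",
    "landscape_result",
    "model_from_free_energies",
    "m_value_regression",
]


@dataclass
class LandscapeResult:
    """Free-energy offsets of states and transition states."""

    delta_g_states: Dict[str, float]  # kJ/mol, reference state -> 0
    delta_g_ts: Dict[Tuple[str, str], float]  # kJ/mol
    phi_i: Optional[float]
    temperature: float
    c_ref: float


@dataclass
class UreaPoint:
    """One denaturant concentration with its fitted exchange model.

    Optional standard deviations of the derived free energies (kJ/mol) are
    used as regression weights.
    """

    concentration: float
    model: ExchangeModel
    sigma_dg_states: Dict[str, float] = field(default_factory=dict)
    sigma_dg_ts: Dict[Tuple[str, str], float] = field(default_factory=dict)


@dataclass
class UreaSeries:
    points: List[UreaPoint]

    def __post_init__(self) -> None:
        concs = [p.concentration for p in self.points]
        if any(c < 0 for c in concs):
            raise ValueError("concentrations must be non-negative")
        if len(set(concs)) < 2:
            raise ValueError("need at least two distinct concentrations")


@dataclass
class MValueResult:
    """m-values (kJ/mol/M) with standard errors for states and barriers."""

    m_states: Dict[str, Tuple[float, float]]
    m_ts: Dict[Tuple[str, str], Tuple[float, float]]


def phi_indirect(model: ExchangeModel) -> float:
    """Fraction of E -> B conversions proceeding via the intermediate I.

    ``model`` must be triangular with states ordered (E, B, I).  Returns a
    value in [0, 1]; raises if both the direct rate and the indirect flux
    vanish (the branching fraction is then undefined).
    """
    if model.topology is not None and model.topology is not Topology.TRIANGULAR:
        raise ValueError("phi_indirect requires a triangular model")
    e, b, i = model.states[:3]
    k_eb = model.rate(e, b)
    k_ei = model.rate(e, i)
    k_ie = model.rate(i, e)
    k_ib = model.rate(i, b)
    indirect = k_ei * k_ib / (k_ie + k_ib) if (k_ie + k_ib) > 0 else 0.0
    denom = k_eb + indirect
    if denom == 0.0:
        raise ValueError("no E -> B flux: both direct and indirect rates are zero")
    return indirect / denom


def free_energy_offsets(
    model: ExchangeModel, temperature: float = DEFAULT_TEMPERATURE_K
) -> Dict[str, float]:
    """dG_EK = -RT ln(p_K / p_E) in kJ/mol; the reference (major) state is 0."""
    rt = R_GAS * temperature / 1000.0
    ref = model.states[0]
    p_ref = model.population(ref)
    out = {}
    for s, p in zip(model.states, model.populations):
        if p <= 0:
            raise ValueError(f"state {s} has zero population")
        out[s] = -rt * np.log(p / p_ref)
    return out


def transition_state_energies(
    model: ExchangeModel,
    temperature: float = DEFAULT_TEMPERATURE_K,
    c_ref: float = DEFAULT_C_REF,
) -> Dict[Tuple[str, str], float]:
    """Barrier heights dG_E,TS(L,M) = -RT ln(p_L/p_E) - RT ln(k_LM / C).

    One value per connected pair, keyed (L, M) with L the lower-free-energy
    state of the pair; by detailed balance the value is identical when
    computed from either direction (asserted to 1e-9 kJ/mol).
    """
    rt = R_GAS * temperature / 1000.0
    dg = free_energy_offsets(model, temperature)
    out: Dict[Tuple[str, str], float] = {}
    for (a, b), kex in model.kex.items():
        if kex <= 0:
            raise ValueError(f"pair ({a}, {b}) has zero exchange rate")
        g_ab = dg[a] - rt * np.log(model.rate(a, b) / c_ref)
        g_ba = dg[b] - rt * np.log(model.rate(b, a) / c_ref)
        if abs(g_ab - g_ba) > 1e-9:
            raise AssertionError(
                f"detailed-balance violation for pair ({a}, {b}): "
                f"{g_ab} != {g_ba}"
            )
        key = (a, b) if dg[a] <= dg[b] else (b, a)
        out[key] = g_ab
    return out


def landscape_result(
    model: ExchangeModel,
    temperature: float = DEFAULT_TEMPERATURE_K,
    c_ref: float = DEFAULT_C_REF,
) -> LandscapeResult:
    """Bundle state and barrier free energies (plus phi_I when triangular)."""
    phi = phi_indirect(model) if model.topology is Topology.TRIANGULAR else None
    return LandscapeResult(
        delta_g_states=free_energy_offsets(model, temperature),
        delta_g_ts=transition_state_energies(model, temperature, c_ref),
        phi_i=phi,
        temperature=temperature,
        c_ref=c_ref,
    )


def model_from_free_energies(
    states: Tuple[str, ...],
    delta_g_states: Mapping[str, float],
    delta_g_ts: Mapping[Tuple[str, str], float],
    topology: Topology,
    temperature: float = DEFAULT_TEMPERATURE_K,
    c_ref: float = DEFAULT_C_REF,
) -> ExchangeModel:
    """Inverse of the landscape mapping: free energies -> ExchangeModel.

    ``delta_g_states`` gives dG_EK (kJ/mol, major state 0) and
    ``delta_g_ts`` the barrier of each connected pair (keyed in either
    direction).  Used by the synthetic urea-titration generator.
    """
    rt = R_GAS * temperature / 1000.0
    rel = np.array([np.exp(-delta_g_states.get(s, 0.0) / rt) for s in states])
    pops = rel / rel.sum()
    pop_map = dict(zip(states, pops))
    kex = {}
    for (a, b), g_ts in delta_g_ts.items():
        k_ab = c_ref * np.exp(-(g_ts - delta_g_states.get(a, 0.0)) / rt)
        k_ba = c_ref * np.exp(-(g_ts - delta_g_states.get(b, 0.0)) / rt)
        # consistency with detailed balance is automatic:
        # k_ab / k_ba = p_b / p_a up to rounding
        assert abs(k_ab * pop_map[a] - k_ba * pop_map[b]) <= 1e-9 * max(
            k_ab * pop_map[a], k_ba * pop_map[b]
        )
        kex[(a, b)] = k_ab + k_ba
    return ExchangeModel(
        states=tuple(states),
        populations=tuple(pops),
        kex=kex,
        topology=topology,
    )


def _weighted_slope(
    x: np.ndarray, y: np.ndarray, sigma: Optional[np.ndarray]
) -> Tuple[float, float]:
    """Weighted least-squares slope and its standard error.

    Falls back to unit weights when uncertainties are absent; with exactly
    two points the slope is the finite difference and the propagated error
    is reported (0 for unweighted two-point input).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("all concentrations equal; regression design is singular")
    if sigma is None or np.any(~np.isfinite(sigma)) or np.any(sigma <= 0):
        w = np.ones_like(x)
    else:
        w = 1.0 / np.asarray(sigma, dtype=float) ** 2
    sw = w.sum()
    xbar = (w * x).sum() / sw
    sxx = (w * (x - xbar) ** 2).sum()
    slope = (w * (x - xbar) * y).sum() / sxx
    if np.allclose(w, 1.0):
        se = _unweighted_se(x, y, slope)
    else:
        se = np.sqrt(1.0 / sxx)
        # inflate by the regression's reduced chi-square when the scatter
        # exceeds the stated per-point uncertainties (standard lack-of-fit
        # scaling)
        n = len(x)
        if n > 2:
            intercept = (w * y).sum() / sw - slope * xbar
            chi2_red = float(
                (w * (y - intercept - slope * x) ** 2).sum() / (n - 2)
            )
            se *= max(1.0, np.sqrt(chi2_red))
    return float(slope), float(se)


def _unweighted_se(x: np.ndarray, y: np.ndarray, slope: float) -> float:
    n = len(x)
    if n <= 2:
        return 0.0
    xbar = x.mean()
    resid = y - y.mean() - slope * (x - xbar)
    s2 = (resid**2).sum() / (n - 2)
    return float(np.sqrt(s2 / ((x - xbar) ** 2).sum()))


def m_value_regression(
    series: UreaSeries, temperature: float = DEFAULT_TEMPERATURE_K
) -> MValueResult:
    """Urea m-values m = -d(dG)/d[urea] for states and transition states.

    dG values are derived from each concentration's model; the regression is
    weighted by the supplied per-point dG uncertainties when available.
    """
    concs = np.array([p.concentration for p in series.points])
    ref_model = series.points[0].model
    states = ref_model.states

    m_states: Dict[str, Tuple[float, float]] = {}
    for s in states[1:]:
        dg = np.array(
            [free_energy_offsets(p.model, temperature)[s] for p in series.points]
        )
        sig = np.array(
            [p.sigma_dg_states.get(s, np.nan) for p in series.points]
        )
        sigma = sig if np.all(np.isfinite(sig)) else None
        slope, se = _weighted_slope(concs, dg, sigma)
        m_states[s] = (-slope, se)

    m_ts: Dict[Tuple[str, str], Tuple[float, float]] = {}
    ts_keys = transition_state_energies(ref_model, temperature).keys()
    # barrier values are direction-invariant; index by unordered pair so a
    # state crossing between concentrations cannot change the key
    per_point_ts = [
        {frozenset(k): v for k, v in transition_state_energies(p.model, temperature).items()}
        for p in series.points
    ]
    for key in ts_keys:
        dg = np.array([ts[frozenset(key)] for ts in per_point_ts])
        sig = np.array(
            [
                p.sigma_dg_ts.get(key, p.sigma_dg_ts.get((key[1], key[0]), np.nan))
                for p in series.points
            ]
        )
        sigma = sig if np.all(np.isfinite(sig)) else None
        slope, se = _weighted_slope(concs, dg, sigma)
        m_ts[key] = (-slope, se)
    return MValueResult(m_states=m_states, m_ts=m_ts)
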