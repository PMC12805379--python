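"""Bloch-McConnell forward simulation of CEST and CPMG observables.

An N-state chemical-exchange process is described by fractional populations
``p_i`` and pairwise exchange rate constants ``kex_ij = k_ij + k_ji``.  A
single spin probe (amide 15N or methyl 13C) carries a chemical shift and
intrinsic relaxation rates in each state.  Two experiments are simulated by
propagating the Bloch-McConnell equations:

* **CEST** -- magnetization starts at thermal equilibrium along z and evolves
  for an irradiation time ``T_EX`` under a weak B1 field applied at a series
  of carrier offsets.  The observable is the ratio ``I/I0`` of the major-state
  z magnetization after and before irradiation.  Saturation transferred
  through exchange produces intensity dips at the minor-state shifts.
* **CPMG** -- transverse magnetization evolves through a constant-time train
  of ideal pi pulses with pulsing frequency ``nu_cpmg``; the observable is the
  effective transverse relaxation rate ``R2_eff = -ln(I/I0) / T_relax``.

The CEST evolution uses a homogeneous 3N-dimensional system (x, y, z
components per state) with no thermal-equilibrium inflow term, so the
far-off-resonance limit decays as ``exp(-R1 * T_EX)``, consistent with the
``I/I0`` normalization.  The CPMG evolution uses the complex N-dimensional
transverse basis with ideal (instantaneous) pi rotations implemented as
complex conjugation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import scipy.linalg

from .constants import larmor_mhz

__all__ = [
    "Topology",
    "InvalidModelError",
    "ExchangeModel",
    "SpinSystem",
    "CESTExperiment",
    "CPMGExperiment",
    "CESTProfile",
    "CPMGProfile",
    "microscopic_rates",
    "exchange_generator",
    "propagate",
    "simulate_cest_profile",
    "simulate_cpmg_profile",
    "cpmg_pulse_count",
]


class Topology(str, enum.Enum):
    """Exchange topologies, named for a major state E and minors B and I."""

    TWO_STATE = "two_state"
    TRIANGULAR = "triangular"
    LINEAR_ON_PATHWAY = "linear_on_pathway"  # E <-> I <-> B
    LINEAR_OFF_PATHWAY = "linear_off_pathway"  # E <-> B <-> I
    BIFURCATED = "bifurcated"  # I <-> E <-> B


class InvalidModelError(ValueError):
    """Raised when an exchange model violates its invariants."""


def microscopic_rates(
    populations: Mapping[str, float],
    kex_pairs: Mapping[Tuple[str, str], float],
) -> Dict[Tuple[str, str], float]:
    """Microscopic rate constants from populations and pairwise kex.

    For a connected pair (i, j) with exchange rate constant
    ``kex_ij = k_ij + k_ji`` and detailed balance ``k_ij p_i = k_ji p_j``,

        k(i -> j) = kex_ij * p_j / (p_i + p_j).

    Returns a map from ordered pairs to rates; both directions are included
    for every pair in ``kex_pairs``.
    """
    rates: Dict[Tuple[str, str], float] = {}
    for (a, b), kex in kex_pairs.items():
        if kex < 0:
            raise InvalidModelError(f"negative exchange rate for pair ({a}, {b}): {kex}")
        pa = populations[a]
        pb = populations[b]
        denom = pa + pb
        if denom <= 0.0:
            raise InvalidModelError(
                f"cannot partition kex for pair ({a}, {b}): both populations are zero"
            )
        rates[(a, b)] = kex * pb / denom
        rates[(b, a)] = kex * pa / denom
    return rates


@dataclass(frozen=True)
class ExchangeModel:
    """N-state exchange model: populations plus pairwise exchange rates.

    Parameters
    ----------
    states:
        Ordered state labels; the first entry is conventionally the major
        (observed) state.
    populations:
        Fractional population per state; must sum to 1.
    kex:
        Map from a state pair (canonical order: by position in ``states``) to
        the exchange rate constant ``kex_ij = k_ij + k_ji`` in s^-1.  Pairs
        absent from the map are not connected (both microscopic rates are
        exactly zero).
    topology:
        Optional tag recording which named topology the connectivity follows.
    """

    states: Tuple[str, ...]
    populations: Tuple[float, ...]
    kex: Dict[Tuple[str, str], float]
    topology: Optional[Topology] = None
    k_micro: Dict[Tuple[str, str], float] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        states = tuple(self.states)
        pops = tuple(float(p) for p in self.populations)
        object.__setattr__(self, "states", states)
        object.__setattr__(self, "populations", pops)
        if len(set(states)) != len(states):
            raise InvalidModelError(f"duplicate state labels: {states}")
        if len(pops) != len(states):
            raise InvalidModelError("one population per state required")
        for s, p in zip(states, pops):
            # minor states live in (0, 1); a degenerate single-state model
            # (population exactly 1) is allowed for limit checks
            if not 0.0 < p <= 1.0:
                raise InvalidModelError(f"population of state {s} not in (0, 1]: {p}")
        if abs(sum(pops) - 1.0) > 1e-12:
            raise InvalidModelError(f"populations sum to {sum(pops)!r}, not 1")
        index = {s: i for i, s in enumerate(states)}
        kex_norm: Dict[Tuple[str, str], float] = {}
        for (a, b), k in self.kex.items():
            if a not in index or b not in index or a == b:
                raise InvalidModelError(f"invalid state pair ({a}, {b})")
            key = (a, b) if index[a] < index[b] else (b, a)
            if key in kex_norm:
                raise InvalidModelError(f"duplicate exchange pair {key}")
            kex_norm[key] = float(k)
        object.__setattr__(self, "kex", kex_norm)
        pop_map = dict(zip(states, pops))
        object.__setattr__(self, "k_micro", microscopic_rates(pop_map, kex_norm))

    @property
    def n_states(self) -> int:
        return len(self.states)

    def population(self, state: str) -> float:
        return self.populations[self.states.index(state)]

    def rate(self, i: str, j: str) -> float:
        """Microscopic rate k(i -> j); zero for unconnected pairs."""
        return self.k_micro.get((i, j), 0.0)

    def kex_of(self, a: str, b: str) -> float:
        index = {s: k for k, s in enumerate(self.states)}
        key = (a, b) if index[a] < index[b] else (b, a)
        return self.kex.get(key, 0.0)


@dataclass(frozen=True)
class SpinSystem:
    """Per-state chemical shifts and relaxation rates for one spin site.

    ``shifts`` are in ppm; ``r1`` and ``r2`` in s^-1, one entry per model
    state.  R1 of unobservable minor states is experimentally inaccessible
    and is normally tied across states by the caller.
    """

    nucleus: str
    shifts: Dict[str, float]
    r1: Dict[str, float]
    r2: Dict[str, float]

    def __post_init__(self) -> None:
        if set(self.shifts) != set(self.r1) or set(self.shifts) != set(self.r2):
            raise ValueError("shifts, r1 and r2 must cover the same states")
        for s in self.shifts:
            if self.r1[s] <= 0 or self.r2[s] <= 0:
                raise ValueError(f"non-positive relaxation rate for state {s}")

    def delta_ppm(self, i: str, j: str) -> float:
        """Chemical-shift difference (shift of j minus shift of i, ppm)."""
        return self.shifts[j] - self.shifts[i]

    def _check_states(self, model: ExchangeModel) -> None:
        if set(self.shifts) != set(model.states):
            raise ValueError(
                f"spin states {sorted(self.shifts)} do not match model states "
                f"{sorted(model.states)}"
            )


@dataclass(frozen=True)
class CESTExperiment:
    """CEST acquisition settings.

    ``offsets`` are carrier offsets in Hz relative to ``carrier_ref`` (ppm);
    ``b1`` is the saturation field strength in Hz; ``t_ex`` the irradiation
    time in s; ``b0`` the static field in Tesla.
    """

    b0: float
    b1: float
    t_ex: float
    offsets: np.ndarray
    carrier_ref: float = 0.0

    def __post_init__(self) -> None:
        offsets = np.asarray(self.offsets, dtype=float)
        object.__setattr__(self, "offsets", offsets)
        if self.b1 <= 0:
            raise ValueError("b1 must be positive")
        if self.t_ex < 0:
            raise ValueError("t_ex must be non-negative")
        if offsets.ndim != 1 or len(offsets) == 0:
            raise ValueError("offsets must be a non-empty 1-D array")
        if np.any(np.diff(offsets) <= 0):
            raise ValueError("offsets must be strictly increasing")

    @classmethod
    def from_ppm(
        cls,
        b0: float,
        b1: float,
        t_ex: float,
        offsets_ppm: np.ndarray,
        nucleus: str,
        carrier_ref: float = 0.0,
    ) -> "CESTExperiment":
        """Build an experiment from offsets given in ppm."""
        hz_per_ppm = larmor_mhz(b0, nucleus)
        offs = (np.asarray(offsets_ppm, dtype=float) - carrier_ref) * hz_per_ppm
        return cls(b0=b0, b1=b1, t_ex=t_ex, offsets=offs, carrier_ref=carrier_ref)

    def offsets_ppm(self, nucleus: str) -> np.ndarray:
        """Absolute carrier positions on the ppm axis of ``nucleus``."""
        return self.carrier_ref + self.offsets / larmor_mhz(self.b0, nucleus)


@dataclass(frozen=True)
class CPMGExperiment:
    """Constant-time CPMG acquisition settings (ideal pi pulses)."""

    b0: float
    t_relax: float
    nu_cpmg: np.ndarray

    def __post_init__(self) -> None:
        nu = np.asarray(self.nu_cpmg, dtype=float)
        object.__setattr__(self, "nu_cpmg", nu)
        if self.t_relax <= 0:
            raise ValueError("t_relax must be positive")
        for v in nu:
            cpmg_pulse_count(self.t_relax, v)  # validates even pulse count


@dataclass
class CESTProfile:
    """Measured or simulated CEST profile for one site."""

    experiment: CESTExperiment
    site_id: str
    intensity_ratio: np.ndarray
    sigma: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.intensity_ratio = np.asarray(self.intensity_ratio, dtype=float)
        if len(self.intensity_ratio) != len(self.experiment.offsets):
            raise ValueError("intensity_ratio length must match offsets")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if len(self.sigma) != len(self.intensity_ratio):
                raise ValueError("sigma length must match data")
            if np.any(self.sigma <= 0):
                raise ValueError("sigma must be positive")


@dataclass
class CPMGProfile:
    """Measured or simulated CPMG dispersion profile for one site."""

    experiment: CPMGExperiment
    site_id: str
    r2_eff: np.ndarray
    sigma: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.r2_eff = np.asarray(self.r2_eff, dtype=float)
        if len(self.r2_eff) != len(self.experiment.nu_cpmg):
            raise ValueError("r2_eff length must match nu_cpmg")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if len(self.sigma) != len(self.r2_eff):
                raise ValueError("sigma length must match data")
            if np.any(self.sigma <= 0):
                raise ValueError("sigma must be positive")


def exchange_generator(model: ExchangeModel) -> np.ndarray:
    """Kinetic generator matrix K with K[j, i] = k(i -> j).

    Columns sum to zero (probability conservation) and the equilibrium
    population vector is annihilated: K @ p = 0 by detailed balance.
    """
    n = model.n_states
    K = np.zeros((n, n))
    idx = {s: i for i, s in enumerate(model.states)}
    for (a, b), k in model.k_micro.items():
        K[idx[b], idx[a]] += k
        K[idx[a], idx[a]] -= k
    return K


def propagate(matrix: np.ndarray, duration: float, initial: np.ndarray) -> np.ndarray:
    """Matrix-exponential action ``expm(matrix * duration) @ initial``."""
    A = np.asarray(matrix)
    v = np.asarray(initial)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("matrix must be square")
    if v.shape[-1] != A.shape[0]:
        raise ValueError("vector length must match matrix size")
    if not np.all(np.isfinite(A)) or not np.all(np.isfinite(v)):
        raise ValueError("non-finite entries in propagation input")
    return scipy.linalg.expm(A * duration) @ v


def _expm_action_batch(mats: np.ndarray, duration: float, v0: np.ndarray) -> np.ndarray:
    """exp(A_k * t) @ v0 for a stack of matrices, via batched eigendecomposition.

    Bloch-McConnell matrices are generically diagonalizable; any member of the
    stack for which the eigendecomposition is ill-conditioned falls back to a
    dense ``expm``.
    """
    lam, V = np.linalg.eig(mats)
    rhs = np.broadcast_to(v0.astype(complex)[:, None], V.shape[:-2] + v0.shape + (1,))
    coeff = np.linalg.solve(V, rhs)[..., 0]
    out = np.einsum("kij,kj->ki", V, coeff * np.exp(lam * duration))
    bad = ~np.all(np.isfinite(out), axis=-1)
    if np.any(bad):
        for k in np.nonzero(bad)[0]:
            out[k] = scipy.linalg.expm(mats[k] * duration) @ v0
    return out


def _cest_evolution_matrices(
    model: ExchangeModel,
    spin: SpinSystem,
    exp: CESTExperiment,
) -> np.ndarray:
    """Stack of 3N x 3N CEST evolution matrices, one per carrier offset.

    Component ordering is block-wise: (x_1..x_N, y_1..y_N, z_1..z_N).  For
    state i with offset Omega_i (rad/s, relative to the effective carrier)
    and a B1 field omega_1 = 2 pi b1 about x,

        dMx_i/dt = -R2_i Mx_i + Omega_i My_i + sum_j K_ij Mx_j
        dMy_i/dt = -Omega_i Mx_i - R2_i My_i + omega_1 Mz_i + ...
        dMz_i/dt = -omega_1 My_i - R1_i Mz_i + ...
    """
    spin._check_states(model)
    n = model.n_states
    K = exchange_generator(model)
    nu_x = larmor_mhz(exp.b0, spin.nucleus)  # MHz == Hz per ppm
    shifts_hz = np.array([spin.shifts[s] for s in model.states]) * nu_x
    carrier_hz = exp.carrier_ref * nu_x + exp.offsets
    omega = 2.0 * np.pi * (shifts_hz[None, :] - carrier_hz[:, None])
    w1 = 2.0 * np.pi * exp.b1
    r1 = np.array([spin.r1[s] for s in model.states])
    r2 = np.array([spin.r2[s] for s in model.states])

    n_off = len(exp.offsets)
    A = np.zeros((n_off, 3 * n, 3 * n))
    for blk in range(3):
        A[:, blk * n : (blk + 1) * n, blk * n : (blk + 1) * n] = K
    i = np.arange(n)
    A[:, i, i] -= r2
    A[:, n + i, n + i] -= r2
    A[:, 2 * n + i, 2 * n + i] -= r1
    A[:, i, n + i] += omega
    A[:, n + i, i] -= omega
    A[:, n + i, 2 * n + i] += w1
    A[:, 2 * n + i, n + i] -= w1
    if not np.all(np.isfinite(A)):
        raise ValueError("non-finite CEST evolution matrix; check model parameters")
    return A


def simulate_cest_profile(
    model: ExchangeModel,
    spin: SpinSystem,
    exp: CESTExperiment,
    observed_state: Optional[str] = None,
) -> CESTProfile:
    """Simulate a CEST profile (``sigma`` left unset).

    The initial vector has z components equal to the equilibrium populations
    and no transverse magnetization; after propagating for ``t_ex`` the
    intensity ratio is z(observed)/p(observed).
    """
    obs = observed_state if observed_state is not None else model.states[0]
    obs_idx = model.states.index(obs)
    n = model.n_states
    v0 = np.zeros(3 * n)
    v0[2 * n :] = model.populations
    if exp.t_ex == 0.0:
        ratio = np.ones(len(exp.offsets))
    else:
        A = _cest_evolution_matrices(model, spin, exp)
        out = _expm_action_batch(A, exp.t_ex, v0)
        ratio = out[:, 2 * n + obs_idx].real / model.populations[obs_idx]
    return CESTProfile(experiment=exp, site_id="", intensity_ratio=ratio)


def cpmg_pulse_count(t_relax: float, nu_cpmg: float) -> int:
    """Even number of pi pulses for a given pulsing frequency.

    The pulse spacing is Delta = 1/(2 nu_cpmg) between pulse centers, so the
    pulse count is ``t_relax * 2 * nu_cpmg`` rounded to the nearest even
    integer.  If rounding changes the effective nu_cpmg by more than 1% the
    frequency is incompatible with the constant-time delay and an error
    listing admissible values is raised.
    """
    if nu_cpmg <= 0:
        raise ValueError("nu_cpmg must be positive")
    n = int(round(t_relax * nu_cpmg)) * 2
    n = max(n, 2)
    nu_eff = n / (2.0 * t_relax)
    if abs(nu_eff - nu_cpmg) > 0.01 * nu_cpmg:
        step = 1.0 / t_relax
        lo = max(step, (np.floor(nu_cpmg / step) - 1) * step)
        admissible = ", ".join(f"{lo + k * step:g}" for k in range(4))
        raise ValueError(
            f"nu_cpmg = {nu_cpmg:g} Hz incompatible with t_relax = {t_relax:g} s "
            f"(requires an even pulse count; admissible values are multiples of "
            f"{step:g} Hz, e.g. {admissible}, ...)"
        )
    return n


def simulate_cpmg_profile(
    model: ExchangeModel,
    spin: SpinSystem,
    exp: CPMGExperiment,
    observed_state: Optional[str] = None,
) -> CPMGProfile:
    """Simulate a constant-time CPMG dispersion profile (``sigma`` unset).

    Transverse magnetization (complex N-vector, initial value = populations)
    evolves through free-precession blocks of duration Delta/2 alternating
    with ideal pi rotations (complex conjugation).  Two successive echoes
    combine into the linear operator U = P conj(P) conj(P) P with
    P = expm(L Delta / 2), so the train is U^(n/2).  R2_eff is
    ``-ln(|M_obs(T)| / p_obs) / T``; the reference signal I0 is the
    observed-state amplitude without the relaxation element.
    """
    spin._check_states(model)
    obs = observed_state if observed_state is not None else model.states[0]
    obs_idx = model.states.index(obs)
    n = model.n_states
    K = exchange_generator(model)
    nu_x = larmor_mhz(exp.b0, spin.nucleus)
    omega = (
        2.0
        * np.pi
        * (np.array([spin.shifts[s] for s in model.states]) - spin.shifts[obs])
        * nu_x
    )
    r2 = np.array([spin.r2[s] for s in model.states])
    L = K.astype(complex) - np.diag(r2 + 1j * omega)
    lam, V = np.linalg.eig(L)
    Vinv = np.linalg.inv(V)
    m0 = np.asarray(model.populations, dtype=complex)
    i0 = model.populations[obs_idx]

    r2_eff = np.empty(len(exp.nu_cpmg))
    for k, nu in enumerate(exp.nu_cpmg):
        npulse = cpmg_pulse_count(exp.t_relax, nu)
        delta = exp.t_relax / npulse
        P = (V * np.exp(lam * (delta / 2.0))) @ Vinv
        A = P @ np.conj(P)
        U = A @ np.conj(A)
        m = np.linalg.matrix_power(U, npulse // 2) @ m0
        intensity = abs(m[obs_idx])
        r2_eff[k] = -np.log(intensity / i0) / exp.t_relax
    return CPMGProfile(experiment=exp, site_id="", r2_eff=r2_eff)
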