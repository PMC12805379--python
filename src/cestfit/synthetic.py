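"""Synthetic CEST/CPMG dataset generation for the built-in study scenarios.

The generator emulates four study conditions:

* ``abc_cpmg`` / ``abc_cest`` -- a linear three-state A <-> B <-> C process
  (kex_AB = 300 s^-1, kex_BC = 5000 s^-1, pB = 2.5%, pC = 0.25%,
  R1 = 1 s^-1, R2 = 10 s^-1) probed at 58 15N sites whose (dw_AB, dw_AC)
  combinations are drawn by a documented surrogate sampler; CPMG at 11.7 and
  18.8 T (T_relax = 20 ms) and CEST at 18.8 T (17 Hz/450 ms, 35 Hz/400 ms).
* ``t4l_cest_11p5C`` -- an experiment-like triangular E/B/I dataset with the
  best-fit kinetics (kex_EB = 297, kex_EI = 170, kex_BI = 1667 s^-1,
  pB = 1.5%, pI = 0.22%) and the measured B1 ladders at 16.4 T.
* ``t4l_tfe`` -- the TFE-perturbed variant (kex_BI = 4000 s^-1, pB = 2.2%,
  pI = 1.8%).
* ``urea_series`` -- a titration at [urea] = 0..3 M in which state and
  barrier free energies shift linearly with the reported m-values.

Gaussian noise (default sigma(I/I0) = 0.005, sigma(R2_eff) = 0.3 s^-1) is
added per point and attached as the uncertainty; all randomness flows from
the scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Tuple, Union

import numpy as np

from .models import Topology
from .spin_dynamics import (
    CESTExperiment,
    CPMGExperiment,
    ExchangeModel,
    SpinSystem,
    simulate_cest_profile,
    simulate_cpmg_profile,
)
from .thermo import (
    free_energy_offsets,
    model_from_free_energies,
    transition_state_energies,
)
from .constants import DEFAULT_TEMPERATURE_K

__all__ = [
    "ScenarioConfig",
    "SCENARIO_NAMES",
    "DEFAULT_SIGMA_CEST",
    "DEFAULT_SIGMA_CPMG",
    "sample_shift_set",
    "generate_scenario",
    "builtin_scenarios",
    "scenario_guesses",
]

DEFAULT_SIGMA_CEST = 0.005
DEFAULT_SIGMA_CPMG = 0.3

SCENARIO_NAMES = ("abc_cpmg", "abc_cest", "t4l_cest_11p5C", "t4l_tfe", "urea_series")

Experiment = Union[CESTExperiment, CPMGExperiment]


@dataclass
class ScenarioConfig:
    """Everything needed to generate one synthetic dataset."""

    name: str
    model: ExchangeModel
    sites: List[Tuple[str, SpinSystem]]
    experiments: List[Tuple[str, Experiment]]  # (nucleus, experiment)
    sigma_cest: float = DEFAULT_SIGMA_CEST
    sigma_cpmg: float = DEFAULT_SIGMA_CPMG
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_cest < 0 or self.sigma_cpmg < 0:
            raise ValueError("noise levels must be non-negative")
        site_nuclei = {spin.nucleus for _, spin in self.sites}
        for nucleus, _ in self.experiments:
            if nucleus not in site_nuclei:
                raise ValueError(
                    f"experiment nucleus {nucleus!r} has no matching site"
                )


def sample_shift_set(
    n_sites: int,
    ranges: Tuple[Tuple[float, float], Tuple[float, float]] = ((1.0, 6.0), (2.0, 6.0)),
    seed: int = 0,
) -> List[Tuple[float, float]]:
    """Surrogate sampler for the 58-site (dw_AB, dw_AC) shift combinations.

    The original table comes from two folding intermediates of the same
    domain, whose shifts from the native state are strongly correlated: the
    minor-minor separation dw_BC = dw_AC - dw_AB is small at most sites with
    a broad-tail minority.  The surrogate draws |dw_AB| uniformly in
    ``ranges[0]`` with a random sign, and dw_BC from a mixture: normal with
    1 ppm standard deviation (75%) or a uniform tail over ``ranges[1]`` ppm
    with a random sign (25%).  At least 20% of sites are guaranteed to have
    |dw_BC| > 2 ppm (resampled from the tail if necessary) whenever the
    ranges make that possible, preserving the minor-dip broadening
    signature.  Collapsing a range to a point pins the corresponding
    magnitude.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    (lo1, hi1), (lo2, hi2) = ranges
    if hi1 < lo1 or hi2 < lo2 or lo1 < 0 or lo2 < 0:
        raise ValueError(f"invalid ppm ranges: {ranges}")
    rng = np.random.default_rng(seed)

    def draw_tail() -> float:
        return float(rng.uniform(lo2, hi2) * rng.choice([-1.0, 1.0]))

    def draw() -> Tuple[float, float]:
        a = float(rng.uniform(lo1, hi1) * rng.choice([-1.0, 1.0]))
        bc = float(rng.normal(0.0, 1.0)) if rng.random() < 0.75 else draw_tail()
        return (a, a + bc)

    pairs = [draw() for _ in range(n_sites)]
    achievable = hi2 > 2.0
    if achievable:
        need = int(np.ceil(0.2 * n_sites))
        for _ in range(1000):
            spread = [abs(c - a) > 2.0 for a, c in pairs]
            if sum(spread) >= need:
                break
            idx = spread.index(False)
            pairs[idx] = (pairs[idx][0], pairs[idx][0] + draw_tail())
    return pairs


def generate_scenario(config: ScenarioConfig):
    """Simulate all profiles of a scenario and add seeded Gaussian noise.

    Returns a :class:`~cestfit.fitting.Dataset`.  When a noise sigma is
    zero the values are the noiseless simulation; the attached per-point
    uncertainty is then the package default (so the dataset stays usable
    for weighted fitting).
    """
    from .fitting import Dataset  # local import to avoid a cycle

    rng = np.random.default_rng(config.seed)
    data = Dataset(nuclei={})
    for site_id, spin in config.sites:
        data.nuclei[site_id] = spin.nucleus
        for nucleus, exp in config.experiments:
            if nucleus != spin.nucleus:
                continue
            if isinstance(exp, CESTExperiment):
                prof = simulate_cest_profile(config.model, spin, exp)
                sigma = config.sigma_cest
                noisy = prof.intensity_ratio + rng.normal(
                    0.0, sigma, size=len(prof.intensity_ratio)
                )
                attach = sigma if sigma > 0 else DEFAULT_SIGMA_CEST
                data.cest.append(
                    replace(
                        prof,
                        site_id=site_id,
                        intensity_ratio=noisy,
                        sigma=np.full(len(noisy), attach),
                    )
                )
            else:
                prof = simulate_cpmg_profile(config.model, spin, exp)
                sigma = config.sigma_cpmg
                noisy = prof.r2_eff + rng.normal(0.0, sigma, size=len(prof.r2_eff))
                attach = sigma if sigma > 0 else DEFAULT_SIGMA_CPMG
                data.cpmg.append(
                    replace(
                        prof,
                        site_id=site_id,
                        r2_eff=noisy,
                        sigma=np.full(len(noisy), attach),
                    )
                )
    return data


# ---------------------------------------------------------------------------
# built-in scenarios


def _abc_model() -> ExchangeModel:
    return ExchangeModel(
        states=("A", "B", "C"),
        populations=(0.9725, 0.025, 0.0025),
        kex={("A", "B"): 300.0, ("B", "C"): 5000.0},
        topology=Topology.LINEAR_OFF_PATHWAY,
    )


def _abc_sites(n_sites: int, seed: int) -> List[Tuple[str, SpinSystem]]:
    pairs = sample_shift_set(n_sites, seed=seed)
    sites = []
    for i, (dw_ab, dw_ac) in enumerate(pairs):
        spin = SpinSystem(
            nucleus="N15",
            shifts={"A": 0.0, "B": dw_ab, "C": dw_ac},
            r1={s: 1.0 for s in "ABC"},
            r2={s: 10.0 for s in "ABC"},
        )
        sites.append((f"s{i:02d}", spin))
    return sites


_CPMG_NU_GRID = np.arange(50.0, 1001.0, 50.0)


def _cest_grid(
    b0: float, b1: float, t_ex: float, nucleus: str, span: float, step: float
) -> CESTExperiment:
    offsets_ppm = np.arange(-span, span + step / 2, step)
    return CESTExperiment.from_ppm(
        b0=b0, b1=b1, t_ex=t_ex, offsets_ppm=offsets_ppm, nucleus=nucleus
    )


def _t4l_model(
    p_b: float = 0.015,
    p_i: float = 0.0022,
    kex_eb: float = 297.0,
    kex_ei: float = 170.0,
    kex_bi: float = 1667.0,
) -> ExchangeModel:
    return ExchangeModel(
        states=("E", "B", "I"),
        populations=(1.0 - p_b - p_i, p_b, p_i),
        kex={("E", "B"): kex_eb, ("E", "I"): kex_ei, ("B", "I"): kex_bi},
        topology=Topology.TRIANGULAR,
    )


def _t4l_sites(
    n_n15: int, n_c13: int, seed: int
) -> List[Tuple[str, SpinSystem]]:
    """Representative amide 15N and methyl 13C sites for the E/B/I scenarios.

    dw_EB magnitudes span the experimentally typical ranges (1-6 ppm 15N,
    0.5-3 ppm 13C); dw_BI spans +-3 ppm with |dw_BI| >= 0.5 ppm at half the
    sites so the B-dip broadening signature is present.
    """
    rng = np.random.default_rng(seed)
    sites = []
    specs = [("N15", 1.0, 6.0)] * n_n15 + [("C13", 0.5, 3.0)] * n_c13
    for i, (nucleus, lo, hi) in enumerate(specs):
        dw_eb = rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])
        if i % 2 == 0:
            dw_bi = rng.uniform(0.5, 3.0) * rng.choice([-1.0, 1.0])
        else:
            dw_bi = rng.uniform(-0.5, 0.5)
        r2 = 12.0 if nucleus == "N15" else 8.0
        r1 = 1.0 if nucleus == "N15" else 1.5
        spin = SpinSystem(
            nucleus=nucleus,
            shifts={"E": 0.0, "B": dw_eb, "I": dw_eb + dw_bi},
            r1={s: r1 for s in "EBI"},
            r2={s: r2 for s in "EBI"},
        )
        prefix = "n" if nucleus == "N15" else "c"
        sites.append((f"{prefix}{i:02d}", spin))
    return sites


_T4L_B1_N15 = (18.1, 33.2, 51.8, 72.6, 129.6)
_T4L_B1_C13 = (16.2, 32.4, 49.1, 98.2)
_T4L_B0 = 16.4
_T4L_T_EX = 0.5

#: Urea response of the E/B/I landscape: m-values in kJ/mol/M for states
#: B and I and the three barriers (slope of dG is -m).
_UREA_M_VALUES = {
    "B": -0.4,
    "I": 0.4,
    frozenset(("E", "B")): 0.4,
    frozenset(("B", "I")): 1.2,
    frozenset(("E", "I")): -0.2,
}
_UREA_CONCENTRATIONS = (0.0, 1.0, 2.0, 3.0)


def _t4l_experiments(
    n15: bool = True, c13: bool = True, b1_subset: Optional[int] = None
) -> List[Tuple[str, Experiment]]:
    exps: List[Tuple[str, Experiment]] = []
    if n15:
        for b1 in _T4L_B1_N15[:b1_subset]:
            exps.append(
                ("N15", _cest_grid(_T4L_B0, b1, _T4L_T_EX, "N15", span=7.0, step=0.25))
            )
    if c13:
        for b1 in _T4L_B1_C13[:b1_subset]:
            exps.append(
                ("C13", _cest_grid(_T4L_B0, b1, _T4L_T_EX, "C13", span=4.0, step=0.15))
            )
    return exps


def _urea_configs(seed: int, n_sites: Optional[int]) -> List[ScenarioConfig]:
    base = _t4l_model()
    temperature = DEFAULT_TEMPERATURE_K
    dg0 = free_energy_offsets(base, temperature)
    ts0 = transition_state_energies(base, temperature)
    n15 = n_sites if n_sites is not None else 11
    sites = _t4l_sites(n15, 0, seed=seed + 17)
    configs = []
    for j, conc in enumerate(_UREA_CONCENTRATIONS):
        dg = {s: dg0[s] - _UREA_M_VALUES.get(s, 0.0) * conc for s in base.states}
        ts = {
            key: g - _UREA_M_VALUES[frozenset(key)] * conc for key, g in ts0.items()
        }
        model = model_from_free_energies(
            base.states, dg, ts, Topology.TRIANGULAR, temperature
        )
        configs.append(
            ScenarioConfig(
                name=f"urea_{conc:g}M",
                model=model,
                sites=sites,
                experiments=_t4l_experiments(n15=True, c13=False),
                seed=seed + j,
            )
        )
    return configs


def builtin_scenarios(
    name: str, seed: int = 0, n_sites: Optional[int] = None
) -> Union[ScenarioConfig, List[ScenarioConfig]]:
    """Fully populated configuration(s) for a named built-in scenario.

    ``urea_series`` returns a list of per-concentration configurations; all
    other names return a single :class:`ScenarioConfig`.  ``n_sites``
    optionally reduces the site count (Fig-1 scenarios default to 58; the
    experiment-like scenarios to 11 15N + 4 13C sites).
    """
    if name == "abc_cpmg":
        n = n_sites if n_sites is not None else 58
        return ScenarioConfig(
            name=name,
            model=_abc_model(),
            sites=_abc_sites(n, seed),
            experiments=[
                ("N15", CPMGExperiment(b0=11.7, t_relax=0.02, nu_cpmg=_CPMG_NU_GRID)),
                ("N15", CPMGExperiment(b0=18.8, t_relax=0.02, nu_cpmg=_CPMG_NU_GRID)),
            ],
            seed=seed,
        )
    if name == "abc_cest":
        n = n_sites if n_sites is not None else 58
        return ScenarioConfig(
            name=name,
            model=_abc_model(),
            sites=_abc_sites(n, seed),
            experiments=[
                ("N15", _cest_grid(18.8, 17.0, 0.45, "N15", span=7.0, step=0.25)),
                ("N15", _cest_grid(18.8, 35.0, 0.40, "N15", span=7.0, step=0.25)),
            ],
            seed=seed,
        )
    if name == "t4l_cest_11p5C":
        n15, c13 = (11, 4) if n_sites is None else (max(n_sites - n_sites // 4, 1), n_sites // 4)
        return ScenarioConfig(
            name=name,
            model=_t4l_model(),
            sites=_t4l_sites(n15, c13, seed),
            experiments=_t4l_experiments(),
            seed=seed,
        )
    if name == "t4l_tfe":
        n15, c13 = (11, 4) if n_sites is None else (max(n_sites - n_sites // 4, 1), n_sites // 4)
        return ScenarioConfig(
            name=name,
            model=_t4l_model(p_b=0.022, p_i=0.018, kex_bi=4000.0),
            sites=_t4l_sites(n15, c13, seed),
            experiments=_t4l_experiments(),
            seed=seed,
        )
    if name == "urea_series":
        return _urea_configs(seed, n_sites)
    raise ValueError(f"unknown scenario {name!r}; options: {', '.join(SCENARIO_NAMES)}")


def scenario_guesses(config: ScenarioConfig) -> Dict[str, Dict[str, float]]:
    """Fit initialization from the generating truth of a scenario.

    Mirrors the practice of starting fits from assigned dip positions: the
    major-state shift and the minor-dip position are taken as known, as are
    ballpark relaxation rates.
    """
    out: Dict[str, Dict[str, float]] = {}
    states = config.model.states
    for site_id, spin in config.sites:
        major = states[0]
        g = {
            "w": spin.shifts[major],
            "dw1": spin.shifts[states[1]] - spin.shifts[major],
            "r2": spin.r2[major],
            "r1": spin.r1[major],
        }
        if len(states) > 2:
            g["dw12"] = spin.shifts[states[2]] - spin.shifts[states[1]]
        out[site_id] = g
    return out
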