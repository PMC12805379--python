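"""Global least-squares fitting of CEST/CPMG datasets to exchange models.

A :class:`FitProblem` maps a :class:`~cestfit.models.ModelSpec` plus a
:class:`Dataset` onto a bounded trust-region least-squares problem:

* shared kinetic parameters (minor-state populations as log-ratios to the
  major state, pairwise kex on a log scale) are common to all sites;
* per-site parameters (major-state shift, shift differences, R2, R1) touch
  only that site's residuals, which makes the Jacobian block-sparse --
  exploited through grouped finite differences (``jac_sparsity``).

Residuals are weighted by the per-point uncertainties, so the objective is
the usual chi-square; CEST and CPMG points enter one joint chi-square when
fit together.  Multi-start optimization (log-uniform restarts of the
kinetic parameters) guards against label switching and local minima.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import scipy.optimize
import scipy.sparse

from .models import ModelSpec, Topology, build_model
from .spin_dynamics import (
    CESTProfile,
    CPMGProfile,
    ExchangeModel,
    SpinSystem,
    simulate_cest_profile,
    simulate_cpmg_profile,
)
from .thermo import phi_indirect

logger = logging.getLogger(__name__)

__all__ = [
    "Dataset",
    "StartConfig",
    "FitResult",
    "ScanCurve",
    "BootstrapResult",
    "FitError",
    "chi2_reduced",
    "fit_global",
    "compare_models",
    "scan_kex",
    "bootstrap_uncertainties",
    "guess_site_shifts",
]


class FitError(RuntimeError):
    """Raised when no optimization start converges."""


@dataclass
class Dataset:
    """CEST and/or CPMG profiles for a set of spin sites.

    ``nuclei`` registers the nucleus ("N15"/"C13") of every site_id that
    appears in the profiles.
    """

    cest: List[CESTProfile] = field(default_factory=list)
    cpmg: List[CPMGProfile] = field(default_factory=list)
    nuclei: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for prof in [*self.cest, *self.cpmg]:
            if prof.site_id not in self.nuclei:
                raise ValueError(f"site {prof.site_id!r} missing from nucleus registry")

    def sites(self) -> List[str]:
        seen: Dict[str, None] = {}
        for prof in [*self.cest, *self.cpmg]:
            seen.setdefault(prof.site_id, None)
        return list(seen)

    @property
    def n_points(self) -> int:
        return sum(len(p.intensity_ratio) for p in self.cest) + sum(
            len(p.r2_eff) for p in self.cpmg
        )

    def profiles_of(self, site: str):
        return (
            [p for p in self.cest if p.site_id == site],
            [p for p in self.cpmg if p.site_id == site],
        )


@dataclass
class StartConfig:
    """Multi-start configuration for :func:`fit_global`.

    ``init`` provides natural-unit initial values for the shared kinetic
    parameters (e.g. ``{"p_B": 0.02, "kex_EB": 300.0}``); the first start
    uses them, further starts draw kinetics log-uniformly within bounds.
    """

    n_starts: int = 10
    init: Optional[Dict[str, float]] = None


@dataclass
class FitResult:
    """Best-fit parameters and diagnostics of a global fit."""

    spec: ModelSpec
    best_values: Dict[str, float]
    chi2_red: float
    n_data: int
    n_params: int
    per_site_shifts: Dict[str, Dict[str, float]]
    per_site_r2: Dict[str, Dict[str, float]]
    per_site_r1: Dict[str, float]
    uncertainties: Dict[str, float]
    convergence: Dict[str, object]

    @property
    def model(self) -> ExchangeModel:
        """Exchange model built from the best-fit kinetic parameters."""
        return build_model(self.spec, self.best_values)


@dataclass
class ScanCurve:
    """Profile of chi2_red and phi_I along a fixed-kex_EI grid."""

    grid: np.ndarray
    chi2_red: np.ndarray
    phi_i: np.ndarray
    ok: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.chi2_red = np.asarray(self.chi2_red, dtype=float)
        self.phi_i = np.asarray(self.phi_i, dtype=float)
        self.ok = np.asarray(self.ok, dtype=bool)
        if not len(self.grid) == len(self.chi2_red) == len(self.phi_i) == len(self.ok):
            raise ValueError("scan arrays must have equal lengths")


@dataclass
class BootstrapResult:
    """Empirical distributions of shared kinetic parameters."""

    samples: Dict[str, np.ndarray]
    intervals: Dict[str, Tuple[float, float]]
    n_trials: int
    n_failed: int


def chi2_reduced(
    data: Dataset,
    simulated: Sequence[np.ndarray],
    n_params: int,
) -> float:
    """Reduced chi-square of simulated observables against a dataset.

    ``simulated`` must align one-to-one with ``data.cest + data.cpmg``.
    """
    profiles = [*data.cest, *data.cpmg]
    if len(simulated) != len(profiles):
        raise ValueError("simulated profiles must align with the dataset")
    chi2 = 0.0
    n = 0
    for prof, calc in zip(profiles, simulated):
        obs = prof.intensity_ratio if isinstance(prof, CESTProfile) else prof.r2_eff
        if prof.sigma is None:
            raise ValueError(f"profile for site {prof.site_id!r} has no uncertainties")
        calc = np.asarray(calc, dtype=float)
        if calc.shape != obs.shape:
            raise ValueError("simulated points must align one-to-one with data")
        chi2 += float(np.sum(((obs - calc) / prof.sigma) ** 2))
        n += len(obs)
    if n <= n_params:
        raise ValueError(f"n_data = {n} <= n_params = {n_params}")
    return chi2 / (n - n_params)


def guess_site_shifts(data: Dataset, site: str) -> Dict[str, float]:
    """Dip-based initial shift guesses for one site.

    Uses the lowest-B1 CEST profile: the deepest dip initializes the
    major-state shift; the deepest local minimum outside an exclusion window
    around it initializes the first minor-state shift difference.  Sites
    without CEST data get a generic 2 ppm guess (CPMG dispersion amplitude
    constrains |dw| but carries no dip position).
    """
    cest, _ = data.profiles_of(site)
    if not cest:
        return {"w": 0.0, "dw1": 2.0}
    prof = min(cest, key=lambda p: p.experiment.b1)
    nucleus = data.nuclei[site]
    ppm = prof.experiment.offsets_ppm(nucleus)
    y = prof.intensity_ratio
    w = float(ppm[np.argmin(y)])
    hz_per_ppm = prof.experiment.offsets[-1] / (ppm[-1] - prof.experiment.carrier_ref)
    window = max(2.0 * prof.experiment.b1 / abs(hz_per_ppm), 0.4)
    mask = np.abs(ppm - w) > window
    if np.any(mask):
        dip = float(ppm[mask][np.argmin(y[mask])])
        depth = 1.0 - float(np.min(y[mask]))
        dw1 = dip - w if depth > 0.01 else 2.0
    else:
        dw1 = 2.0
    return {"w": w, "dw1": dw1}


# ---------------------------------------------------------------------------
# internal parameter machinery


@dataclass
class _Param:
    name: str
    value: float  # natural units
    lo: float
    hi: float
    transform: str  # "lin" | "log" | "pop"
    site: Optional[str] = None
    vary: bool = True

    def to_x(self, value: float) -> float:
        if self.transform == "log":
            return np.log(value)
        if self.transform == "pop":
            return np.log(value / (1.0 - value))
        return value

    def from_x(self, x: float) -> float:
        if self.transform == "log":
            return float(np.exp(x))
        if self.transform == "pop":
            e = np.exp(x)
            return float(e / (1.0 + e))
        return float(x)

    def dvalue_dx(self, value: float) -> float:
        if self.transform == "log":
            return value
        if self.transform == "pop":
            return value * (1.0 - value)
        return 1.0


class FitProblem:
    """Weighted least-squares problem for one spec and one dataset."""

    R2_BOUNDS = (0.2, 400.0)
    R1_BOUNDS = (0.05, 20.0)

    def __init__(
        self,
        data: Dataset,
        spec: ModelSpec,
        guesses: Optional[Mapping[str, Mapping[str, float]]] = None,
        dw1_window: Optional[float] = None,
    ):
        self.data = data
        self.spec = spec
        self.dw1_window = dw1_window
        sites = data.sites()
        if not sites:
            raise ValueError("dataset is empty")
        unknown = sorted(set(spec.sign_constraints) - set(sites))
        if unknown:
            raise ValueError(f"sign constraints for unknown site(s): {unknown}")
        for prof in [*data.cest, *data.cpmg]:
            if prof.sigma is None:
                raise ValueError(
                    f"profile for site {prof.site_id!r} has no uncertainties"
                )
        self.params: Dict[str, _Param] = {}
        self._build_shared()
        self._build_per_site(guesses or {})
        self._index_rows()

    # -- construction -------------------------------------------------------

    def _add(self, p: _Param) -> None:
        self.params[p.name] = p

    def _build_shared(self) -> None:
        spec = self.spec
        p_lo, p_hi = spec.pop_bounds
        k_lo, k_hi = spec.kex_bounds
        default_p = {m: 0.02 / (1 + i) for i, m in enumerate(spec.minor_states)}
        for m in spec.minor_states:
            self._add(
                _Param(f"p_{m}", default_p[m], p_lo, p_hi, transform="pop")
            )
        for a, b in spec.edges:
            self._add(_Param(f"kex_{a}{b}", 500.0, k_lo, k_hi, transform="log"))

    def _build_per_site(self, guesses: Mapping[str, Mapping[str, float]]) -> None:
        spec = self.spec
        dw_lo, dw_hi = spec.dw_bounds
        m1 = spec.states[1]
        m2 = spec.states[2] if spec.n_states > 2 else None
        for site in self.data.sites():
            cest, _cpmg = self.data.profiles_of(site)
            g = dict(guess_site_shifts(self.data, site))
            g.update(guesses.get(site, {}))
            if cest:
                w0 = g["w"]
                self._add(
                    _Param(f"w@{site}", w0, w0 - 2.0, w0 + 2.0, "lin", site=site)
                )
            d_lo, d_hi = dw_lo, dw_hi
            if self.dw1_window is not None:
                # anchor the first minor-state shift near its assigned dip
                d_lo = max(d_lo, g["dw1"] - self.dw1_window)
                d_hi = min(d_hi, g["dw1"] + self.dw1_window)
            self._add(
                _Param(f"dw_{m1}@{site}", g["dw1"], d_lo, d_hi, "lin", site=site)
            )
            if m2 is not None:
                lo, hi = dw_lo, dw_hi
                sign = spec.sign_constraints.get(site)
                if sign == +1:
                    lo = 0.0
                elif sign == -1:
                    hi = 0.0
                dw12 = float(g.get("dw12", 0.25 if hi > 0 else -0.25))
                dw12 = min(max(dw12, lo), hi)
                self._add(
                    _Param(f"dw_{m1}{m2}@{site}", dw12, lo, hi, "lin", site=site)
                )
            r2_0 = float(g.get("r2", 12.0))
            self._add(_Param(f"r2@{site}", r2_0, *self.R2_BOUNDS, "log", site=site))
            if spec.r2_mode == "free_minor":
                self._add(
                    _Param(f"r2_{m1}@{site}", r2_0, *self.R2_BOUNDS, "log", site=site)
                )
            if cest:
                if spec.r1_mode == "fit":
                    r1_0 = float(g.get("r1", 1.0))
                    self._add(
                        _Param(f"r1@{site}", r1_0, *self.R1_BOUNDS, "log", site=site)
                    )

    def _index_rows(self) -> None:
        self._profiles: List[Tuple[str, object]] = []
        self._slices: List[slice] = []
        start = 0
        for prof in [*self.data.cest, *self.data.cpmg]:
            n = len(prof.intensity_ratio if isinstance(prof, CESTProfile) else prof.r2_eff)
            self._profiles.append((prof.site_id, prof))
            self._slices.append(slice(start, start + n))
            start += n
        self.n_rows = start

    # -- parameter vector helpers -------------------------------------------

    def free_names(self) -> List[str]:
        return [n for n, p in self.params.items() if p.vary]

    def x0(self) -> np.ndarray:
        return np.array([p.to_x(p.value) for p in self.params.values() if p.vary])

    def bounds(self) -> Tuple[np.ndarray, np.ndarray]:
        lo = []
        hi = []
        for p in self.params.values():
            if not p.vary:
                continue
            lo.append(p.to_x(p.lo) if p.lo > -np.inf else -np.inf)
            hi.append(p.to_x(p.hi) if p.hi < np.inf else np.inf)
        return np.array(lo), np.array(hi)

    def values_from_x(self, x: np.ndarray) -> Dict[str, float]:
        out = {}
        k = 0
        for name, p in self.params.items():
            if p.vary:
                out[name] = p.from_x(x[k])
                k += 1
            else:
                out[name] = p.value
        return out

    def set_values(self, values: Mapping[str, float]) -> None:
        for name, v in values.items():
            if name in self.params:
                p = self.params[name]
                p.value = float(min(max(v, p.lo), p.hi))

    def fix(self, name: str, value: Optional[float] = None) -> None:
        p = self.params[name]
        if value is not None:
            p.value = float(value)
        p.vary = False

    def release(self, name: str) -> None:
        self.params[name].vary = True

    @property
    def n_free(self) -> int:
        return sum(p.vary for p in self.params.values())

    # -- model evaluation ----------------------------------------------------

    def _spin_for(self, site: str, values: Mapping[str, float]) -> SpinSystem:
        spec = self.spec
        states = spec.states
        m1 = states[1]
        w = values.get(f"w@{site}", 0.0)
        shifts = {states[0]: w, m1: w + values[f"dw_{m1}@{site}"]}
        if spec.n_states > 2:
            m2 = states[2]
            shifts[m2] = shifts[m1] + values[f"dw_{m1}{m2}@{site}"]
        r2_major = values[f"r2@{site}"]
        r2 = {s: r2_major for s in states}
        if spec.r2_mode == "free_minor":
            r2[m1] = values[f"r2_{m1}@{site}"]
        r1_val = values.get(f"r1@{site}", spec.r1_value)
        r1 = {s: r1_val for s in states}
        return SpinSystem(
            nucleus=self.data.nuclei[site], shifts=shifts, r1=r1, r2=r2
        )

    def simulate(self, values: Mapping[str, float]) -> List[np.ndarray]:
        model = build_model(self.spec, values)
        spins = {site: self._spin_for(site, values) for site in self.data.sites()}
        out: List[np.ndarray] = []
        for site, prof in self._profiles:
            if isinstance(prof, CESTProfile):
                sim = simulate_cest_profile(model, spins[site], prof.experiment)
                out.append(sim.intensity_ratio)
            else:
                sim = simulate_cpmg_profile(model, spins[site], prof.experiment)
                out.append(sim.r2_eff)
        return out

    def residuals(self, x: np.ndarray) -> np.ndarray:
        values = self.values_from_x(x)
        res = np.empty(self.n_rows)
        try:
            sims = self.simulate(values)
        except Exception:  # pragma: no cover - pathological corner of space
            return np.full(self.n_rows, 1e6)
        for (site, prof), sl, calc in zip(self._profiles, self._slices, sims):
            obs = prof.intensity_ratio if isinstance(prof, CESTProfile) else prof.r2_eff
            res[sl] = (obs - calc) / prof.sigma
        if not np.all(np.isfinite(res)):
            res[~np.isfinite(res)] = 1e6
        return res

    def jac_sparsity(self) -> scipy.sparse.lil_matrix:
        names = self.free_names()
        S = scipy.sparse.lil_matrix((self.n_rows, len(names)), dtype=bool)
        col_site = [self.params[n].site for n in names]
        for j, site in enumerate(col_site):
            if site is None:
                S[:, j] = True
            else:
                for (psite, _), sl in zip(self._profiles, self._slices):
                    if psite == site:
                        S[sl, j] = True
        return S

    def solve(self, x0: Optional[np.ndarray] = None, max_nfev: Optional[int] = None):
        x0 = self.x0() if x0 is None else np.asarray(x0, dtype=float)
        lo, hi = self.bounds()
        x0 = np.clip(x0, lo + 1e-12, hi - 1e-12)
        return scipy.optimize.least_squares(
            self.residuals,
            x0,
            bounds=(lo, hi),
            method="trf",
            tr_solver="lsmr",
            jac_sparsity=self.jac_sparsity(),
            x_scale="jac",
            max_nfev=max_nfev,
        )


# ---------------------------------------------------------------------------
# public fitting API


def _random_kinetic_start(problem: FitProblem, rng: np.random.Generator) -> np.ndarray:
    """Start vector with kinetics drawn log-uniformly within bounds."""
    x = problem.x0().copy()
    k = 0
    for name, p in problem.params.items():
        if not p.vary:
            continue
        if p.site is None:
            if name.startswith("kex_"):
                v = np.exp(rng.uniform(np.log(p.lo), np.log(p.hi)))
                x[k] = p.to_x(v)
            elif name.startswith("p_"):
                v = np.exp(rng.uniform(np.log(p.lo), np.log(p.hi)))
                x[k] = p.to_x(v)
        k += 1
    return x


def _finish(problem: FitProblem, result) -> FitResult:
    values = problem.values_from_x(result.x)
    n_free = problem.n_free
    dof = problem.n_rows - n_free
    chi2 = float(np.sum(result.fun**2))
    chi2_red = chi2 / dof if dof > 0 else np.inf

    # linearized covariance -> natural-unit standard errors
    J = result.jac
    if scipy.sparse.issparse(J):
        J = J.toarray()
    uncertainties: Dict[str, float] = {}
    try:
        cov = np.linalg.pinv(J.T @ J)
        stderr_x = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        for name, se in zip(problem.free_names(), stderr_x):
            p = problem.params[name]
            uncertainties[name] = float(se * abs(p.dvalue_dx(values[name])))
    except np.linalg.LinAlgError:  # pragma: no cover
        pass

    spec = problem.spec
    states = spec.states
    m1 = states[1]
    per_site_shifts: Dict[str, Dict[str, float]] = {}
    per_site_r2: Dict[str, Dict[str, float]] = {}
    per_site_r1: Dict[str, float] = {}
    for site in problem.data.sites():
        w = values.get(f"w@{site}", 0.0)
        shifts = {states[0]: w, m1: w + values[f"dw_{m1}@{site}"]}
        if spec.n_states > 2:
            m2 = states[2]
            shifts[m2] = shifts[m1] + values[f"dw_{m1}{m2}@{site}"]
        per_site_shifts[site] = shifts
        r2 = {s: values[f"r2@{site}"] for s in states}
        if spec.r2_mode == "free_minor":
            r2[m1] = values[f"r2_{m1}@{site}"]
        per_site_r2[site] = r2
        if f"r1@{site}" in values:
            per_site_r1[site] = values[f"r1@{site}"]

    best = {k: v for k, v in values.items() if "@" not in k}
    p_major = 1.0 - sum(best[f"p_{m}"] for m in spec.minor_states)
    best[f"p_{states[0]}"] = p_major
    return FitResult(
        spec=spec,
        best_values={**best, **{k: v for k, v in values.items() if "@" in k}},
        chi2_red=chi2_red,
        n_data=problem.n_rows,
        n_params=n_free,
        per_site_shifts=per_site_shifts,
        per_site_r2=per_site_r2,
        per_site_r1=per_site_r1,
        uncertainties=uncertainties,
        convergence={
            "nfev": int(result.nfev),
            "status": int(result.status),
            "message": str(result.message),
        },
    )


def fit_global(
    data: Dataset,
    spec: ModelSpec,
    starts: Optional[StartConfig] = None,
    seed: int = 0,
    guesses: Optional[Mapping[str, Mapping[str, float]]] = None,
    dw1_window: Optional[float] = None,
    fixed: Optional[Mapping[str, float]] = None,
) -> FitResult:
    """Fit a model spec to a dataset; deterministic given seed and starts.

    ``fixed`` pins named parameters (shared or per-site, e.g. ``dw_B@s01``)
    at given values; a titration analysis uses this to hold chemical shifts
    at their reference-condition assignments.  The best of all starts by
    chi-square wins; ties are broken by the lower total kex.  Raises
    :class:`FitError` with per-start diagnostics if no start converges.
    """
    starts = starts or StartConfig()
    problem = FitProblem(data, spec, guesses=guesses, dw1_window=dw1_window)
    if starts.init:
        problem.set_values(starts.init)
    if fixed:
        for name, value in fixed.items():
            if name in problem.params:
                problem.fix(name, value)
    rng = np.random.default_rng(seed)
    attempts = []
    diagnostics = []
    for s in range(max(starts.n_starts, 1)):
        x0 = problem.x0() if s == 0 else _random_kinetic_start(problem, rng)
        try:
            res = problem.solve(x0)
        except Exception as exc:  # keep going; other starts may converge
            diagnostics.append(f"start {s}: {exc!r}")
            continue
        if res.status <= 0:
            diagnostics.append(f"start {s}: status {res.status} ({res.message})")
            continue
        chi2 = float(np.sum(res.fun**2))
        vals = problem.values_from_x(res.x)
        total_kex = sum(v for k, v in vals.items() if k.startswith("kex_"))
        attempts.append((chi2, total_kex, s, res))
        logger.debug("start %d: chi2 = %.6g", s, chi2)
    if not attempts:
        raise FitError("no start converged:\n" + "\n".join(diagnostics))
    attempts.sort(key=lambda t: (round(t[0], 9), t[1], t[2]))
    chi2, _, s_best, res = attempts[0]
    fit = _finish(problem, res)
    fit.convergence["n_starts"] = max(starts.n_starts, 1)
    fit.convergence["n_converged"] = len(attempts)
    fit.convergence["best_start"] = s_best
    fit.convergence["start_chi2"] = sorted(a[0] for a in attempts)
    logger.info(
        "fit %s: chi2_red = %.4g (%d/%d starts converged)",
        spec.topology.value,
        fit.chi2_red,
        len(attempts),
        max(starts.n_starts, 1),
    )
    return fit


def compare_models(
    data: Dataset,
    specs: Sequence[ModelSpec],
    seed: int = 0,
    starts: Optional[StartConfig] = None,
    guesses: Optional[Mapping[str, Mapping[str, float]]] = None,
    inits: Optional[Sequence[Optional[Dict[str, float]]]] = None,
) -> List[FitResult]:
    """Fit each spec and return results ranked by chi2_red (best first).

    Fit failures for individual specs are reported as placeholder results
    with infinite chi2_red rather than aborting the comparison.
    """
    if len(specs) < 2:
        raise ValueError("need at least two specs to compare")
    results: List[FitResult] = []
    for i, spec in enumerate(specs):
        st = starts or StartConfig()
        if inits is not None and inits[i] is not None:
            st = replace(st, init=inits[i])
        try:
            results.append(fit_global(data, spec, starts=st, seed=seed, guesses=guesses))
        except FitError as exc:
            results.append(
                FitResult(
                    spec=spec,
                    best_values={},
                    chi2_red=np.inf,
                    n_data=data.n_points,
                    n_params=0,
                    per_site_shifts={},
                    per_site_r2={},
                    per_site_r1={},
                    uncertainties={},
                    convergence={"error": str(exc)},
                )
            )
    return sorted(results, key=lambda r: r.chi2_red)


def scan_kex(
    data: Dataset,
    spec: ModelSpec,
    grid: Sequence[float],
    seed: int = 0,
    starts: Optional[StartConfig] = None,
    guesses: Optional[Mapping[str, Mapping[str, float]]] = None,
    dw1_window: Optional[float] = None,
) -> ScanCurve:
    """chi2_red and phi_I as a function of a fixed kex between the major
    state and the second minor state (kex_EI in the triangular scheme).

    Each grid point re-fits all remaining parameters, warm-started from the
    previous point; failed points are flagged and the scan continues.
    """
    grid = np.asarray(grid, dtype=float)
    if len(grid) < 3 or np.any(grid <= 0):
        raise ValueError("grid must contain >= 3 positive values")
    if spec.topology is not Topology.TRIANGULAR:
        raise ValueError("kex scan requires the triangular topology")
    scanned = f"kex_{spec.states[0]}{spec.states[2]}"

    base = fit_global(
        data, spec, starts=starts, seed=seed, guesses=guesses, dw1_window=dw1_window
    )
    problem = FitProblem(data, spec, guesses=guesses, dw1_window=dw1_window)
    problem.set_values(base.best_values)
    chi2 = np.full(len(grid), np.nan)
    phi = np.full(len(grid), np.nan)
    ok = np.zeros(len(grid), dtype=bool)
    order = np.argsort(np.abs(np.log(grid / base.best_values[scanned])))
    warm: Dict[int, Dict[str, float]] = {}
    for idx in order:
        problem.set_values(base.best_values)
        # warm start from the nearest already-solved grid point
        solved = [j for j in warm if ok[j]]
        if solved:
            nearest = min(solved, key=lambda j: abs(np.log(grid[j] / grid[idx])))
            problem.set_values(warm[nearest])
        problem.fix(scanned, float(grid[idx]))
        try:
            res = problem.solve()
            if res.status <= 0:
                raise FitError(res.message)
            values = problem.values_from_x(res.x)
            dof = problem.n_rows - problem.n_free
            chi2[idx] = float(np.sum(res.fun**2)) / dof
            phi[idx] = phi_indirect(build_model(spec, values))
            warm[idx] = values
            ok[idx] = True
        except Exception as exc:
            logger.warning("scan point kex = %g failed: %s", grid[idx], exc)
        finally:
            problem.release(scanned)
    return ScanCurve(grid=grid, chi2_red=chi2, phi_i=phi, ok=ok)


def bootstrap_uncertainties(
    data: Dataset,
    spec: ModelSpec,
    n_trials: int,
    seed: int = 0,
    starts: Optional[StartConfig] = None,
    guesses: Optional[Mapping[str, Mapping[str, float]]] = None,
    base_fit: Optional[FitResult] = None,
    dw1_window: Optional[float] = None,
) -> BootstrapResult:
    """Site-level bootstrap of the shared kinetic parameters.

    Sites are resampled with replacement; each trial keeps all profiles of
    the chosen sites (a duplicated site becomes an independent copy with its
    own per-site parameters), preserving within-profile correlation.  Refits
    are warm-started from the full-data best fit.  Returns empirical
    distributions and central 68% intervals; reproducible given the seed.
    """
    if n_trials < 2:
        raise ValueError("n_trials must be >= 2")
    rng = np.random.default_rng(seed)
    if base_fit is None:
        base_fit = fit_global(
            data, spec, starts=starts, seed=seed, guesses=guesses, dw1_window=dw1_window
        )
    sites = data.sites()
    kin_names = list(spec.kinetic_param_names())
    samples: Dict[str, List[float]] = {k: [] for k in kin_names}
    n_failed = 0
    for _trial in range(n_trials):
        chosen = rng.choice(len(sites), size=len(sites), replace=True)
        boot = Dataset(nuclei={})
        boot_guesses: Dict[str, Dict[str, float]] = {}
        warm: Dict[str, float] = {
            k: v for k, v in base_fit.best_values.items() if "@" not in k
        }
        counts: Dict[str, int] = {}
        boot_signs: Dict[str, int] = {}
        for i in chosen:
            site = sites[i]
            counts[site] = counts.get(site, 0) + 1
            new_id = site if counts[site] == 1 else f"{site}#{counts[site]}"
            boot.nuclei[new_id] = data.nuclei[site]
            if site in spec.sign_constraints:
                boot_signs[new_id] = spec.sign_constraints[site]
            cest, cpmg = data.profiles_of(site)
            for p in cest:
                boot.cest.append(replace(p, site_id=new_id))
            for p in cpmg:
                boot.cpmg.append(replace(p, site_id=new_id))
            if guesses and site in guesses:
                boot_guesses[new_id] = dict(guesses[site])
            for name, v in base_fit.best_values.items():
                if name.endswith(f"@{site}"):
                    warm[name.replace(f"@{site}", f"@{new_id}")] = v
        try:
            trial_spec = replace(spec, sign_constraints=boot_signs)
            problem = FitProblem(
                boot, trial_spec, guesses=boot_guesses, dw1_window=dw1_window
            )
            problem.set_values(warm)
            res = problem.solve()
            if res.status <= 0:
                raise FitError(res.message)
            values = problem.values_from_x(res.x)
            for k in kin_names:
                samples[k].append(values[k])
        except Exception as exc:
            logger.warning("bootstrap trial failed: %s", exc)
            n_failed += 1
    if n_failed > 0.2 * n_trials:
        raise FitError(f"{n_failed}/{n_trials} bootstrap trials failed")
    arrays = {k: np.asarray(v) for k, v in samples.items()}
    intervals = {
        k: (float(np.percentile(v, 16)), float(np.percentile(v, 84)))
        for k, v in arrays.items()
    }
    return BootstrapResult(
        samples=arrays, intervals=intervals, n_trials=n_trials, n_failed=n_failed
    )
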