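"""Exchange topologies and the mapping from fit parameters to models.

Five connectivity schemes between a major state E and minor states B and I
are supported (state labels are configurable; the defaults follow the
E/B/I naming and the positional convention major, first minor, second minor):

* ``two_state``            E <-> B
* ``triangular``           E <-> B, E <-> I, B <-> I
* ``linear_on_pathway``    E <-> I <-> B   (I on the E-to-B pathway)
* ``linear_off_pathway``   E <-> B <-> I   (I off-pathway)
* ``bifurcated``           I <-> E <-> B   (independent exchange with E)

Fits are parameterized by (populations, pairwise kex) with detailed balance
imposed, which guarantees thermodynamic consistency on the triangular cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Mapping, Optional, Tuple

from .spin_dynamics import ExchangeModel, InvalidModelError, Topology

__all__ = ["Topology", "ModelSpec", "TOPOLOGY_EDGES", "build_model", "apply_sign_constraints"]

#: Connected pairs per topology, as indices into (major, minor1, minor2).
TOPOLOGY_EDGES: Dict[Topology, Tuple[Tuple[int, int], ...]] = {
    Topology.TWO_STATE: ((0, 1),),
    Topology.TRIANGULAR: ((0, 1), (0, 2), (1, 2)),
    Topology.LINEAR_ON_PATHWAY: ((0, 2), (1, 2)),
    Topology.LINEAR_OFF_PATHWAY: ((0, 1), (1, 2)),
    Topology.BIFURCATED: ((0, 1), (0, 2)),
}


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of an exchange-fit model.

    Attributes
    ----------
    topology:
        One of the five supported schemes.
    states:
        State labels, major first.  Two-state topologies use the first two.
    r2_mode:
        ``"tied"`` (R2 equal across states, one parameter per site) or
        ``"free_minor"`` (independent R2 for the minor state; the telltale
        diagnostic for unmodelled extra states in two-state fits).
    r1_mode / r1_value:
        ``"fit"`` fits one R1 per site tied across states; ``"fixed"`` pins
        it to ``r1_value``.  Minor-state R1 is never independently varied.
    sign_constraints:
        Map site_id -> +1/-1 constraining the sign of the chemical-shift
        difference between the two minor states at that site (one-sided
        parameter bound during fitting).
    kex_bounds, pop_bounds, dw_bounds:
        Box bounds for rate constants (s^-1), minor-state populations and
        shift differences (ppm).
    """

    topology: Topology
    states: Tuple[str, ...] = ("E", "B", "I")
    r2_mode: str = "tied"
    r1_mode: str = "fit"
    r1_value: float = 1.0
    sign_constraints: Mapping[str, int] = field(default_factory=dict)
    kex_bounds: Tuple[float, float] = (10.0, 2.0e4)
    pop_bounds: Tuple[float, float] = (1.0e-4, 0.2)
    dw_bounds: Tuple[float, float] = (-12.0, 12.0)

    def __post_init__(self) -> None:
        topo = Topology(self.topology)
        object.__setattr__(self, "topology", topo)
        n_needed = 2 if topo is Topology.TWO_STATE else 3
        if len(self.states) < n_needed:
            raise ValueError(f"{topo.value} needs {n_needed} state labels")
        object.__setattr__(self, "states", tuple(self.states)[:n_needed])
        if self.r2_mode not in ("tied", "free_minor"):
            raise ValueError(f"unknown r2_mode {self.r2_mode!r}")
        if self.r1_mode not in ("fit", "fixed"):
            raise ValueError(f"unknown r1_mode {self.r1_mode!r}")
        for sign in dict(self.sign_constraints).values():
            if sign not in (+1, -1):
                raise ValueError("sign constraints must be +1 or -1")

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def minor_states(self) -> Tuple[str, ...]:
        return self.states[1:]

    @property
    def edges(self) -> Tuple[Tuple[str, str], ...]:
        return tuple(
            (self.states[i], self.states[j]) for i, j in TOPOLOGY_EDGES[self.topology]
        )

    def kinetic_param_names(self) -> Tuple[str, ...]:
        """Names of the shared kinetic parameters, e.g. p_B, kex_EB."""
        names = [f"p_{s}" for s in self.minor_states]
        names += [f"kex_{a}{b}" for a, b in self.edges]
        return tuple(names)


def build_model(spec: ModelSpec, values: Mapping[str, float]) -> ExchangeModel:
    """Construct a validated :class:`ExchangeModel` from named values.

    ``values`` must provide ``p_<minor>`` for every minor state and
    ``kex_<a><b>`` for every connected pair; the major-state population is
    the simplex remainder.  Topology edges absent from the scheme get both
    microscopic rates exactly zero (they carry no kex parameter at all).
    """
    missing = [k for k in spec.kinetic_param_names() if k not in values]
    if missing:
        raise InvalidModelError(f"missing parameter(s): {missing}")
    pops_minor = []
    for s in spec.minor_states:
        p = float(values[f"p_{s}"])
        if not 0.0 < p < 1.0:
            raise InvalidModelError(f"population p_{s} = {p} outside (0, 1)")
        pops_minor.append(p)
    p_major = 1.0 - sum(pops_minor)
    if p_major <= 0.0:
        raise InvalidModelError(
            f"minor populations sum to {sum(pops_minor)}; simplex violated"
        )
    kex = {}
    for a, b in spec.edges:
        k = float(values[f"kex_{a}{b}"])
        if k < 0:
            raise InvalidModelError(f"kex_{a}{b} = {k} is negative")
        kex[(a, b)] = k
    return ExchangeModel(
        states=spec.states,
        populations=(p_major, *pops_minor),
        kex=kex,
        topology=spec.topology,
    )


def apply_sign_constraints(
    spec: ModelSpec,
    site_signs: Mapping[str, int],
    known_sites: Optional[Iterable[str]] = None,
) -> ModelSpec:
    """Return a spec whose minor-minor shift difference is sign-bounded.

    ``site_signs`` maps site ids to +1 (difference >= 0) or -1 (<= 0).  When
    ``known_sites`` is given, signs for unknown sites raise an error; the
    same validation also happens when the spec meets a dataset during
    fitting.
    """
    if known_sites is not None:
        unknown = sorted(set(site_signs) - set(known_sites))
        if unknown:
            raise ValueError(f"sign constraints for unknown site(s): {unknown}")
    merged = dict(spec.sign_constraints)
    merged.update({site: int(s) for site, s in site_signs.items()})
    return replace(spec, sign_constraints=merged)
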