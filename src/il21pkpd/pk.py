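"""Semi-physiological multi-compartment pharmacokinetics of systemic IL-21.

The drug is tracked as amounts (µg) in well-mixed compartments.  Intravenous
(IV) dosing uses a 4-compartment system: plasma exchanging bidirectionally
with three secondary tissues.  Subcutaneous (SC) and intraperitoneal (IP)
dosing use an 8-compartment system: an administration depot, up to three
absorption compartments feeding the plasma (possibly non-sequentially), and
the same three secondary tissues.  Inter-compartment transition and
degradation are saturable (Michaelis–Menten-type), reducing to linear
kinetics when the saturation constants vanish.

Target-tissue drug levels are not a compartment: they are slaved to plasma
concentration through a dimensionless blood:tissue ratio ``s`` (tissue =
plasma / s), so no drug mass leaves the system through that coupling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

__all__ = [
    "PKTopology",
    "PKParams",
    "PKState",
    "saturating_rate",
    "transition_rate",
    "degradation_rate",
    "pk_rhs",
    "plasma_concentration",
    "tissue_concentration",
    "iv_topology",
    "depot_topology",
    "topology_to_dict",
    "topology_from_dict",
    "params_to_dict",
    "params_from_dict",
    "load_pk_yaml",
    "dump_pk_yaml",
]

ROUTES = ("IV", "SC", "IP")

#: compartment labels, fixed per route family
IV_COMPARTMENTS = ("plasma", "sec1", "sec2", "sec3")
DEPOT_COMPARTMENTS = ("depot", "abs1", "abs2", "abs3", "plasma", "sec1", "sec2", "sec3")


class PKConfigError(ValueError):
    """Topology/parameter mismatch or malformed configuration."""


@dataclass(frozen=True)
class PKTopology:
    """Connectivity of the compartment system for one administration route.

    Parameters
    ----------
    route
        ``"IV"``, ``"SC"`` or ``"IP"``.
    compartments
        Ordered compartment labels.  Must contain ``"plasma"``; 4 labels for
        IV, 8 for SC/IP (first label is the injection depot).
    transitions
        Ordered pairs ``(src, dst)`` permitted to carry drug flow.  Reverse
        flow is modelled as a separately enabled ``(dst, src)`` pair.
    degradations
        Compartments permitted to degrade (eliminate) drug.
    """

    route: str
    compartments: tuple[str, ...]
    transitions: tuple[tuple[str, str], ...]
    degradations: tuple[str, ...]

    def __post_init__(self):
        if self.route not in ROUTES:
            raise PKConfigError(f"unknown route {self.route!r}; expected one of {ROUTES}")
        n = len(self.compartments)
        expected = 4 if self.route == "IV" else 8
        if n != expected:
            raise PKConfigError(
                f"{self.route} topology must have {expected} compartments, got {n}"
            )
        if len(set(self.compartments)) != n:
            raise PKConfigError("duplicate compartment labels")
        if "plasma" not in self.compartments:
            raise PKConfigError("topology must contain a 'plasma' compartment")
        for (i, j) in self.transitions:
            if i not in self.compartments or j not in self.compartments:
                raise PKConfigError(f"transition ({i}->{j}) references unknown compartment")
            if i == j:
                raise PKConfigError(f"self-transition on {i!r}")
        for c in self.degradations:
            if c not in self.compartments:
                raise PKConfigError(f"degradation on unknown compartment {c!r}")
        # every compartment must be reachable from the dosed compartment
        reach = {self.dosed_compartment}
        frontier = [self.dosed_compartment]
        adj: dict[str, list[str]] = {}
        for (i, j) in self.transitions:
            adj.setdefault(i, []).append(j)
        while frontier:
            c = frontier.pop()
            for nxt in adj.get(c, ()):
                if nxt not in reach:
                    reach.add(nxt)
                    frontier.append(nxt)
        missing = set(self.compartments) - reach
        if missing:
            raise PKConfigError(
                f"compartments unreachable from {self.dosed_compartment!r}: {sorted(missing)}"
            )

    @property
    def n_compartments(self) -> int:
        return len(self.compartments)

    @property
    def dosed_compartment(self) -> str:
        """Where a bolus lands: the depot for SC/IP, plasma for IV."""
        return "plasma" if self.route == "IV" else self.compartments[0]

    @property
    def plasma_index(self) -> int:
        return self.compartments.index("plasma")

    @property
    def dosed_index(self) -> int:
        return self.compartments.index(self.dosed_compartment)

    def index(self, label: str) -> int:
        return self.compartments.index(label)


@dataclass
class PKParams:
    """Kinetic constants attached to a :class:`PKTopology`.

    ``w``/``alpha`` are per-transition rate (1/day) and saturation (1/µg)
    constants; ``d``/``beta`` the per-compartment analogues for degradation.
    ``s`` is the route-specific plasma:tissue concentration ratio
    (dimensionless, realistic range 1–100) and ``v_plasma`` the plasma
    volume in ml (2 ml for a mouse).
    """

    w: dict[tuple[str, str], float] = field(default_factory=dict)
    alpha: dict[tuple[str, str], float] = field(default_factory=dict)
    d: dict[str, float] = field(default_factory=dict)
    beta: dict[str, float] = field(default_factory=dict)
    s: float = 10.0
    v_plasma: float = 2.0

    def validate(self, topology: PKTopology) -> None:
        for pair in topology.transitions:
            if pair not in self.w:
                raise PKConfigError(f"missing transition rate w for {pair[0]}->{pair[1]}")
            if self.w[pair] < 0 or self.alpha.get(pair, 0.0) < 0:
                raise PKConfigError(f"negative constant for transition {pair}")
        for c in topology.degradations:
            if c not in self.d:
                raise PKConfigError(f"missing degradation rate d for {c!r}")
            if self.d[c] < 0 or self.beta.get(c, 0.0) < 0:
                raise PKConfigError(f"negative constant for degradation in {c!r}")
        if self.v_plasma <= 0:
            raise PKConfigError("v_plasma must be positive")
        if not (1.0 <= self.s <= 100.0):
            warnings.warn(
                f"s={self.s} outside the realistic blood:tissue ratio range [1, 100]",
                stacklevel=2,
            )

    def copy(self) -> "PKParams":
        return PKParams(dict(self.w), dict(self.alpha), dict(self.d), dict(self.beta),
                        self.s, self.v_plasma)


@dataclass
class PKState:
    """Drug amounts (µg) per compartment plus a cumulative-degradation tally.

    The tally makes the mass balance checkable: injected total equals the sum
    of compartment amounts plus ``degraded`` at all times, to integration
    tolerance.
    """

    amounts: np.ndarray
    degraded: float = 0.0

    @property
    def total(self) -> float:
        return float(np.sum(self.amounts) + self.degraded)


def saturating_rate(x: float, rate: float, sat: float) -> float:
    """Default saturable flux  ``rate * x / (1 + sat * x)``.

    Linear (``rate * x``) when ``sat == 0``; approaches the ceiling
    ``rate / sat`` as ``x`` grows.  This single form backs both drug
    transition and degradation and is the pluggable primitive: pass an
    alternative callable to :func:`pk_rhs` to change the kinetic law.
    """
    if x < 0 or rate < 0 or sat < 0:
        raise ValueError("saturating_rate requires non-negative x, rate and sat")
    return rate * x / (1.0 + sat * x)


def transition_rate(x_i: float, w: float, alpha: float) -> float:
    """Drug flow (µg/day) out of a compartment holding ``x_i`` µg."""
    return saturating_rate(x_i, w, alpha)


def degradation_rate(x_i: float, d: float, beta: float) -> float:
    """Drug loss (µg/day) from a compartment holding ``x_i`` µg."""
    return saturating_rate(x_i, d, beta)


def pk_rhs(
    state: PKState,
    topology: PKTopology,
    params: PKParams,
    rate_fn=saturating_rate,
) -> PKState:
    """Time derivative of the PK state (reference implementation).

    Returns a :class:`PKState` holding d(amounts)/dt and d(degraded)/dt.
    The fast simulation path uses a compiled kernel with the default rate
    form; this function accepts any ``rate_fn(x, rate, sat)`` and is the
    ground truth the kernel is checked against.
    """
    params.validate(topology)
    x = state.amounts
    if len(x) != topology.n_compartments:
        raise PKConfigError("state size does not match topology")
    dx = np.zeros_like(x, dtype=float)
    for (a, b) in topology.transitions:
        i, j = topology.index(a), topology.index(b)
        flow = rate_fn(max(x[i], 0.0), params.w[(a, b)], params.alpha.get((a, b), 0.0))
        dx[i] -= flow
        dx[j] += flow
    ddeg = 0.0
    for c in topology.degradations:
        i = topology.index(c)
        loss = rate_fn(max(x[i], 0.0), params.d[c], params.beta.get(c, 0.0))
        dx[i] -= loss
        ddeg += loss
    return PKState(amounts=dx, degraded=ddeg)


def plasma_concentration(state: PKState | float, params: PKParams,
                         plasma_index: int = 0) -> float:
    """Plasma concentration (µg/ml) = plasma amount / plasma volume."""
    if params.v_plasma <= 0:
        raise ValueError("plasma volume must be positive")
    x0 = state if np.isscalar(state) else state.amounts[plasma_index]
    return float(x0) / params.v_plasma


def tissue_concentration(plasma_conc, s: float):
    """Target-tissue concentration (µg/ml) as a fraction of plasma levels.

    ``s`` is the blood:tissue ratio; tissue = plasma / s, so tissue levels
    never exceed plasma levels for s >= 1.
    """
    if s < 1.0:
        warnings.warn(f"s={s} below the realistic range [1, 100]", stacklevel=2)
    if s <= 0:
        raise ValueError("s must be positive")
    return np.asarray(plasma_conc) / s if np.ndim(plasma_conc) else float(plasma_conc) / s


# ---------------------------------------------------------------------------
# default topologies


def iv_topology() -> PKTopology:
    """4-compartment IV system: plasma <-> three secondary tissues."""
    trans = []
    for sec in ("sec1", "sec2", "sec3"):
        trans.append(("plasma", sec))
        trans.append((sec, "plasma"))
    return PKTopology(
        route="IV",
        compartments=IV_COMPARTMENTS,
        transitions=tuple(trans),
        degradations=("plasma", "sec1", "sec2", "sec3"),
    )


def depot_topology(route: str = "SC", shortcut: bool = True) -> PKTopology:
    """8-compartment SC/IP system.

    Absorption side: depot -> abs1 -> abs2 -> abs3 -> plasma chain plus an
    optional depot -> plasma shortcut (non-sequential flow).  Distribution
    side: plasma exchanging with three secondary tissues, as in IV.
    """
    if route not in ("SC", "IP"):
        raise PKConfigError("depot topology is for SC or IP routes")
    trans = [("depot", "abs1"), ("abs1", "abs2"), ("abs2", "abs3"), ("abs3", "plasma")]
    if shortcut:
        trans.append(("depot", "plasma"))
    for sec in ("sec1", "sec2", "sec3"):
        trans.append(("plasma", sec))
        trans.append((sec, "plasma"))
    return PKTopology(
        route=route,
        compartments=DEPOT_COMPARTMENTS,
        transitions=tuple(trans),
        degradations=("plasma", "sec1", "sec2", "sec3"),
    )


# ---------------------------------------------------------------------------
# YAML round-trip


def topology_to_dict(topology: PKTopology) -> dict:
    return {
        "route": topology.route,
        "compartments": list(topology.compartments),
        "transitions": [[a, b] for (a, b) in topology.transitions],
        "degradations": list(topology.degradations),
    }


def topology_from_dict(d: dict) -> PKTopology:
    return PKTopology(
        route=d["route"],
        compartments=tuple(d["compartments"]),
        transitions=tuple((a, b) for a, b in d["transitions"]),
        degradations=tuple(d["degradations"]),
    )


def params_to_dict(params: PKParams) -> dict:
    return {
        "transitions": {
            f"{a}->{b}": {"w": float(params.w[(a, b)]),
                          "alpha": float(params.alpha.get((a, b), 0.0))}
            for (a, b) in params.w
        },
        "degradations": {
            c: {"d": float(params.d[c]), "beta": float(params.beta.get(c, 0.0))}
            for c in params.d
        },
        "s": float(params.s),
        "v_plasma": float(params.v_plasma),
    }


def params_from_dict(d: dict) -> PKParams:
    w, alpha = {}, {}
    for key, val in d.get("transitions", {}).items():
        a, b = key.split("->")
        w[(a, b)] = float(val["w"])
        alpha[(a, b)] = float(val.get("alpha", 0.0))
    dd, beta = {}, {}
    for c, val in d.get("degradations", {}).items():
        dd[c] = float(val["d"])
        beta[c] = float(val.get("beta", 0.0))
    return PKParams(w=w, alpha=alpha, d=dd, beta=beta,
                    s=float(d.get("s", 10.0)), v_plasma=float(d.get("v_plasma", 2.0)))


def dump_pk_yaml(path, topology: PKTopology, params: PKParams) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"topology": topology_to_dict(topology),
                        "params": params_to_dict(params)}, fh, sort_keys=False)


def load_pk_yaml(path) -> tuple[PKTopology, PKParams]:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    topo = topology_from_dict(d["topology"])
    par = params_from_dict(d["params"])
    par.validate(topo)
    return topo, par
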