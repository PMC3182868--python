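"""Target-tissue pharmacodynamics and disease dynamics of IL-21 therapy.

Six coupled states: NK cells (N), CTLs (C), per-cell cytotoxic-protein
levels in each effector (pN, pC), an IL-21-driven memory factor (Mem) and
the tumor-cell population (T).  The drug input is the target-tissue IL-21
concentration u (µg/ml), slaved to plasma levels on the PK side.

Qualitative structure (each drug effect saturates with its own
half-saturation constant):

* IL-21 inhibits NK survival: N has constant influx, baseline death, and a
  drug-driven death term increasing and saturating in u.
* IL-21 promotes CTL expansion through memory: Mem accumulates saturably
  with u and decays slowly; C expands proportionally to Mem with a
  logistic ceiling set by D_max (expansion intensity scaled by sigma), plus
  a small constant influx and baseline death.
* IL-21 enhances the cytotoxic-protein stores of both effectors: pN and pC
  relax toward a baseline plus a saturable drug-induced boost.
* The tumor grows logistically (rate r, carrying capacity K) and is killed
  by mass-action effector contact, (k1*N*pN + k2*C*pC)*T.  The calibrated
  configuration is CTL-dominant (k2 ~ 10*k1); k1 = k2 reproduces the
  "equal effector balance" variant.

With no drug and Mem(0)=0 the immune states sit at a steady baseline, so
the drug-free tumor follows an exact logistic curve with effective rate
r - kappa0 and capacity K*(1 - kappa0/r), where kappa0 is the baseline
kill-rate coefficient (see :func:`drug_free_logistic`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace, fields

import numpy as np

__all__ = [
    "dump_pd_yaml",
    "load_pd_yaml",
    "PDParams",
    "PDState",
    "logistic_growth",
    "tumor_kill_rate",
    "pd_rhs",
    "cells_to_volume",
    "baseline_state",
    "baseline_kill_coefficient",
    "drug_free_logistic",
    "CELLS_PER_MM3",
]

#: volume scaling: 1e6 tumor cells occupy 1 mm^3
CELLS_PER_MM3 = 1.0e6


@dataclass
class PDParams:
    """Rate constants of the PD/disease system (time unit: days).

    Immune-system constants (influx/death/saturation of effectors, memory
    and proteins) are shared across tumor types; ``sigma`` and ``d_max``
    (CTL response intensity and ceiling) are tumor-type specific; ``r`` and
    ``K`` are specific to tumor type x therapy-onset dataset; ``k1``/``k2``
    are the NK and CTL interaction affinities to the tumor.
    """

    # NK compartment
    influx_nk: float       # cells/day constant influx
    death_nk: float        # 1/day baseline death
    drug_death_nk: float   # 1/day maximal extra death under saturating drug
    h_nk: float            # µg/ml half-saturation of NK inhibition
    # memory factor
    mem_gain: float        # units/day accumulation at saturating drug
    h_mem: float           # µg/ml half-saturation of memory induction
    mem_decay: float       # 1/day
    # CTL compartment
    sigma: float           # 1/(memory unit * day) expansion intensity
    d_max: float           # cells, CTL ceiling
    influx_ctl: float      # cells/day small constant influx
    death_ctl: float       # 1/day baseline death
    # cytotoxic proteins (per-cell, arbitrary units)
    prot_base_nk: float
    prot_gain_nk: float
    h_prot_nk: float       # µg/ml
    prot_decay_nk: float   # 1/day relaxation rate
    prot_base_ctl: float
    prot_gain_ctl: float
    h_prot_ctl: float
    prot_decay_ctl: float
    # tumor interaction and growth
    k1: float              # per (cell * protein unit * day), NK affinity
    k2: float              # per (cell * protein unit * day), CTL affinity
    r: float               # 1/day intrinsic growth
    K: float               # cells, carrying capacity

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if v < 0:
                raise ValueError(f"PD parameter {f.name} must be non-negative, got {v}")
        if self.r <= 0 or self.K <= 0:
            raise ValueError("tumor growth requires r > 0 and K > 0")

    def to_vector(self) -> np.ndarray:
        """Flatten to the fixed ordering the compiled kernel consumes."""
        return np.array([
            self.influx_nk, self.death_nk, self.drug_death_nk, self.h_nk,
            self.mem_gain, self.h_mem, self.mem_decay,
            self.sigma, self.d_max, self.influx_ctl, self.death_ctl,
            self.prot_base_nk, self.prot_gain_nk, self.h_prot_nk, self.prot_decay_nk,
            self.prot_base_ctl, self.prot_gain_ctl, self.h_prot_ctl, self.prot_decay_ctl,
            self.k1, self.k2, self.r, self.K,
        ], dtype=float)

    def copy(self, **overrides) -> "PDParams":
        return replace(self, **overrides)


@dataclass
class PDState:
    """One point of the PD/disease state space (all components >= 0)."""

    N: float       # NK cells
    C: float       # CTLs
    pN: float      # per-NK cytotoxic protein
    pC: float      # per-CTL cytotoxic protein
    Mem: float     # memory factor
    T: float       # tumor cells

    def to_array(self) -> np.ndarray:
        return np.array([self.N, self.C, self.pN, self.pC, self.Mem, self.T], float)

    @classmethod
    def from_array(cls, a) -> "PDState":
        return cls(*map(float, a))


def dump_pd_yaml(path, params: PDParams) -> None:
    """Write a PD parameter set to YAML (one key per rate constant)."""
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump({f.name: float(getattr(params, f.name))
                        for f in fields(params)}, fh, sort_keys=False)


def load_pd_yaml(path) -> PDParams:
    import yaml

    with open(path) as fh:
        return PDParams(**yaml.safe_load(fh))


def logistic_growth(T: float, r: float, K: float) -> float:
    """Logistic tumor growth rate r*T*(1 - T/K) (cells/day)."""
    if K <= 0:
        raise ValueError("carrying capacity K must be positive")
    if T < 0 or r < 0:
        raise ValueError("T and r must be non-negative")
    return r * T * (1.0 - T / K)


def tumor_kill_rate(T, N, C, pN, pC, k1, k2):
    """Effector-mediated tumor loss (cells/day), mass-action in each arm.

    ``k2 = 0`` reproduces a T-cell-neutralized animal (no CTL killing);
    ``k1 = 0`` an NK-neutralized one.
    """
    if min(T, N, C, pN, pC, k1, k2) < 0:
        raise ValueError("tumor_kill_rate requires non-negative inputs")
    return (k1 * N * pN + k2 * C * pC) * T


def _sat(u: float, h: float) -> float:
    return u / (h + u) if (h + u) > 0 else 0.0


def pd_rhs(state: PDState, u: float, params: PDParams) -> PDState:
    """Time derivative of the PD/disease state at tissue drug level ``u``.

    Reference implementation; the compiled kernel used for long simulations
    is checked against this function.
    """
    if u < 0:
        raise ValueError("tissue drug concentration u must be non-negative")
    p = params
    N, C, pN, pC, Mem, T = state.N, state.C, state.pN, state.pC, state.Mem, state.T
    dN = p.influx_nk - p.death_nk * N - p.drug_death_nk * _sat(u, p.h_nk) * N
    dC = p.influx_ctl + p.sigma * Mem * C * (1.0 - C / p.d_max) - p.death_ctl * C
    dpN = p.prot_decay_nk * (p.prot_base_nk + p.prot_gain_nk * _sat(u, p.h_prot_nk) - pN)
    dpC = p.prot_decay_ctl * (p.prot_base_ctl + p.prot_gain_ctl * _sat(u, p.h_prot_ctl) - pC)
    dMem = p.mem_gain * _sat(u, p.h_mem) - p.mem_decay * Mem
    dT = logistic_growth(T, p.r, p.K) - tumor_kill_rate(T, N, C, pN, pC, p.k1, p.k2)
    return PDState(dN, dC, dpN, dpC, dMem, dT)


def cells_to_volume(T):
    """Tumor volume in mm^3, assuming 1e6 cells per mm^3."""
    if np.any(np.asarray(T) < 0):
        raise ValueError("cell count must be non-negative")
    return np.asarray(T) / CELLS_PER_MM3 if np.ndim(T) else float(T) / CELLS_PER_MM3


def baseline_state(params: PDParams, T0: float) -> PDState:
    """Drug-free initial condition: immune states at their u=0 steady state.

    Mem starts at 0 and CTLs at their small influx/death balance (the seed
    from which drug-driven expansion can grow); the tumor starts at the
    inoculum ``T0``.
    """
    return PDState(
        N=params.influx_nk / params.death_nk,
        C=params.influx_ctl / params.death_ctl,
        pN=params.prot_base_nk,
        pC=params.prot_base_ctl,
        Mem=0.0,
        T=float(T0),
    )


def baseline_kill_coefficient(params: PDParams) -> float:
    """Per-day tumor kill-rate coefficient exerted by baseline effectors."""
    b = baseline_state(params, T0=1.0)
    return params.k1 * b.N * b.pN + params.k2 * b.C * b.pC


def drug_free_logistic(params: PDParams, T0: float, t) -> np.ndarray:
    """Closed-form drug-free tumor trajectory (cells).

    With immune states pinned at baseline, dT/dt = r*T*(1-T/K) - kappa0*T is
    itself logistic with r_eff = r - kappa0 and K_eff = K * r_eff / r; this
    is the analytic oracle for PBS-control simulations.
    """
    kappa0 = baseline_kill_coefficient(params)
    r_eff = params.r - kappa0
    t = np.asarray(t, dtype=float)
    if abs(r_eff) < 1e-14:
        # pure decay-free balance: dT/dt = -r T^2 / K
        return params.K * T0 / (params.K + params.r * T0 * t)
    K_eff = params.K * r_eff / params.r
    e = np.exp(r_eff * t)
    return K_eff * T0 * e / (K_eff + T0 * (e - 1.0))
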