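"""Coupled PK+PD therapy simulation with fixed-step RK4 and bolus events.

Dose events are snapped to the integration grid and applied as
instantaneous state increments; the recorded state at an event time is the
post-bolus state (so an IV 50 µg bolus into 2 ml plasma reads 25 µg/ml at
t = 0+).  The euthanasia threshold is deliberately not enforced here — the
model tracks the mean cohort trajectory; censoring belongs to the
synthetic-cohort generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .pd import PDParams, PDState, baseline_state, CELLS_PER_MM3
from .pk import PKConfigError, PKParams, PKTopology
from .regimen import DoseEvent, Regimen, expand_regimen

__all__ = ["Trajectory", "TherapyModel", "simulate_therapy", "simulate_single_dose",
           "IntegrationError", "DEFAULT_DT", "DEFAULT_INOCULUM"]

#: default RK4 step (days); ~3 minutes of model time
DEFAULT_DT = 0.002
#: tumor inoculum at day 0 (cells)
DEFAULT_INOCULUM = 1.0e5


class IntegrationError(RuntimeError):
    pass


@dataclass
class _CompiledPK:
    tsrc: np.ndarray
    tdst: np.ndarray
    tw: np.ndarray
    talpha: np.ndarray
    didx: np.ndarray
    dd: np.ndarray
    dbeta: np.ndarray
    plasma_i: int
    dosed_i: int
    n_pk: int


def _compile_pk(topology: PKTopology, params: PKParams) -> _CompiledPK:
    params.validate(topology)
    tsrc = np.array([topology.index(a) for a, _ in topology.transitions], np.int64)
    tdst = np.array([topology.index(b) for _, b in topology.transitions], np.int64)
    tw = np.array([params.w[p] for p in topology.transitions], float)
    talpha = np.array([params.alpha.get(p, 0.0) for p in topology.transitions], float)
    didx = np.array([topology.index(c) for c in topology.degradations], np.int64)
    dd = np.array([params.d[c] for c in topology.degradations], float)
    dbeta = np.array([params.beta.get(c, 0.0) for c in topology.degradations], float)
    return _CompiledPK(tsrc, tdst, tw, talpha, didx, dd, dbeta,
                       topology.plasma_index, topology.dosed_index,
                       topology.n_compartments)


@dataclass
class Trajectory:
    """Dense output of one simulation on the RK4 grid.

    ``states`` rows follow the kernel layout: PK amounts, cumulative
    degraded drug, then (N, C, pN, pC, Mem, T).
    """

    times: np.ndarray
    states: np.ndarray
    compartments: tuple[str, ...]
    plasma_index: int
    v_plasma: float
    s: float
    total_injected: float
    pd_on: bool = True
    injected_cum: np.ndarray | None = None   # drug injected up to each time

    @property
    def n_pk(self) -> int:
        return len(self.compartments)

    @property
    def pk_amounts(self) -> np.ndarray:
        return self.states[:, : self.n_pk]

    @property
    def degraded(self) -> np.ndarray:
        return self.states[:, self.n_pk]

    @property
    def plasma_conc(self) -> np.ndarray:
        """Plasma concentration, µg/ml."""
        return self.states[:, self.plasma_index] / self.v_plasma

    @property
    def tissue_conc(self) -> np.ndarray:
        """Target-tissue concentration, µg/ml (plasma / s)."""
        return self.plasma_conc / self.s

    def _pd(self, k: int) -> np.ndarray:
        return self.states[:, self.n_pk + 1 + k]

    @property
    def nk(self) -> np.ndarray:
        return self._pd(0)

    @property
    def ctl(self) -> np.ndarray:
        return self._pd(1)

    @property
    def prot_nk(self) -> np.ndarray:
        return self._pd(2)

    @property
    def prot_ctl(self) -> np.ndarray:
        return self._pd(3)

    @property
    def memory(self) -> np.ndarray:
        return self._pd(4)

    @property
    def tumor_cells(self) -> np.ndarray:
        return self._pd(5)

    @property
    def tumor_mm3(self) -> np.ndarray:
        return self.tumor_cells / CELLS_PER_MM3

    @property
    def final_tumor_mm3(self) -> float:
        return float(self.tumor_mm3[-1])

    def at(self, times, series: np.ndarray) -> np.ndarray:
        """Linear interpolation of any stored series onto ``times``."""
        return np.interp(np.asarray(times, float), self.times, series)

    def mass_balance_error(self) -> float:
        """Max relative violation of (injected-so-far = in-system + degraded)."""
        total = self.pk_amounts.sum(axis=1) + self.degraded
        injected = self.injected_cum if self.injected_cum is not None \
            else np.full_like(total, self.total_injected)
        scale = max(self.total_injected, 1e-12)
        return float(np.max(np.abs(total - injected)) / scale)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_days": self.times,
            "plasma_ug_ml": self.plasma_conc,
            "tissue_ug_ml": self.tissue_conc,
            "NK": self.nk,
            "CTL": self.ctl,
            "memory": self.memory,
            "tumor_cells": self.tumor_cells,
            "tumor_mm3": self.tumor_mm3,
        })


def _check_non_negative(traj: Trajectory) -> None:
    pk_floor = -1e-6 * max(traj.total_injected, 1.0)
    if traj.pk_amounts.min(initial=0.0) < pk_floor:
        raise IntegrationError(
            "PK amounts went negative beyond tolerance; use a smaller dt")
    if traj.pd_on:
        pdblock = traj.states[:, traj.n_pk + 1:]
        scale = np.maximum(np.abs(pdblock).max(axis=0), 1.0)
        if (pdblock.min(axis=0) / scale).min() < -1e-6:
            raise IntegrationError(
                "PD state went negative beyond tolerance; use a smaller dt")


def simulate_therapy(
    regimen: Regimen,
    topology: PKTopology,
    pk_params: PKParams,
    pd_params: PDParams | None,
    t_end: float,
    dt: float = DEFAULT_DT,
    T0: float = DEFAULT_INOCULUM,
    t_start: float = 0.0,
    initial_y: np.ndarray | None = None,
    events: list[DoseEvent] | None = None,
) -> Trajectory:
    """Integrate the joint PK+PD system under a dosing regimen.

    Deterministic for fixed inputs.  ``pd_params=None`` integrates the PK
    system alone.  ``t_start``/``initial_y`` allow resuming a saved state
    (events at or before ``t_start`` are assumed already applied).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if regimen.route != topology.route:
        raise PKConfigError(
            f"regimen route {regimen.route} does not match topology route {topology.route}")
    cpk = _compile_pk(topology, pk_params)
    pd_on = pd_params is not None
    dim = cpk.n_pk + 7
    if events is None:
        events = expand_regimen(regimen)
    events = [e for e in events if e.time_day > t_start + 1e-12 or
              (initial_y is None and abs(e.time_day - t_start) <= 1e-12)]
    # doses scheduled after the simulation horizon are simply not given
    events = [e for e in events if e.time_day <= t_end + 1e-9]

    n_steps = int(round((t_end - t_start) / dt))
    if n_steps <= 0:
        raise ValueError("t_end must exceed t_start by at least one step")
    times = t_start + dt * np.arange(n_steps + 1)

    if initial_y is not None:
        y = np.asarray(initial_y, float).copy()
        if y.shape != (dim,):
            raise ValueError(f"initial_y must have shape ({dim},)")
    else:
        y = np.zeros(dim)
        if pd_on:
            y[cpk.n_pk + 1:] = baseline_state(pd_params, T0).to_array()

    pdp = pd_params.to_vector() if pd_on else np.zeros(23)
    inv_vs = 1.0 / (pk_params.v_plasma * pk_params.s)

    # group events by snapped grid index; each event lands in the
    # compartment it names (depot for SC/IP boluses, plasma for IV)
    by_index: dict[int, dict[int, float]] = {}
    for e in events:
        idx = int(round((e.time_day - t_start) / dt))
        idx = min(max(idx, 0), n_steps)
        comp_i = topology.index(e.compartment)
        slot = by_index.setdefault(idx, {})
        slot[comp_i] = slot.get(comp_i, 0.0) + e.amount_ug
    injected = sum(e.amount_ug for e in events)
    base_total = float(y[: cpk.n_pk].sum() + y[cpk.n_pk])

    states = np.empty((n_steps + 1, dim))
    if 0 in by_index:
        for comp_i, amt in by_index[0].items():
            y[comp_i] += amt
    states[0] = y
    cursor = 0
    for idx in sorted(i for i in by_index if i > 0) + [n_steps]:
        seg = idx - cursor
        if seg > 0:
            _kernels.integrate_segment(
                y, dt, seg, states, cursor + 1,
                cpk.n_pk, cpk.tsrc, cpk.tdst, cpk.tw, cpk.talpha,
                cpk.didx, cpk.dd, cpk.dbeta,
                cpk.plasma_i, inv_vs, pdp, pd_on)
        if idx in by_index and idx != 0:
            for comp_i, amt in by_index[idx].items():
                y[comp_i] += amt
            states[idx] = y
        cursor = idx
        if cursor >= n_steps:
            break

    injected_cum = np.full(n_steps + 1, base_total)
    for idx, slot in by_index.items():
        injected_cum[idx:] += sum(slot.values())

    traj = Trajectory(
        times=times, states=states, compartments=topology.compartments,
        plasma_index=cpk.plasma_i, v_plasma=pk_params.v_plasma, s=pk_params.s,
        total_injected=injected + base_total, pd_on=pd_on,
        injected_cum=injected_cum)
    _check_non_negative(traj)
    return traj


def simulate_single_dose(
    topology: PKTopology,
    pk_params: PKParams,
    dose_ug: float,
    t_end: float,
    dt: float = DEFAULT_DT,
) -> Trajectory:
    """PK-only simulation of one bolus at t=0 (PD block inert)."""
    reg = Regimen(route=topology.route, dose_ug=dose_ug, onset_day=0.0, n_doses=1)
    return simulate_therapy(reg, topology, pk_params, None, t_end, dt=dt)


@dataclass
class TherapyModel:
    """A fully parameterized model: one route's PK plus the PD/disease side."""

    topology: PKTopology
    pk_params: PKParams
    pd_params: PDParams
    label: str = ""

    def simulate(self, regimen: Regimen, t_end: float, dt: float = DEFAULT_DT,
                 T0: float = DEFAULT_INOCULUM) -> Trajectory:
        return simulate_therapy(regimen, self.topology, self.pk_params,
                                self.pd_params, t_end, dt=dt, T0=T0)

    def neutralized(self, which: str) -> "TherapyModel":
        """Model variant mimicking effector neutralization.

        ``"Tcell"`` removes CTL killing (k2=0); ``"NK"`` removes NK killing
        (k1=0); ``"none"`` returns an unchanged copy.
        """
        if which == "none":
            pdp = self.pd_params.copy()
        elif which == "Tcell":
            pdp = self.pd_params.copy(k2=0.0)
        elif which == "NK":
            pdp = self.pd_params.copy(k1=0.0)
        else:
            raise ValueError("neutralization must be 'none', 'NK' or 'Tcell'")
        return TherapyModel(self.topology, self.pk_params, pdp,
                            label=f"{self.label}/{which}")
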