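"""In-silico regimen experiments: onset, fractionation and dose scans.

All scans are deterministic given (model parameters, grid, step size) and
share one endpoint day so final tumor volumes are comparable across grid
points.  For the melanoma early-onset setting the endpoint is day 20 (end
of the reference therapy window); doses scheduled after the endpoint are
not administered.  Statistical comparison (two-tailed pooled-variance t
test) is meant for synthetic cohorts carrying animal-level noise, never
for noiseless trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .regimen import Regimen, expand_regimen
from .simulate import DEFAULT_INOCULUM, TherapyModel, Trajectory

__all__ = [
    "ScanResult",
    "SchemeError",
    "B16_ENDPOINT_DAY",
    "DEFAULT_ONSETS",
    "DEFAULT_FRACTIONATION_INTERVALS_H",
    "DEFAULT_DAILY_DOSES",
    "make_fractionation_schemes",
    "scan_onset",
    "scan_fractionation",
    "scan_dose",
    "endpoint_ratio",
    "t_test_endpoints",
]

#: end-of-therapy endpoint for the B16 early-onset setting
B16_ENDPOINT_DAY = 20.0
#: default scan grids
DEFAULT_ONSETS = (1.0, 3.0, 5.0, 8.0, 10.0)
DEFAULT_FRACTIONATION_INTERVALS_H = (72.0, 48.0, 24.0, 12.0, 6.0, 3.0)
DEFAULT_DAILY_DOSES = (0.5, 1.0, 2.0, 5.0, 12.0, 25.0, 50.0, 100.0)


class SchemeError(ValueError):
    """A fractionation scheme violates the iso-dose/window constraint."""


@dataclass
class ScanResult:
    """Final tumor volumes over one scanned variable at a common endpoint."""

    scan_variable: str
    grid: list
    final_tumor_mm3: np.ndarray
    endpoint_day: float
    trajectories: list[Trajectory] | None = None
    labels: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.grid)

    def as_dict(self) -> dict:
        return dict(zip(self.grid, self.final_tumor_mm3.tolist()))

    def to_dataframe(self, reference_index: int = 0):
        """Tidy table: grid value, final volume, percent vs reference point."""
        import pandas as pd

        ref = self.final_tumor_mm3[reference_index]
        return pd.DataFrame({
            "grid_value": [str(g) for g in self.grid],
            "final_tumor_mm3": self.final_tumor_mm3,
            "pct_vs_reference": 100.0 * (1.0 - self.final_tumor_mm3 / ref),
        })


def _simulate_truncated(model: TherapyModel, regimen: Regimen, t_end: float,
                        dt: float, T0: float) -> Trajectory:
    events = [e for e in expand_regimen(regimen) if e.time_day <= t_end + 1e-9]
    from .simulate import simulate_therapy

    return simulate_therapy(regimen, model.topology, model.pk_params,
                            model.pd_params, t_end, dt=dt, T0=T0, events=events)


def scan_onset(onsets, base: Regimen, model: TherapyModel,
               endpoint_day: float = B16_ENDPOINT_DAY, dt: float = 0.002,
               T0: float = DEFAULT_INOCULUM, keep_trajectories: bool = False) -> ScanResult:
    """Shift therapy onset while keeping dose, interval and duration.

    Every regimen is evaluated at the same endpoint day; doses falling
    after the endpoint are not given (a day-10 onset of a 16-dose daily
    schedule contributes only its first 11 injections by day 20).
    """
    onsets = [float(o) for o in onsets]
    for o in onsets:
        if o < 1.0:
            raise ValueError(f"onset {o} is before day 1 post-inoculation")
        if o > endpoint_day:
            raise ValueError(f"onset {o} lies beyond the endpoint day {endpoint_day}")
    trajs, finals = [], []
    for o in onsets:
        reg = base.replace(onset_day=o)
        traj = _simulate_truncated(model, reg, endpoint_day, dt, T0)
        finals.append(traj.final_tumor_mm3)
        trajs.append(traj)
    return ScanResult("onset_day", onsets, np.array(finals), endpoint_day,
                      trajs if keep_trajectories else None,
                      labels=[f"onset-{o:g}" for o in onsets])


def make_fractionation_schemes(total_dose: float = 800.0,
                               intervals_h=DEFAULT_FRACTIONATION_INTERVALS_H,
                               window_days: float = 17.0):
    """Iso-dose (dose, interval) schemes filling the treatment window.

    For each inter-dosing interval the number of injections is the maximum
    that fits the window, and the per-dose amount is total/n.
    """
    schemes = []
    for iv_h in intervals_h:
        interval = float(iv_h) / 24.0
        n = int(np.floor(window_days / interval)) + 1
        schemes.append((total_dose / n, interval))
    return schemes


def scan_fractionation(total_dose: float, schemes, model: TherapyModel,
                       window_days: float = 17.0, onset_day: float = 3.0,
                       endpoint_day: float = B16_ENDPOINT_DAY, dt: float = 0.002,
                       T0: float = DEFAULT_INOCULUM,
                       keep_trajectories: bool = False) -> ScanResult:
    """Distribute one total dose across the window in different schemes.

    Each scheme is a (dose_ug, interval_days) pair; the implied number of
    injections must reproduce the total dose and fit inside the window,
    otherwise the scheme is rejected by name.
    """
    grid, finals, trajs, labels = [], [], [], []
    for dose, interval in schemes:
        if dose <= 0 or interval <= 0:
            raise SchemeError(f"scheme ({dose} µg / {interval} d) is degenerate")
        n = int(round(total_dose / dose))
        if abs(n * dose - total_dose) > 1e-6 * total_dose:
            raise SchemeError(
                f"scheme ({dose} µg every {interval} d) cannot reach the "
                f"iso-dose total of {total_dose} µg with an integer dose count")
        if (n - 1) * interval > window_days + 1e-9:
            raise SchemeError(
                f"scheme ({dose} µg every {interval} d, {n} doses) exceeds "
                f"the {window_days}-day treatment window")
        reg = Regimen(model.topology.route, dose, onset_day, interval, n,
                      label=f"{dose:g}ug-q{interval * 24:g}h")
        traj = _simulate_truncated(model, reg, endpoint_day, dt, T0)
        grid.append((dose, interval))
        finals.append(traj.final_tumor_mm3)
        labels.append(reg.label)
        trajs.append(traj)
    return ScanResult("fractionation(dose,interval)", grid, np.array(finals),
                      endpoint_day, trajs if keep_trajectories else None, labels)


def scan_dose(daily_doses, model: TherapyModel, onset_day: float = 3.0,
              n_doses: int = 16, endpoint_day: float = B16_ENDPOINT_DAY,
              dt: float = 0.002, T0: float = DEFAULT_INOCULUM,
              keep_trajectories: bool = False) -> ScanResult:
    """Daily-dose titration; dose 0 is the PBS-control anchor."""
    doses = [float(d) for d in daily_doses]
    if 0.0 not in doses:
        doses = [0.0] + doses
    if any(d < 0 for d in doses):
        raise ValueError("doses must be non-negative")
    finals, trajs = [], []
    for d in doses:
        reg = Regimen(model.topology.route, d, onset_day, 1.0,
                      n_doses if d > 0 else 0, label=f"{d:g}ug-daily")
        traj = _simulate_truncated(model, reg, endpoint_day, dt, T0)
        finals.append(traj.final_tumor_mm3)
        trajs.append(traj)
    return ScanResult("daily_dose_ug", doses, np.array(finals), endpoint_day,
                      trajs if keep_trajectories else None,
                      labels=[f"{d:g}ug" for d in doses])


def endpoint_ratio(volume_a: float, volume_b: float) -> float:
    """Percent difference 100*(1 - A/B) of two same-day endpoints."""
    if volume_b == 0:
        raise ZeroDivisionError("reference endpoint volume is zero")
    return 100.0 * (1.0 - volume_a / volume_b)


def t_test_endpoints(group_a, group_b):
    """Two-sided pooled-variance Student t test on endpoint volumes."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two animals")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValueError("degenerate test: zero pooled variance")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)
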