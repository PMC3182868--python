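"""Virtual-cohort data generation for calibration and validation.

Emulates the preclinical data classes the calibration pipeline trains on,
from known ground-truth parameters: single-dose serum PK profiles per
route, tumor-volume cohorts under PBS/treated/neutralized arms with
~3x/week caliper measurements, animal-level heterogeneity, measurement
noise, and euthanasia censoring at 1000 mm³.  All outputs are pure
functions of (spec, ground truth, seed).

Cohort construction: one model trajectory per arm; each virtual animal is
the trajectory scaled by a lognormal animal-level factor, with
multiplicative measurement noise per caliper reading.  Once an animal's
measured volume reaches the euthanasia threshold that measurement is its
last: later time points drop out of the cohort mean and SEM (SD/sqrt(n)
over surviving animals).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calibration import TimeSeriesDataset, TrainingBundle
from .pd import PDParams
from .pk import (
    PKParams,
    PKTopology,
    params_from_dict as pk_params_from_dict,
    params_to_dict as pk_params_to_dict,
    topology_from_dict,
    topology_to_dict,
)
from .presets import (
    default_pd_params,
    default_pk_params,
    default_topology,
    standard_b16_regimen,
)
from .regimen import Regimen, expand_regimen
from .simulate import DEFAULT_INOCULUM, simulate_single_dose, simulate_therapy

__all__ = [
    "NoiseModel",
    "CohortSpec",
    "GroundTruth",
    "EUTHANASIA_MM3",
    "B16_MEASUREMENT_DAYS",
    "generate_pk_profiles",
    "generate_tumor_cohort",
    "make_training_bundle",
    "bundle_from_manifest",
    "default_ground_truth",
]

#: individual-animal euthanasia threshold (mm³)
EUTHANASIA_MM3 = 1000.0
#: ~3x/week caliper schedule for the B16 early-onset window
B16_MEASUREMENT_DAYS = (3.0, 6.0, 8.0, 10.0, 13.0, 15.0, 17.0, 20.0)
#: PK sampling times (days) after a single dose
PK_SAMPLING_DAYS = (0.021, 0.042, 0.083, 0.167, 0.25, 0.333, 0.5, 0.75, 1.0, 1.5)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise description for one generated dataset.

    ``proportional_cv`` is the per-reading coefficient of variation;
    ``additive_sd`` an absolute noise floor (mm³ for tumor, µg/ml for PK);
    ``animal_cv`` the lognormal between-animal scale heterogeneity.
    """

    proportional_cv: float = 0.10
    additive_sd: float = 0.0
    animal_cv: float = 0.15
    floor_at_zero: bool = True

    def __post_init__(self):
        if self.proportional_cv < 0 or self.additive_sd < 0 or self.animal_cv < 0:
            raise ValueError("noise magnitudes must be non-negative")


@dataclass(frozen=True)
class CohortSpec:
    """One virtual murine cohort (tumor type, arm, schedule, noise, seed)."""

    tumor_type: str = "B16"
    regimen: Regimen = field(default_factory=standard_b16_regimen)
    n_mice: int = 10
    measurement_days: tuple = B16_MEASUREMENT_DAYS
    noise: NoiseModel = field(default_factory=NoiseModel)
    neutralization: str = "none"   # none | NK | Tcell
    seed: int = 0

    def __post_init__(self):
        if self.n_mice < 1:
            raise ValueError("n_mice must be at least 1")
        if self.neutralization not in ("none", "NK", "Tcell"):
            raise ValueError("neutralization must be none, NK or Tcell")
        if len(self.measurement_days) and self.regimen.n_doses:
            if min(self.measurement_days) < 0:
                raise ValueError("measurement days must be non-negative")


def _lognormal_factors(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    """Unit-median lognormal scale factors with the requested CV."""
    if cv == 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv ** 2))
    return np.exp(rng.normal(0.0, sigma, n) - sigma ** 2 / 2)


def generate_pk_profiles(route: str, dose_ug: float, sampling_times,
                         topology: PKTopology, pk_params: PKParams,
                         noise: NoiseModel = NoiseModel(), n_mice: int = 6,
                         seed: int = 0, dt: float = 0.002) -> TimeSeriesDataset:
    """Mean±SEM serum concentrations after one bolus, over a virtual group."""
    if dose_ug <= 0:
        raise ValueError("dose_ug must be positive")
    times = np.asarray(sampling_times, float)
    traj = simulate_single_dose(topology, pk_params, dose_ug,
                                float(times.max()), dt=dt)
    true_conc = traj.at(times, traj.plasma_conc)
    rng = np.random.default_rng(seed)
    factors = _lognormal_factors(rng, n_mice, noise.animal_cv)
    readings = np.empty((n_mice, len(times)))
    for i in range(n_mice):
        eps = rng.normal(0.0, 1.0, len(times))
        vals = true_conc * factors[i] * (1.0 + noise.proportional_cv * eps)
        vals = vals + rng.normal(0.0, noise.additive_sd, len(times)) \
            if noise.additive_sd else vals
        readings[i] = np.maximum(vals, 0.0) if noise.floor_at_zero else vals
    mean = readings.mean(axis=0)
    sd = readings.std(axis=0, ddof=1) if n_mice > 1 else np.zeros(len(times))
    return TimeSeriesDataset(times, mean, sd / np.sqrt(n_mice),
                             np.full(len(times), n_mice),
                             arm=f"PK-{route}-{dose_ug:g}ug")


@dataclass
class GroundTruth:
    """The generating model: per-route PK, PD presets, reference regimens."""

    topologies: dict[str, PKTopology]
    pk_params: dict[str, PKParams]
    pd_params: PDParams
    t0_cells: float = DEFAULT_INOCULUM


def default_ground_truth(preset: str = "B16-early",
                         routes=("SC", "IP", "IV")) -> GroundTruth:
    return GroundTruth(
        topologies={r: default_topology(r) for r in routes},
        pk_params={r: default_pk_params(r) for r in routes},
        pd_params=default_pd_params(preset),
    )


def generate_tumor_cohort(spec: CohortSpec, truth: GroundTruth,
                          dt: float = 0.002):
    """Per-animal tumor-volume table plus the censored cohort mean±SEM.

    Neutralized arms simulate with the corresponding affinity zeroed
    (``Tcell`` -> k2=0, ``NK`` -> k1=0).  Returns ``(dataset, animals)``
    where ``animals`` is a tidy DataFrame with one row per surviving
    measurement.
    """
    reg = spec.regimen
    route = reg.route
    pdp = truth.pd_params
    if spec.neutralization == "Tcell":
        pdp = pdp.copy(k2=0.0)
    elif spec.neutralization == "NK":
        pdp = pdp.copy(k1=0.0)
    days = np.asarray(spec.measurement_days, float)
    t_end = float(days.max())
    events = [e for e in expand_regimen(reg) if e.time_day <= t_end + 1e-9]
    traj = simulate_therapy(reg, truth.topologies[route], truth.pk_params[route],
                            pdp, t_end, dt=dt, T0=truth.t0_cells, events=events)
    true_vol = traj.at(days, traj.tumor_mm3)

    rng = np.random.default_rng(spec.seed)
    noise = spec.noise
    factors = _lognormal_factors(rng, spec.n_mice, noise.animal_cv)
    rows = []
    for i in range(spec.n_mice):
        eps = rng.normal(0.0, 1.0, len(days))
        vals = true_vol * factors[i] * (1.0 + noise.proportional_cv * eps)
        if noise.additive_sd:
            vals = vals + rng.normal(0.0, noise.additive_sd, len(days))
        if noise.floor_at_zero:
            vals = np.maximum(vals, 0.0)
        for j, (day, v) in enumerate(zip(days, vals)):
            rows.append((i, day, float(v)))
            if v >= EUTHANASIA_MM3:
                break   # euthanized: no further measurements from this animal
    animals = pd.DataFrame(rows, columns=["animal", "time_days", "tumor_mm3"])

    times, means, sems, ns = [], [], [], []
    for day in days:
        obs = animals.loc[animals.time_days == day, "tumor_mm3"].values
        if len(obs) == 0:
            continue
        times.append(day)
        means.append(obs.mean())
        sems.append(obs.std(ddof=1) / np.sqrt(len(obs)) if len(obs) > 1 else 0.0)
        ns.append(len(obs))
    if len(times) < 2:
        import warnings

        warnings.warn("degenerate cohort: fewer than two time points survive "
                      "censoring", stacklevel=2)
    label = f"{spec.tumor_type}-{reg.label or 'arm'}-{spec.neutralization}"
    dataset = TimeSeriesDataset(np.array(times), np.array(means),
                                np.array(sems), np.array(ns), arm=label)
    return dataset, animals


def make_training_bundle(truth: GroundTruth | None = None, seed: int = 0,
                         noise: NoiseModel | None = None, n_mice: int = 8,
                         pk_dose_ug: float = 50.0,
                         dt: float = 0.002) -> tuple[TrainingBundle, dict]:
    """All arms the sequential protocol needs, plus held-out validation.

    Training: single-dose PK per route; B16 early-onset PBS control;
    T-cell- and NK-neutralized treated arms; early-onset 50 µg/day treated
    arms via SC and IP.  Validation (never fit): the late-onset (day 8)
    treated arm and a low-dose (12 µg/day) arm.  Returns the bundle and a
    manifest from which the identical bundle can be regenerated.
    """
    if truth is None:
        truth = default_ground_truth()
    if noise is None:
        noise = NoiseModel(proportional_cv=0.05, animal_cv=0.10)
    routes = [r for r in ("SC", "IP") if r in truth.pk_params]
    pk_routes = list(truth.pk_params)

    pk_profiles = {
        r: generate_pk_profiles(r, pk_dose_ug, PK_SAMPLING_DAYS,
                                truth.topologies[r], truth.pk_params[r],
                                noise, n_mice=6, seed=seed + 11 + i, dt=dt)
        for i, r in enumerate(pk_routes)
    }

    std = standard_b16_regimen()
    pbs = std.replace(dose_ug=0.0, n_doses=0, label="PBS")
    late = std.replace(onset_day=8.0, label="50ug-daily-late")
    low = std.replace(dose_ug=12.0, label="12ug-daily")

    def cohort(reg, neut, s):
        spec = CohortSpec(regimen=reg, n_mice=n_mice, noise=noise,
                          neutralization=neut, seed=s)
        return generate_tumor_cohort(spec, truth, dt=dt)[0]

    treated = {}
    for i, r in enumerate(routes):
        reg_r = std.replace(route=r, label=f"50ug-daily-{r}")
        treated[r] = cohort(reg_r, "none", seed + 31 + i)

    late_days = tuple(d for d in (8.0, 10.0, 13.0, 15.0, 17.0, 20.0, 22.0, 24.0, 27.0))
    late_spec = CohortSpec(regimen=late, n_mice=n_mice, noise=noise,
                           measurement_days=late_days, seed=seed + 71)
    late_ds = generate_tumor_cohort(late_spec, truth, dt=dt)[0]

    bundle = TrainingBundle(
        topologies=dict(truth.topologies),
        pk_profiles=pk_profiles,
        pk_dose_ug=pk_dose_ug,
        pbs_control=cohort(pbs, "none", seed + 41),
        tcell_neutralized=cohort(std.replace(label="50ug-daily-Tneut"),
                                 "Tcell", seed + 51),
        nk_neutralized=cohort(std.replace(label="50ug-daily-NKneut"),
                              "NK", seed + 61),
        treated=treated,
        regimens={"pbs": pbs, "neutralized": std,
                  **{f"treated_{r}": std.replace(route=r) for r in routes}},
        t0_cells=truth.t0_cells,
        validation={
            "late_onset": (late, late_ds, "SC"),
            "low_dose": (low, cohort(low, "none", seed + 81), "SC"),
        },
    )
    manifest = {
        "seed": seed,
        "n_mice": n_mice,
        "pk_dose_ug": pk_dose_ug,
        "dt": dt,
        "noise": {"proportional_cv": noise.proportional_cv,
                  "additive_sd": noise.additive_sd,
                  "animal_cv": noise.animal_cv,
                  "floor_at_zero": noise.floor_at_zero},
        "ground_truth": {
            "t0_cells": truth.t0_cells,
            "pd": {f.name: getattr(truth.pd_params, f.name)
                   for f in truth.pd_params.__dataclass_fields__.values()},
            "pk": {r: pk_params_to_dict(truth.pk_params[r]) for r in pk_routes},
            "topologies": {r: topology_to_dict(truth.topologies[r])
                           for r in pk_routes},
            "routes": pk_routes,
        },
    }
    return bundle, manifest


def bundle_from_manifest(manifest: dict) -> TrainingBundle:
    """Regenerate the identical bundle recorded by :func:`make_training_bundle`.

    The manifest pins the seed, cohort sizes, noise model and every
    ground-truth parameter (PK rates, topologies, PD constants).
    """
    gt = manifest["ground_truth"]
    routes = gt["routes"]
    pd_params = PDParams(**gt["pd"])
    truth = GroundTruth(
        topologies={r: topology_from_dict(gt["topologies"][r]) for r in routes},
        pk_params={r: pk_params_from_dict(gt["pk"][r]) for r in routes},
        pd_params=pd_params,
        t0_cells=gt["t0_cells"],
    )
    n = manifest["noise"]
    noise = NoiseModel(proportional_cv=n["proportional_cv"],
                       additive_sd=n["additive_sd"],
                       animal_cv=n["animal_cv"],
                       floor_at_zero=n["floor_at_zero"])
    bundle, _ = make_training_bundle(truth, seed=manifest["seed"], noise=noise,
                                     n_mice=manifest["n_mice"],
                                     pk_dose_ug=manifest["pk_dose_ug"],
                                     dt=manifest["dt"])
    return bundle
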