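"""Default model parameterizations ("calibrated-style" presets).

These presets are the package's own plausible-range murine parameter sets,
constructed so the default B16 model exhibits the qualitative systemic
IL-21 phenomenology: a short serum half-life after a 50 µg dose, strong NK
suppression with CTL-dominant killing (k2 = 10*k1), an early-onset
advantage, a fractionation benefit that saturates around a 12-hour
inter-dosing interval, and a 5–50 µg/day efficacy plateau.  They also
serve as the ground truth behind the synthetic-data generator.

PD presets: ``B16-early``, ``B16-late``, ``RenCa-early``, ``RenCa-late``.
Growth parameters (r, K) differ per tumor type x onset dataset; sigma and
d_max differ per tumor type (B16 non-immunogenic, RenCa moderately
immunogenic); all other immune constants are shared.
"""

from __future__ import annotations

from .pd import PDParams
from .pk import PKParams, PKTopology, depot_topology, iv_topology
from .regimen import Regimen

__all__ = [
    "default_topology",
    "default_pk_params",
    "default_pd_params",
    "default_model",
    "standard_b16_regimen",
    "fractionated_b16_regimen",
    "PD_PRESETS",
]

# ---------------------------------------------------------------------------
# PK presets (time unit: days; amounts in µg; concentrations in µg/ml)

#: route-specific plasma:tissue ratios, inside the realistic [1, 100] band
DEFAULT_S = {"SC": 30.0, "IP": 20.0, "IV": 25.0}


def default_topology(route: str) -> PKTopology:
    return iv_topology() if route == "IV" else depot_topology(route)


def default_pk_params(route: str) -> PKParams:
    """Plausible murine IL-21 kinetics for one route.

    Plasma elimination ~16/day (terminal half-life ~1-2 h); depot absorption
    split between a fast shortcut and a slower 3-compartment chain, giving
    SC/IP plasma peaks of a few µg/ml after a 50 µg dose.  Mild saturation
    on SC absorption and on secondary-tissue degradation reflects the
    partly nonlinear transport the cytokine shows at this dose.
    """
    if route == "IV":
        w = {}
        alpha = {}
        for sec, (wo, wb) in {"sec1": (0.6, 18.0), "sec2": (0.4, 16.0),
                              "sec3": (0.25, 14.0)}.items():
            w[("plasma", sec)] = wo
            w[(sec, "plasma")] = wb
            alpha[("plasma", sec)] = 0.0
            alpha[(sec, "plasma")] = 0.0
        d = {"plasma": 16.0, "sec1": 3.0, "sec2": 2.5, "sec3": 2.0}
        beta = {"plasma": 0.0, "sec1": 0.05, "sec2": 0.05, "sec3": 0.05}
        return PKParams(w=w, alpha=alpha, d=d, beta=beta,
                        s=DEFAULT_S["IV"], v_plasma=2.0)
    if route not in ("SC", "IP"):
        raise ValueError(f"unknown route {route!r}")
    w = {
        ("depot", "abs1"): 9.0,
        ("abs1", "abs2"): 16.0,
        ("abs2", "abs3"): 16.0,
        ("abs3", "plasma"): 16.0,
        ("depot", "plasma"): 3.0,
        ("plasma", "sec1"): 0.6,
        ("sec1", "plasma"): 18.0,
        ("plasma", "sec2"): 0.4,
        ("sec2", "plasma"): 16.0,
        ("plasma", "sec3"): 0.25,
        ("sec3", "plasma"): 14.0,
    }
    alpha = {k: 0.0 for k in w}
    if route == "SC":
        # SC absorption is partly saturable; IP is satisfied by linear transport
        alpha[("depot", "abs1")] = 0.01
        alpha[("depot", "plasma")] = 0.01
    d = {"plasma": 16.0, "sec1": 3.0, "sec2": 2.5, "sec3": 2.0}
    beta = {"plasma": 0.0, "sec1": 0.05, "sec2": 0.05, "sec3": 0.05}
    return PKParams(w=w, alpha=alpha, d=d, beta=beta,
                    s=DEFAULT_S[route], v_plasma=2.0)


# ---------------------------------------------------------------------------
# PD presets

#: immune constants shared across tumor types
_SHARED_IMMUNE = dict(
    influx_nk=2.0e6,      # cells/day
    death_nk=0.2,         # 1/day -> baseline NK pool 1e7
    drug_death_nk=3.0,    # 1/day at saturating drug
    h_nk=0.05,            # µg/ml (peak-level sensing)
    mem_gain=1.0,         # memory units/day at saturating drug
    h_mem=0.002,          # µg/ml (coverage-time sensing)
    mem_decay=0.5,        # 1/day (weeks-scale commitment turnover)
    influx_ctl=5.0,       # cells/day -> baseline CTL seed 10 cells
    death_ctl=0.5,        # 1/day
    prot_base_nk=0.0,     # cytotoxic proteins are drug-induced
    prot_gain_nk=1.5,
    h_prot_nk=0.002,
    prot_decay_nk=3.0,    # 1/day (hours-scale protein turnover)
    prot_base_ctl=0.0,
    prot_gain_ctl=1.0,
    h_prot_ctl=0.008,
    prot_decay_ctl=3.0,
)

#: tumor-type response intensity (sigma, 1/(memory*day)) and CTL ceiling (cells)
_TUMOR_IMMUNOGENICITY = {
    "B16": dict(sigma=1.5, d_max=1.0e6),
    "RenCa": dict(sigma=2.0, d_max=2.0e6),
}

#: effector-tumor affinities; CTL-dominant configuration k2 = 10*k1
_AFFINITIES = dict(k1=2.0e-8, k2=2.0e-7)

#: growth parameters per (tumor type x onset dataset)
_GROWTH = {
    "B16-early": dict(r=0.52, K=3.0e9),
    "B16-late": dict(r=0.47, K=3.0e9),
    "RenCa-early": dict(r=0.40, K=2.5e9),
    "RenCa-late": dict(r=0.36, K=2.5e9),
}

PD_PRESETS = tuple(_GROWTH)


def default_pd_params(preset: str = "B16-early", equal_balance: bool = False) -> PDParams:
    """One of the named PD presets.

    ``equal_balance=True`` switches from the CTL-dominant affinities to the
    k1 = k2 configuration (set at the geometric mean of the dominant pair),
    mirroring the early-tumorigenesis sensitivity variant.
    """
    if preset not in _GROWTH:
        raise KeyError(f"unknown PD preset {preset!r}; choose from {PD_PRESETS}")
    tumor = preset.split("-")[0]
    kw = dict(_SHARED_IMMUNE)
    kw.update(_TUMOR_IMMUNOGENICITY[tumor])
    kw.update(_AFFINITIES)
    kw.update(_GROWTH[preset])
    p = PDParams(**kw)
    if equal_balance:
        k_eq = (p.k1 * p.k2) ** 0.5
        p = p.copy(k1=k_eq, k2=k_eq)
    return p


def default_model(route: str = "SC", preset: str = "B16-early"):
    """Convenience bundle of default topology + PK + PD for one route."""
    from .simulate import TherapyModel

    return TherapyModel(
        topology=default_topology(route),
        pk_params=default_pk_params(route),
        pd_params=default_pd_params(preset),
        label=f"{preset}/{route}",
    )


def standard_b16_regimen() -> Regimen:
    """The reference B16 schedule: 16 SC injections of 50 µg from day 3."""
    return Regimen(route="SC", dose_ug=50.0, onset_day=3.0, interval_days=1.0,
                   n_doses=16, label="50ug-daily")


def fractionated_b16_regimen() -> Regimen:
    """Iso-dose fractionation of the standard schedule: 32 x 25 µg every 12 h."""
    return Regimen(route="SC", dose_ug=25.0, onset_day=3.0, interval_days=0.5,
                   n_doses=32, label="25ug-q12h")
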