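"""Dosing regimens and their expansion to timestamped bolus events."""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

__all__ = ["Regimen", "DoseEvent", "expand_regimen", "volume_from_diameters"]


class DoseEvent(NamedTuple):
    time_day: float
    compartment: str   # "depot" for SC/IP, "plasma" for IV
    amount_ug: float


@dataclass(frozen=True)
class Regimen:
    """A repeated-bolus schedule.

    ``interval_days`` examples: 1.0 daily, 0.5 twice daily (12-h interval),
    7/3 for a 3x/week schedule.  ``n_doses = 0`` is a PBS/vehicle control.
    """

    route: str                  # "IV", "SC" or "IP"
    dose_ug: float
    onset_day: float
    interval_days: float = 1.0
    n_doses: int = 1
    label: str = ""

    def __post_init__(self):
        if self.route not in ("IV", "SC", "IP"):
            raise ValueError(f"unknown route {self.route!r}")
        if self.dose_ug < 0:
            raise ValueError("dose_ug must be non-negative")
        if self.n_doses < 0:
            raise ValueError("n_doses must be non-negative")
        if self.interval_days <= 0:
            raise ValueError("interval_days must be positive")

    @property
    def total_dose(self) -> float:
        return self.dose_ug * self.n_doses

    @property
    def last_dose_day(self) -> float:
        if self.n_doses == 0:
            return self.onset_day
        return self.onset_day + (self.n_doses - 1) * self.interval_days

    def replace(self, **kw) -> "Regimen":
        return replace(self, **kw)


def expand_regimen(regimen: Regimen) -> list[DoseEvent]:
    """Expand a regimen into its bolus events.

    SC/IP doses land in the administration depot, IV doses directly in
    plasma.  An ``n_doses = 0`` (control) regimen expands to no events.
    """
    target = "plasma" if regimen.route == "IV" else "depot"
    return [
        DoseEvent(regimen.onset_day + k * regimen.interval_days, target, regimen.dose_ug)
        for k in range(regimen.n_doses)
    ]


def volume_from_diameters(d1: float, d2: float) -> float:
    """Tumor volume (mm^3) from two perpendicular caliper diameters (mm).

    Standard murine ellipsoid approximation: length * width^2 / 2, with
    length the larger of the two diameters.
    """
    if d1 < 0 or d2 < 0:
        raise ValueError("diameters must be non-negative")
    lo, hi = (d1, d2) if d1 <= d2 else (d2, d1)
    return hi * lo * lo / 2.0
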