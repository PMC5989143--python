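"""Population and hospital-level scaling of per-patient model outputs.

Per-patient incremental costs and QALYs are multiplied up to a national
case count (incidence x population x adoption window) and down to a
single hospital's annual budget, including the break-even patient count
at which the bundle outlay pays for itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "PopulationFrame",
    "total_cases",
    "scale_national",
    "format_national",
    "hospital_budget",
    "breakeven_patients",
    "US_POPULATION",
    "US_SEPSIS_INCIDENCE_PER_100K",
    "ADOPTION_WINDOW_YEARS",
]

#: US population used for national scaling.  Not itself a reported input;
#: it is the unique round figure consistent with the reference national
#: totals (300/100k x 325M x 2.5y x $6,115 ~ $14.9bn).  Overridable.
US_POPULATION = 325_000_000.0

#: Annual severe-sepsis incidence, cases per 100,000 population.
US_SEPSIS_INCIDENCE_PER_100K = 300.0

#: Years between early adoption and the arrival of definitive trial
#: evidence — the window over which the opportunity cost accrues.
ADOPTION_WINDOW_YEARS = 2.5


@dataclass(frozen=True)
class PopulationFrame:
    """Incidence, population and accrual window for national scaling."""

    incidence_per_100k: float = US_SEPSIS_INCIDENCE_PER_100K
    population: float = US_POPULATION
    horizon_years: float = ADOPTION_WINDOW_YEARS

    def __post_init__(self) -> None:
        for name in ("incidence_per_100k", "population", "horizon_years"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def total_cases(frame: PopulationFrame) -> float:
    """Expected sepsis cases over the frame's window:
    incidence/100k x population x years."""
    return frame.incidence_per_100k / 100_000.0 * frame.population * frame.horizon_years


def scale_national(per_patient_value: float, cases: float) -> float:
    """Total national consequence of a per-patient value (USD or QALY).

    Linear: the raw product is returned; use :func:`format_national` for
    the one-decimal billions/millions display convention.
    """
    if cases < 0:
        raise ValueError("cases must be nonnegative")
    return per_patient_value * cases


def format_national(value: float, kind: str) -> str:
    """Display a national total as the field reports them: USD in
    billions ("$14.9bn", sign in front of the $) and QALYs in millions
    ("3.6m"), one decimal."""
    if kind == "usd":
        sign = "-" if value < 0 else ""
        return f"{sign}${abs(value) / 1e9:.1f}bn"
    if kind == "qaly":
        return f"{value / 1e6:.1f}m"
    raise ValueError(f"unknown kind {kind!r}; expected 'usd' or 'qaly'")


def hospital_budget(patients_per_year: float, c_bundle: float) -> float:
    """Annual bundle outlay for a hospital treating ``patients_per_year``
    sepsis patients."""
    if patients_per_year <= 0 or c_bundle <= 0:
        raise ValueError("patients_per_year and c_bundle must be positive")
    return patients_per_year * c_bundle


def breakeven_patients(annual_outlay: float, per_patient_saving: float) -> int:
    """Smallest number of patients for whom the bundle must be effective
    so that the per-patient saving covers the annual outlay."""
    if per_patient_saving <= 0:
        raise ValueError(
            "per_patient_saving must be positive; no break-even exists otherwise"
        )
    if annual_outlay < 0:
        raise ValueError("annual_outlay must be nonnegative")
    return math.ceil(annual_outlay / per_patient_saving)
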