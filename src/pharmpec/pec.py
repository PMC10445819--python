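"""Surface-water predicted environmental concentrations from annual sales mass.

The screening model distributes a year's sold mass of an API into the
nation's wastewater and dilutes it into receiving waters:

    PEC_SW = M × (1 − f_removal) / (365 × Q_ww × P × D)

where M is grams of API sold in the year, f_removal the fraction removed at
wastewater treatment (worst-case default 0), Q_ww the per-capita wastewater
volume in litres per person per day, P the population, and D the dilution
factor between effluent and receiving water (default 10).  The result is a
concentration in g L⁻¹, conventionally also reported in ng L⁻¹.

The defaults are deliberately conservative: zero removal and zero human
metabolism overestimate exposure for well-removed APIs, and the dilution
factor of 10 is below the 50–75 achieved by deep coastal outfalls, so the
model is a worst-case screen, not a fate simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .filters import AnnualAPIWeight

__all__ = [
    "PECParameters",
    "PECResult",
    "compute_pec",
    "per_capita_weight",
    "pec_table",
    "write_pec",
]

DAYS_PER_YEAR = 365.0


@dataclass(frozen=True)
class PECParameters:
    """Inputs of the surface-water PEC equation.

    ``wastewater_consumption`` is in L person⁻¹ day⁻¹ (200 is the standard
    guideline default; national statistics provide per-year values for
    reproduction runs), ``population`` in persons, ``dilution_factor``
    unitless (≥ 1), ``wwtp_removal`` a fraction in [0, 1].
    """

    wwtp_removal: float = 0.0
    wastewater_consumption: float = 200.0
    population: float = 5_000_000.0
    dilution_factor: float = 10.0
    days_per_year: float = DAYS_PER_YEAR

    def __post_init__(self) -> None:
        if not 0.0 <= self.wwtp_removal <= 1.0:
            raise ValueError("wwtp_removal must be within [0, 1]")
        for name in ("wastewater_consumption", "population", "dilution_factor", "days_per_year"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class PECResult:
    """A surface-water concentration for one API in one year, inputs echoed."""

    api_name: str
    year: int
    pec_g_per_L: float
    grams_sold: float
    params: PECParameters

    @property
    def pec_ng_per_L(self) -> float:
        return self.pec_g_per_L * 1e9


def compute_pec(weight: AnnualAPIWeight, params: PECParameters) -> PECResult:
    """Evaluate the PEC equation for one annual API mass.

    Raises ``ValueError`` for non-finite or negative sold mass; the result
    is zero exactly when the mass is zero or removal is complete.
    """
    grams = weight.grams
    if not math.isfinite(grams) or grams < 0:
        raise ValueError(f"{weight.api_name}/{weight.year}: grams must be finite and >= 0")
    denominator = (
        params.days_per_year
        * params.wastewater_consumption
        * params.population
        * params.dilution_factor
    )
    pec = grams * (1.0 - params.wwtp_removal) / denominator
    return PECResult(
        api_name=weight.api_name,
        year=weight.year,
        pec_g_per_L=pec,
        grams_sold=grams,
        params=params,
    )


def per_capita_weight(weight: AnnualAPIWeight, population: float) -> float:
    """Grams sold per person per year, for cross-study trend comparison."""
    if not population > 0:
        raise ValueError("population must be strictly positive")
    return weight.grams / population


def pec_table(
    weights: Iterable[AnnualAPIWeight],
    params_by_year: Mapping[int, PECParameters] | PECParameters,
) -> pd.DataFrame:
    """PECs for a whole weights dataset, with per-year parameters.

    ``params_by_year`` may be a single parameter set applied to every year
    or a mapping year → parameters (population and wastewater volume vary
    between years in national statistics).
    """
    rows = []
    for w in weights:
        params = (
            params_by_year
            if isinstance(params_by_year, PECParameters)
            else params_by_year[w.year]
        )
        r = compute_pec(w, params)
        rows.append(
            {
                "api_name": r.api_name,
                "year": r.year,
                "grams": r.grams_sold,
                "pec_g_per_L": r.pec_g_per_L,
                "pec_ng_per_L": r.pec_ng_per_L,
            }
        )
    return pd.DataFrame(
        rows, columns=["api_name", "year", "grams", "pec_g_per_L", "pec_ng_per_L"]
    )


def write_pec(path: str | Path, table: pd.DataFrame) -> None:
    """Write PEC output with 4-significant-digit scientific notation."""
    table.to_csv(path, index=False, float_format="%.4g")
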