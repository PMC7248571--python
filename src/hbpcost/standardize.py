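"""Standardisation of raw study unit costs to 2016 USD for a target setting.

Pipeline: currency conversion at the study's market exchange rate,
inflation to 2016 with a deflator-style index, GNI-per-capita transfer of
the non-traded component, and annualisation of per-episode costs.

Exchange-rate dollars are used throughout (no PPP adjustment). The
bundled ``indices.csv`` series is a documented stand-in deflator and FX
table covering 1990–2016; callers may supply their own
:class:`PriceIndexSeries`.
"""

from __future__ import annotations

import dataclasses
from functools import lru_cache
from importlib import resources
from typing import Mapping

import pandas as pd

from .registry import CostBasis, UnitCostRecord

__all__ = [
    "PriceIndexSeries",
    "default_indices",
    "to_usd_2016",
    "transfer_unit_cost",
    "annualize",
    "standardized_annual_cost",
]

BASE_YEAR = 2016


@dataclasses.dataclass(frozen=True)
class PriceIndexSeries:
    """Deflator index (base year 2016 == 1.0) plus a USD exchange-rate table."""

    index: Mapping[int, float]  # year -> index value
    fx: Mapping[tuple[str, int], float]  # (currency, year) -> USD per unit
    base_year: int = BASE_YEAR

    def __post_init__(self) -> None:
        if self.base_year not in self.index:
            raise ValueError(f"base year {self.base_year} missing from index")
        for year, value in self.index.items():
            if value <= 0:
                raise ValueError(f"index value for {year} must be > 0, got {value}")


@lru_cache(maxsize=1)
def default_indices() -> PriceIndexSeries:
    """Bundled deflator/FX series (stand-in; override via ``indices.csv``)."""
    with resources.files("hbpcost.data").joinpath("indices.csv").open() as fh:
        df = pd.read_csv(fh)
    return indices_from_frame(df)


def indices_from_frame(df: pd.DataFrame) -> PriceIndexSeries:
    """Build a :class:`PriceIndexSeries` from (year, index, currency, fx_rate) rows."""
    index: dict[int, float] = {}
    fx: dict[tuple[str, int], float] = {}
    for _, row in df.iterrows():
        year = int(row["year"])
        index.setdefault(year, float(row["index"]))
        fx[(str(row["currency"]), year)] = float(row["fx_rate"])
    return PriceIndexSeries(index=index, fx=fx)


def to_usd_2016(
    value: float,
    currency: str,
    price_year: int,
    indices: PriceIndexSeries | None = None,
) -> float:
    """Convert a study cost to base-year (2016) US dollars.

    result = value × fx(currency, price_year) × index(2016) / index(price_year)
    """
    indices = indices or default_indices()
    key = (currency, price_year)
    if key not in indices.fx:
        raise KeyError(f"no exchange rate for currency/year {key!r}")
    if price_year not in indices.index:
        raise KeyError(f"no price index for year {price_year}")
    usd = value * indices.fx[key]
    return usd * indices.index[indices.base_year] / indices.index[price_year]


def transfer_unit_cost(
    cost_usd2016: float,
    traded_fraction: float,
    source_gni_pc: float,
    target_gni_pc: float,
) -> float:
    """Transfer a standardised cost from its source setting to a target group.

    The traded component is kept at world-market prices; the non-traded
    component is scaled by the ratio of per-capita GNI:

    result = cost × [f + (1 − f) × target_gni_pc / source_gni_pc]
    """
    if not 0.0 <= traded_fraction <= 1.0:
        raise ValueError(f"traded_fraction {traded_fraction} outside [0, 1]")
    if source_gni_pc <= 0 or target_gni_pc <= 0:
        raise ValueError("GNI per capita must be > 0")
    return cost_usd2016 * (
        traded_fraction + (1.0 - traded_fraction) * target_gni_pc / source_gni_pc
    )


def annualize(unit_cost: UnitCostRecord) -> float:
    """Express a standardised unit cost per beneficiary-year.

    Per-patient-year costs pass through; per-episode costs are multiplied
    by the annual episode rate.
    """
    if unit_cost.cost_basis is CostBasis.PER_PATIENT_YEAR:
        return unit_cost.value
    if unit_cost.episodes_per_beneficiary_year is None:
        raise ValueError("per_episode cost without episodes_per_beneficiary_year")
    return unit_cost.value * unit_cost.episodes_per_beneficiary_year


def standardized_annual_cost(
    unit_cost: UnitCostRecord,
    traded_fraction: float,
    target_gni_pc: float,
    indices: PriceIndexSeries | None = None,
) -> float:
    """Full pipeline: raw record → USD(2016) → GNI transfer → per beneficiary-year."""
    usd = to_usd_2016(
        unit_cost.value, unit_cost.currency, unit_cost.price_year, indices
    )
    transferred = transfer_unit_cost(
        usd, traded_fraction, unit_cost.source_gni_per_capita, target_gni_pc
    )
    return annualize(dataclasses.replace(unit_cost, value=transferred))
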