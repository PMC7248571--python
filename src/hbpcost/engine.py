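"""Counterfactual costing engine.

Given a validated registry, computes baseline, incremental and total
annual service-delivery (SD) costs per intervention per country group at
a counterfactual coverage target (default 80%), de-duplicated and
package-level aggregates, and health-system markups on de-duplicated
totals.

Conventions:

* baseline cost  = annual unit cost × population in need × baseline coverage
* total cost     = same at max(baseline, target) coverage when negative
  increments are clamped (the default: coverage above target is
  maintained, not cut), else at the target
* incremental    = total − baseline
* markups apply to de-duplicated totals only; package rows carry
  service-delivery costs.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Iterable, Sequence

import pandas as pd

from .registry import CountryGroup, Intervention, Registry
from .standardize import PriceIndexSeries, standardized_annual_cost

__all__ = [
    "CoveragePolicy",
    "MarkupConfig",
    "CostResult",
    "annual_unit_cost",
    "annual_sd_cost",
    "cost_intervention",
    "compute_costs",
    "dedup_total",
    "package_total",
    "apply_markups",
    "grand_total",
    "per_capita",
    "share_of_gni",
]

Selector = Callable[[Intervention], bool]


@dataclasses.dataclass(frozen=True)
class CoveragePolicy:
    """Counterfactual coverage target and clamping behaviour."""

    target_coverage: float = 0.80
    clamp_negative_increments: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.target_coverage <= 1.0:
            raise ValueError(
                f"target_coverage must be in (0, 1], got {self.target_coverage}"
            )


@dataclasses.dataclass(frozen=True)
class MarkupConfig:
    """Facility and above-facility markups on de-duplicated SD cost.

    The defaults (0.45 + 0.298 = 0.748) are jointly calibrated so the
    health-system share of the grand total is 42.8%; the facility /
    above-facility split is configuration, the sum is the calibrated
    quantity. In-service training is assumed to live inside the markups.
    """

    facility_markup: float = 0.45
    above_facility_markup: float = 0.298

    def __post_init__(self) -> None:
        if self.facility_markup < 0 or self.above_facility_markup < 0:
            raise ValueError("markups must be >= 0")

    @property
    def combined(self) -> float:
        return self.facility_markup + self.above_facility_markup


@dataclasses.dataclass(frozen=True)
class CostResult:
    """Per-(intervention, group) cost rows plus the inputs that produced them.

    ``rows`` columns: intervention_id, group, platform, timing, objective,
    hpp, baseline_sd, incremental_sd, total_sd (all USD/yr).
    """

    rows: pd.DataFrame
    registry: Registry
    policy: CoveragePolicy
    markups: MarkupConfig

    @property
    def group_ids(self) -> list[str]:
        return [g.id for g in self.registry.groups]


def annual_unit_cost(
    intervention: Intervention,
    group: CountryGroup,
    indices: PriceIndexSeries | None = None,
) -> float:
    """Standardised, annualised unit cost (USD/beneficiary-year) for one group."""
    rec = intervention.records[group.id]
    return standardized_annual_cost(
        rec.unit_cost, rec.traded_fraction, group.gni_per_capita, indices
    )


def annual_sd_cost(
    intervention: Intervention,
    group: CountryGroup,
    coverage: float,
    indices: PriceIndexSeries | None = None,
) -> float:
    """Annual service-delivery cost at the given coverage of population in need."""
    if not 0.0 <= coverage <= 1.0:
        raise ValueError(f"coverage {coverage} outside [0, 1]")
    rec = intervention.records[group.id]
    return annual_unit_cost(intervention, group, indices) * rec.population_in_need * coverage


def cost_intervention(
    intervention: Intervention,
    group: CountryGroup,
    policy: CoveragePolicy | None = None,
    indices: PriceIndexSeries | None = None,
) -> tuple[float, float, float]:
    """(baseline_sd, incremental_sd, total_sd) for one intervention and group."""
    policy = policy or CoveragePolicy()
    rec = intervention.records[group.id]
    baseline = annual_sd_cost(intervention, group, rec.baseline_coverage, indices)
    cov_total = (
        max(rec.baseline_coverage, policy.target_coverage)
        if policy.clamp_negative_increments
        else policy.target_coverage
    )
    total = annual_sd_cost(intervention, group, cov_total, indices)
    return baseline, total - baseline, total


def compute_costs(
    registry: Registry,
    policy: CoveragePolicy | None = None,
    markups: MarkupConfig | None = None,
    indices: PriceIndexSeries | None = None,
    select: Selector | str | None = None,
) -> CostResult:
    """Cost every (intervention, group) cell of the registry.

    ``select`` restricts the costed set: ``"hpp"`` keeps flagged
    interventions only, a callable keeps those it accepts. The same
    engine runs either way — there is no separate package-set code path.
    """
    policy = policy or CoveragePolicy()
    markups = markups or MarkupConfig()
    if select == "hpp":
        registry = registry.hpp_subset
    elif select == "euhc" or select is None:
        pass
    elif callable(select):
        registry = registry.subset(select)
    else:
        raise ValueError(f"unknown selection {select!r}")

    rows = []
    for iv in registry.interventions:
        for group in registry.groups:
            baseline, incremental, total = cost_intervention(
                iv, group, policy, indices
            )
            rows.append(
                {
                    "intervention_id": iv.id,
                    "group": group.id,
                    "platform": iv.platform.value,
                    "timing": iv.timing.value,
                    "objective": iv.objective.value,
                    "hpp": iv.hpp,
                    "baseline_sd": baseline,
                    "incremental_sd": incremental,
                    "total_sd": total,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "intervention_id",
            "group",
            "platform",
            "timing",
            "objective",
            "hpp",
            "baseline_sd",
            "incremental_sd",
            "total_sd",
        ],
    )
    return CostResult(rows=df, registry=registry, policy=policy, markups=markups)


def _select_rows(
    results: CostResult,
    interventions: Iterable[str] | None,
    groups: Iterable[str] | None,
) -> pd.DataFrame:
    df = results.rows
    if interventions is not None:
        wanted = set(interventions)
        known = set(df["intervention_id"])
        unknown = wanted - known
        if unknown:
            raise KeyError(f"unknown intervention ids: {sorted(unknown)}")
        df = df[df["intervention_id"].isin(wanted)]
    if groups is not None:
        df = df[df["group"].isin(set(groups))]
    return df


def dedup_total(
    results: CostResult,
    interventions: Iterable[str] | None = None,
    groups: Iterable[str] | None = None,
    field: str = "total",
) -> float:
    """Sum a cost field over UNIQUE interventions in the selection.

    Membership in several packages never multiplies an intervention's
    cost; rows are already one per (intervention, group).
    """
    df = _select_rows(results, interventions, groups)
    return float(df[f"{field}_sd"].sum())


def package_total(
    results: CostResult,
    package_id: int,
    groups: Iterable[str] | None = None,
    field: str = "total",
) -> float:
    """Sum over interventions belonging to one package (duplication intended)."""
    if package_id not in results.registry.packages:
        raise KeyError(f"unknown package id {package_id}")
    members = [
        iv.id for iv in results.registry.interventions if package_id in iv.packages
    ]
    if not members:
        return 0.0
    return dedup_total(results, interventions=members, groups=groups, field=field)


def apply_markups(dedup_sd: float, markups: MarkupConfig) -> tuple[float, float]:
    """(health_system, grand_total) from a de-duplicated SD total."""
    if dedup_sd < 0:
        raise ValueError("dedup_sd must be >= 0")
    health_system = dedup_sd * markups.combined
    return health_system, dedup_sd + health_system


def grand_total(
    results: CostResult,
    groups: Iterable[str] | None = None,
    field: str = "total",
) -> float:
    """De-duplicated SD total plus health-system markups."""
    sd = dedup_total(results, groups=groups, field=field)
    return apply_markups(sd, results.markups)[1]


def per_capita(cost: float, group: CountryGroup) -> float:
    """Annual cost per person in the group."""
    if group.population <= 0:
        raise ValueError("population must be > 0")
    return cost / group.population


def share_of_gni(cost: float, group: CountryGroup) -> float:
    """Annual cost as a proportion of the group's GNI (decimal, not %)."""
    if group.gni_total <= 0:
        raise ValueError("gni_total must be > 0")
    return cost / group.gni_total
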