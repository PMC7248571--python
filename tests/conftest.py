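"""Shared builders and fixtures.

All test registries are built programmatically; nothing binary is read
from disk.
"""

from __future__ import annotations

import pytest

from hbpcost.registry import (
    CostBasis,
    CountryGroup,
    GroupRecord,
    Intervention,
    Objective,
    Platform,
    Registry,
    Timing,
    UnitCostRecord,
)


def make_group(gid: str = "G", population: float = 1e6, gni_total: float = 1e9):
    return CountryGroup(gid, population, gni_total)


def make_record(
    group: CountryGroup,
    unit_value: float = 2.0,
    population_in_need: float = 1e6,
    baseline_coverage: float = 0.3,
    traded_fraction: float = 1.0,
    currency: str = "USD",
    price_year: int = 2016,
    source_gni_pc: float | None = None,
    cost_basis: CostBasis = CostBasis.PER_PATIENT_YEAR,
    episodes: float | None = None,
) -> GroupRecord:
    """Record whose standardisation is the identity by default:
    USD, base price year, fully traded inputs."""
    return GroupRecord(
        unit_cost=UnitCostRecord(
            value=unit_value,
            currency=currency,
            price_year=price_year,
            source_gni_per_capita=(
                group.gni_per_capita if source_gni_pc is None else source_gni_pc
            ),
            cost_basis=cost_basis,
            episodes_per_beneficiary_year=episodes,
        ),
        traded_fraction=traded_fraction,
        population_in_need=population_in_need,
        baseline_coverage=baseline_coverage,
    )


def make_intervention(
    iid: str,
    records: dict[str, GroupRecord],
    packages=frozenset({1}),
    platform: Platform = Platform.HEALTH_CENTRE,
    timing: Timing = Timing.CHRONIC,
    objective: Objective = Objective.DISABILITY,
    hpp: bool = False,
    pathology: bool = False,
    name: str | None = None,
) -> Intervention:
    return Intervention(
        id=iid,
        name=name or iid,
        packages=frozenset(packages),
        platform=platform,
        timing=timing,
        objective=objective,
        hpp=hpp,
        pathology=pathology,
        records=records,
    )


def make_registry(interventions, groups=None, packages=None) -> Registry:
    groups = tuple(groups) if groups else (make_group(),)
    if packages is None:
        pids = sorted({p for iv in interventions for p in iv.packages})
        packages = {p: f"Package {p}" for p in pids} or {1: "Package 1"}
    return Registry(tuple(interventions), groups, dict(packages))


@pytest.fixture
def group():
    return make_group()


@pytest.fixture
def single_intervention_registry(group):
    iv = make_intervention("a", {group.id: make_record(group)})
    return make_registry([iv], groups=[group])
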