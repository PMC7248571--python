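"""Seeded generator of essential-package-like registries.

Makes every other module testable offline: two stylised country groups,
a 218-intervention / 21-package / 115-flagged registry with overlapping
package membership, and a calibrated fixture whose incremental-cost
shares by platform and timing match published headline shares.

Dollar magnitudes of generated registries are NOT estimates of anything;
only structure (counts, overlaps, classification mix) and — for the
calibrated fixture — cost *shares* are meaningful.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np

from .engine import CoveragePolicy, compute_costs
from .registry import (
    CostBasis,
    CountryGroup,
    GroupRecord,
    Intervention,
    Objective,
    Platform,
    Registry,
    Timing,
    UnitCostRecord,
    validate_registry,
)

__all__ = [
    "stylized_groups",
    "default_package_names",
    "generate_registry",
    "calibrated_fixture",
    "PLATFORM_SHARE_TARGETS",
    "TIMING_SHARE_TARGETS",
]

# Stylised 2015 income groups: (population, total GNI) in USD.
_STYLIZED = (
    ("LIC", 0.90e9, 0.70e12),
    ("lower-MIC", 2.7e9, 5.9e12),
)

_PACKAGE_NAMES = [
    "Maternal and newborn health",
    "Child health",
    "School-age health and development",
    "Adolescent health and development",
    "Reproductive health and contraception",
    "HIV and STIs",
    "Tuberculosis",
    "Malaria and adult febrile illness",
    "Neglected tropical diseases",
    "Pandemic and emergency preparedness",
    "Cardiovascular, respiratory, and related disorders",
    "Cancer",
    "Mental, neurological, and substance use disorders",
    "Musculoskeletal disorders",
    "Congenital and genetic disorders",
    "Injury prevention",
    "Environmental improvement",
    "Surgery",
    "Rehabilitation",
    "Palliative care and pain control",
    "Pathology",
]

_PATHOLOGY_PACKAGE = 21

# Published incremental-cost share targets (combined groups) the
# calibrated fixture is reweighted toward.
PLATFORM_SHARE_TARGETS: Mapping[str, float] = {
    Platform.POPULATION_BASED.value: 0.016,
    Platform.COMMUNITY.value: 0.118,
    Platform.HEALTH_CENTRE.value: 0.498,
    Platform.FIRST_LEVEL_HOSPITAL.value: 0.310,
    Platform.REFERRAL_SPECIALTY_HOSPITAL.value: 0.058,
}
TIMING_SHARE_TARGETS: Mapping[str, float] = {
    Timing.URGENT.value: 0.285,
    Timing.CHRONIC.value: 0.455,
    Timing.TIME_BOUND.value: 0.260,
}

# Sampling weights for classification draws (counts, not cost shares).
_DEFAULT_WEIGHTS = {
    "platform": {
        Platform.POPULATION_BASED.value: 0.08,
        Platform.COMMUNITY.value: 0.22,
        Platform.HEALTH_CENTRE.value: 0.30,
        Platform.FIRST_LEVEL_HOSPITAL.value: 0.25,
        Platform.REFERRAL_SPECIALTY_HOSPITAL.value: 0.15,
    },
    "timing": {
        Timing.URGENT.value: 0.30,
        Timing.CHRONIC.value: 0.40,
        Timing.TIME_BOUND.value: 0.30,
    },
    # Proportional to published per-objective intervention counts.
    "objective": {
        Objective.UNDER5_MORTALITY.value: 52 / 218,
        Objective.MORTALITY_5_69_CMPN.value: 44 / 218,
        Objective.MORTALITY_5_69_NCDI.value: 45 / 218,
        Objective.DISABILITY.value: 58 / 218,
        Objective.NON_HEALTH.value: 19 / 218,
    },
}


def stylized_groups() -> list[CountryGroup]:
    """The two stylised 2015 income groups used throughout."""
    return [CountryGroup(gid, pop, gni) for gid, pop, gni in _STYLIZED]


def default_package_names(n_packages: int = 21) -> dict[int, str]:
    names = {}
    for i in range(n_packages):
        names[i + 1] = (
            _PACKAGE_NAMES[i] if i < len(_PACKAGE_NAMES) else f"Package {i + 1}"
        )
    return names


def _draw_category(rng: np.random.Generator, weights: Mapping[str, float]) -> str:
    cats = list(weights)
    probs = np.array([weights[c] for c in cats], dtype=float)
    return cats[rng.choice(len(cats), p=probs / probs.sum())]


def generate_registry(
    seed: int,
    n_interventions: int = 218,
    n_packages: int = 21,
    n_hpp: int = 115,
    overlap_rate: float = 0.25,
    dimension_weights: Mapping[str, Mapping[str, float]] | None = None,
    cost_range: tuple[float, float] = (0.5, 500.0),
    pin_range: tuple[float, float] = (0.001, 0.30),
) -> Registry:
    """Seeded random registry with the requested structural counts.

    ``overlap_rate`` is the per-extra-package Bernoulli probability, so
    expected membership multiplicity is roughly ``1 + 2 × overlap_rate``;
    at 0 every intervention sits in exactly one package. Unit costs are
    log-uniform over ``cost_range`` USD/beneficiary-year; populations in
    need are log-uniform fractions (``pin_range``) of group population;
    baseline coverages are Beta(2, 3). A fixed seed reproduces the
    registry exactly.
    """
    if n_hpp > n_interventions:
        raise ValueError("n_hpp cannot exceed n_interventions")
    if n_packages < 1 or n_interventions < 1:
        raise ValueError("counts must be >= 1")
    weights = {**_DEFAULT_WEIGHTS, **(dimension_weights or {})}
    rng = np.random.default_rng(seed)
    groups = stylized_groups()
    packages = default_package_names(n_packages)
    hpp_ids = set(rng.choice(n_interventions, size=n_hpp, replace=False).tolist())

    interventions = []
    for i in range(n_interventions):
        primary = int(rng.integers(1, n_packages + 1))
        extra = {
            int(p)
            for p in rng.integers(1, n_packages + 1, size=2)
            if rng.random() < overlap_rate
        }
        pkg_ids = frozenset({primary} | extra)
        pathology = primary == _PATHOLOGY_PACKAGE and n_packages >= _PATHOLOGY_PACKAGE
        platform = Platform(_draw_category(rng, weights["platform"]))
        timing = Timing(_draw_category(rng, weights["timing"]))
        objective = (
            Objective.UNALLOCATED
            if pathology
            else Objective(_draw_category(rng, weights["objective"]))
        )
        per_episode = timing is Timing.URGENT
        episodes = float(np.round(rng.uniform(1.0, 3.0), 3)) if per_episode else None
        base_cost = float(
            np.exp(rng.uniform(np.log(cost_range[0]), np.log(cost_range[1])))
        )
        source_gni_pc = float(np.exp(rng.uniform(np.log(500.0), np.log(15000.0))))
        price_year = int(rng.integers(2005, 2017))
        records = {}
        for g in groups:
            pin_frac = float(
                np.exp(rng.uniform(np.log(pin_range[0]), np.log(pin_range[1])))
            )
            records[g.id] = GroupRecord(
                unit_cost=UnitCostRecord(
                    value=base_cost * float(rng.uniform(0.8, 1.25)),
                    currency="USD",
                    price_year=price_year,
                    source_gni_per_capita=source_gni_pc,
                    cost_basis=(
                        CostBasis.PER_EPISODE if per_episode else CostBasis.PER_PATIENT_YEAR
                    ),
                    episodes_per_beneficiary_year=episodes,
                ),
                traded_fraction=float(rng.uniform(0.1, 0.6)),
                population_in_need=pin_frac * g.population,
                baseline_coverage=float(rng.beta(2.0, 3.0)),
            )
        interventions.append(
            Intervention(
                id=f"iv{i + 1:03d}",
                name=f"Intervention {i + 1}",
                packages=pkg_ids,
                platform=platform,
                timing=timing,
                objective=objective,
                hpp=i in hpp_ids,
                pathology=pathology,
                records=records,
            )
        )
    registry = Registry(tuple(interventions), tuple(groups), packages)
    diags = validate_registry(registry)
    if diags:  # generator bug, not user error
        raise AssertionError(f"generated registry invalid: {diags[:3]}")
    return registry


def _scale_unit_costs(registry: Registry, scale: np.ndarray) -> Registry:
    interventions = []
    for iv, s in zip(registry.interventions, scale):
        records = {
            gid: dataclasses.replace(
                rec,
                unit_cost=dataclasses.replace(
                    rec.unit_cost, value=rec.unit_cost.value * float(s)
                ),
            )
            for gid, rec in iv.records.items()
        }
        interventions.append(dataclasses.replace(iv, records=records))
    return dataclasses.replace(registry, interventions=tuple(interventions))


def calibrated_fixture(
    seed: int = 0,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> Registry:
    """Registry whose combined-group incremental shares hit the published
    platform and timing targets.

    Starts from :func:`generate_registry` and iteratively rescales each
    intervention's unit costs (iterative proportional fitting on the
    platform and timing margins of per-intervention incremental cost,
    which is linear in unit cost), so the default-policy incremental
    shares converge onto the targets. Pure function of the seed.
    """
    registry = generate_registry(seed)
    policy = CoveragePolicy()
    results = compute_costs(registry, policy)
    inc = (
        results.rows.groupby("intervention_id", sort=False)["incremental_sd"]
        .sum()
        .reindex([iv.id for iv in registry.interventions])
        .to_numpy()
    )
    platforms = np.array([iv.platform.value for iv in registry.interventions])
    timings = np.array([iv.timing.value for iv in registry.interventions])
    for cats, targets in (
        (platforms, PLATFORM_SHARE_TARGETS),
        (timings, TIMING_SHARE_TARGETS),
    ):
        for cat in targets:
            if inc[cats == cat].sum() <= 0:
                raise RuntimeError(
                    f"category {cat!r} has no incremental cost; reseed the fixture"
                )

    scale = np.ones(len(inc))
    for _ in range(max_iter):
        worst = 0.0
        for cats, targets in (
            (platforms, PLATFORM_SHARE_TARGETS),
            (timings, TIMING_SHARE_TARGETS),
        ):
            for cat, target_share in targets.items():
                weighted = inc * scale
                share = weighted[cats == cat].sum() / weighted.sum()
                worst = max(worst, abs(share - target_share))
                scale[cats == cat] *= target_share / share
        if worst < tol:
            break
    return _scale_unit_costs(registry, scale)
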