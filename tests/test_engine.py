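"""Costing engine: arithmetic examples, aggregation, and oracle properties."""

from __future__ import annotations

import dataclasses

import pytest

from hbpcost.engine import (
    CostResult,
    CoveragePolicy,
    MarkupConfig,
    annual_sd_cost,
    apply_markups,
    compute_costs,
    cost_intervention,
    dedup_total,
    grand_total,
    package_total,
    per_capita,
    share_of_gni,
)
from hbpcost.registry import CountryGroup
from hbpcost.report import round_sig
from hbpcost.standardize import default_indices
from hbpcost.synth import generate_registry

from conftest import make_group, make_intervention, make_record, make_registry


# ---------------------------------------------------------------------------
# independent brute-force oracle (plain arithmetic, no engine imports)

def oracle_rows(registry, target=0.8, clamp=True):
    """Re-derive every cost cell with explicit formula arithmetic."""
    idx = default_indices()
    out = {}
    for iv in registry.interventions:
        for g in registry.groups:
            rec = iv.records[g.id]
            uc = rec.unit_cost
            v = (
                uc.value
                * idx.fx[(uc.currency, uc.price_year)]
                * idx.index[2016]
                / idx.index[uc.price_year]
            )
            gni_pc = g.gni_total / g.population
            v = v * (
                rec.traded_fraction
                + (1 - rec.traded_fraction) * gni_pc / uc.source_gni_per_capita
            )
            if uc.cost_basis.value == "per_episode":
                v = v * uc.episodes_per_beneficiary_year
            baseline = v * rec.population_in_need * rec.baseline_coverage
            cov = max(rec.baseline_coverage, target) if clamp else target
            total = v * rec.population_in_need * cov
            out[(iv.id, g.id)] = (baseline, total - baseline, total)
    return out


def oracle_grand_total(registry, target=0.8, markup=0.748, field=2):
    cells = oracle_rows(registry, target)
    return sum(c[field] for c in cells.values()) * (1 + markup)


# ---------------------------------------------------------------------------
# examples

class TestAnnualSdCost:
    def test_multiplication(self, group):
        iv = make_intervention("a", {group.id: make_record(group, 2.0, 1e6)})
        assert annual_sd_cost(iv, group, 0.3) == pytest.approx(600_000.0)

    def test_zero_coverage(self, group):
        iv = make_intervention("a", {group.id: make_record(group)})
        assert annual_sd_cost(iv, group, 0.0) == 0.0

    def test_zero_population(self, group):
        iv = make_intervention(
            "a", {group.id: make_record(group, population_in_need=0.0)}
        )
        assert annual_sd_cost(iv, group, 0.5) == 0.0

    def test_coverage_out_of_range_raises(self, group):
        iv = make_intervention("a", {group.id: make_record(group)})
        with pytest.raises(ValueError):
            annual_sd_cost(iv, group, 1.2)


class TestCostIntervention:
    def test_gap_arithmetic(self, group):
        iv = make_intervention(
            "a", {group.id: make_record(group, 2.0, 1e6, baseline_coverage=0.3)}
        )
        b, i, t = cost_intervention(iv, group, CoveragePolicy(0.8))
        assert (b, i, t) == pytest.approx((600_000.0, 1_000_000.0, 1_600_000.0))

    def test_no_gap_zero_incremental(self, group):
        iv = make_intervention(
            "a", {group.id: make_record(group, baseline_coverage=0.8)}
        )
        _, inc, _ = cost_intervention(iv, group, CoveragePolicy(0.8))
        assert inc == pytest.approx(0.0)

    def test_clamp_keeps_above_target_coverage(self, group):
        iv = make_intervention(
            "a", {group.id: make_record(group, baseline_coverage=0.9)}
        )
        b, i, t = cost_intervention(iv, group, CoveragePolicy(0.8))
        assert i == 0.0 and t == pytest.approx(b)

    def test_unclamped_allows_negative_increment(self, group):
        iv = make_intervention(
            "a", {group.id: make_record(group, baseline_coverage=0.9)}
        )
        _, inc, _ = cost_intervention(
            iv, group, CoveragePolicy(0.8, clamp_negative_increments=False)
        )
        assert inc < 0.0

    def test_total_is_baseline_plus_incremental_by_construction(self, group):
        iv = make_intervention("a", {group.id: make_record(group)})
        b, i, t = cost_intervention(iv, group)
        assert t == b + i


class TestDedupAndPackages:
    def test_multi_package_membership_counted_once(self, group):
        rec = make_record(group, 10.0, 1.0, baseline_coverage=0.8)
        iv = make_intervention("a", {group.id: rec}, packages={1, 2})
        reg = make_registry([iv], groups=[group])
        res = compute_costs(reg)
        assert dedup_total(res) == pytest.approx(8.0)
        both = package_total(res, 1) + package_total(res, 2)
        assert both == pytest.approx(16.0)

    def test_disjoint_packages_dedup_equals_sum(self, group):
        ivs = [
            make_intervention(
                f"i{k}", {group.id: make_record(group, float(k + 1))}, packages={k + 1}
            )
            for k in range(3)
        ]
        res = compute_costs(make_registry(ivs, groups=[group]))
        total = sum(package_total(res, k + 1) for k in range(3))
        assert dedup_total(res) == pytest.approx(total)

    def test_empty_selection_is_zero(self, single_intervention_registry):
        res = compute_costs(single_intervention_registry)
        assert dedup_total(res, interventions=[]) == 0.0

    def test_unknown_intervention_raises(self, single_intervention_registry):
        res = compute_costs(single_intervention_registry)
        with pytest.raises(KeyError):
            dedup_total(res, interventions=["nope"])

    def test_unknown_package_raises(self, single_intervention_registry):
        res = compute_costs(single_intervention_registry)
        with pytest.raises(KeyError):
            package_total(res, 99)

    def test_overlapping_package_shares_exceed_one(self):
        reg = generate_registry(11, n_interventions=30, n_hpp=10, overlap_rate=0.6)
        res = compute_costs(reg)
        dedup = dedup_total(res)
        share_sum = sum(
            package_total(res, pid) / dedup for pid in reg.packages
        )
        assert share_sum > 1.0


class TestMarkups:
    def test_zero_markups(self):
        assert apply_markups(100.0, MarkupConfig(0.0, 0.0)) == (0.0, 100.0)

    def test_arithmetic(self):
        hs, grand = apply_markups(100.0, MarkupConfig(0.5, 0.25))
        assert (hs, grand) == pytest.approx((75.0, 175.0))
        assert 100.0 * hs / grand == pytest.approx(42.857, rel=1e-3)

    def test_default_markups_reproduce_health_system_share(self):
        markups = MarkupConfig()
        hs, grand = apply_markups(100.0, markups)
        assert round(100.0 * hs / grand, 1) == 42.8
        assert round(100.0 * 100.0 / grand, 1) == 57.2

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            MarkupConfig(-0.1, 0.0)
        with pytest.raises(ValueError):
            apply_markups(-1.0, MarkupConfig())


class TestPerCapitaAndGniShares:
    LIC = CountryGroup("LIC", 0.90e9, 0.70e12)
    LMIC = CountryGroup("lower-MIC", 2.7e9, 5.9e12)

    def test_per_capita_lic(self):
        assert round_sig(per_capita(71e9, self.LIC)) == 79

    def test_per_capita_lmic(self):
        assert round_sig(per_capita(350e9, self.LMIC)) == 130

    def test_per_capita_zero(self):
        assert per_capita(0.0, self.LIC) == 0.0

    def test_gni_share_lmic(self):
        assert round_sig(100 * share_of_gni(250e9, self.LMIC)) == 4.2

    def test_gni_share_hpp_lmic(self):
        assert round_sig(100 * share_of_gni(120e9, self.LMIC)) == 2.0

    def test_gni_share_zero(self):
        assert share_of_gni(0.0, self.LIC) == 0.0


# ---------------------------------------------------------------------------
# properties against the oracle

@pytest.mark.parametrize("seed", range(6))
def test_engine_matches_brute_force_oracle(seed):
    reg = generate_registry(seed, n_interventions=seed % 20 + 1, n_hpp=1)
    res = compute_costs(reg)
    cells = oracle_rows(reg)
    for _, row in res.rows.iterrows():
        b, i, t = cells[(row["intervention_id"], row["group"])]
        assert row["baseline_sd"] == pytest.approx(b, rel=1e-9)
        assert row["incremental_sd"] == pytest.approx(i, rel=1e-9, abs=1e-6)
        assert row["total_sd"] == pytest.approx(t, rel=1e-9)
    assert grand_total(res) == pytest.approx(oracle_grand_total(reg), rel=1e-9)


@pytest.mark.parametrize("seed", [0, 3])
def test_incremental_monotone_in_target_coverage(seed):
    reg = generate_registry(seed, n_interventions=15, n_hpp=5)
    previous = -1.0
    for target in (0.2, 0.4, 0.6, 0.8, 1.0):
        res = compute_costs(reg, CoveragePolicy(target))
        inc = dedup_total(res, field="incremental")
        assert inc >= previous
        previous = inc


def test_incremental_never_increases_with_baseline_coverage(group):
    costs = []
    for cov in (0.1, 0.3, 0.5, 0.7, 0.9):
        iv = make_intervention(
            "a", {group.id: make_record(group, baseline_coverage=cov)}
        )
        res = compute_costs(make_registry([iv], groups=[group]))
        costs.append(dedup_total(res, field="incremental"))
    assert costs == sorted(costs, reverse=True)


def test_homogeneity_in_unit_costs():
    reg = generate_registry(2, n_interventions=10, n_hpp=3)
    k = 3.7
    scaled = dataclasses.replace(
        reg,
        interventions=tuple(
            dataclasses.replace(
                iv,
                records={
                    gid: dataclasses.replace(
                        rec,
                        unit_cost=dataclasses.replace(
                            rec.unit_cost, value=rec.unit_cost.value * k
                        ),
                    )
                    for gid, rec in iv.records.items()
                },
            )
            for iv in reg.interventions
        ),
    )
    base, scaled_res = compute_costs(reg), compute_costs(scaled)
    for field in ("baseline", "incremental", "total"):
        assert dedup_total(scaled_res, field=field) == pytest.approx(
            k * dedup_total(base, field=field), rel=1e-9
        )
    assert grand_total(scaled_res) == pytest.approx(k * grand_total(base), rel=1e-9)


@pytest.mark.parametrize("overlap,expect_equal", [(0.0, True), (0.7, False)])
def test_dedup_vs_package_sum_conservation(overlap, expect_equal):
    reg = generate_registry(9, n_interventions=40, n_hpp=10, overlap_rate=overlap)
    res = compute_costs(reg)
    dedup = dedup_total(res)
    pkg_sum = sum(package_total(res, pid) for pid in reg.packages)
    assert dedup <= pkg_sum * (1 + 1e-9)
    if expect_equal:
        assert dedup == pytest.approx(pkg_sum, rel=1e-12)
    else:
        overlapping = any(len(iv.packages) > 1 for iv in reg.interventions)
        assert overlapping and pkg_sum > dedup


def test_hpp_selection_runs_same_engine():
    reg = generate_registry(4, n_interventions=20, n_hpp=7)
    full = compute_costs(reg)
    hpp = compute_costs(reg, select="hpp")
    assert set(hpp.rows["intervention_id"]) == {
        iv.id for iv in reg.interventions if iv.hpp
    }
    wanted = [iv.id for iv in reg.interventions if iv.hpp]
    assert dedup_total(hpp) == pytest.approx(
        dedup_total(full, interventions=wanted), rel=1e-12
    )
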