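"""Cost decomposition by platform, timing, objective and package.

Shares are computed over service-delivery costs before markups; when a
grand-total breakdown is requested, markups are allocated pro-rata so
shares are unchanged. Combined-group shares pool the groups' costs
before dividing — they are never averages of per-group shares.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd

from .engine import (
    CostResult,
    apply_markups,
    dedup_total,
    package_total,
    share_of_gni,
)
from .registry import Objective

__all__ = ["share_by", "objective_table"]

DIMENSIONS = ("platform", "timing", "objective", "package")
COST_FIELDS = ("baseline", "incremental", "total")

_OBJECTIVE_ORDER = [o.value for o in Objective]


def share_by(
    results: CostResult,
    dimension: str,
    cost_field: str = "incremental",
    groups: Iterable[str] | None = None,
) -> dict:
    """Share of de-duplicated cost by category of one classification dimension.

    Platform and timing partition the interventions, so their shares sum
    to 1. Objective shares include an ``unallocated`` category carrying
    the pathology remainder, and also sum to 1. Package shares use the
    same de-duplicated denominator but overlapping membership makes them
    sum to >= 1.
    """
    if dimension not in DIMENSIONS:
        raise ValueError(f"unknown dimension {dimension!r}")
    if cost_field not in COST_FIELDS:
        raise ValueError(f"unknown cost field {cost_field!r}")
    df = results.rows
    if groups is not None:
        group_set = set(groups)
        if not group_set:
            raise ValueError("empty group selection")
        df = df[df["group"].isin(group_set)]
    if df.empty:
        raise ValueError("no cost rows in selection")
    col = f"{cost_field}_sd"
    denom = float(df[col].sum())
    if denom == 0.0:
        raise ValueError("zero total cost in selection; shares undefined")

    if dimension == "package":
        return {
            pid: package_total(results, pid, groups=groups, field=cost_field) / denom
            for pid in sorted(results.registry.packages)
        }

    sums = df.groupby(dimension)[col].sum()
    if dimension == "platform":
        order = [p for p in _platform_order(results) if p in sums.index or True]
    elif dimension == "timing":
        order = ["urgent", "chronic", "time_bound"]
    else:
        order = _OBJECTIVE_ORDER
    return {cat: float(sums.get(cat, 0.0)) / denom for cat in order}


def _platform_order(results: CostResult) -> list[str]:
    return [
        "population_based",
        "community",
        "health_centre",
        "first_level_hospital",
        "referral_specialty_hospital",
    ]


def objective_table(
    results: CostResult,
    group_id: str,
    cost_field: str = "total",
) -> pd.DataFrame:
    """Per-objective cost table for one group, markups allocated pro-rata.

    Columns: ``n_interventions``, ``cost`` (grand USD/yr), ``pct_gni``
    (percent), ``share`` (proportion of the grand total). The
    ``unallocated`` row carries the pathology remainder — it is reported,
    never spread across the named objectives — and a ``total`` row closes
    the table, so named-objective shares sum to <= 1.
    """
    group = results.registry.group(group_id)
    df = results.rows[results.rows["group"] == group_id]
    col = f"{cost_field}_sd"
    dedup_sd = float(df[col].sum())
    _, grand = apply_markups(dedup_sd, results.markups)
    markup_factor = 1.0 + results.markups.combined

    counts = {o: 0 for o in _OBJECTIVE_ORDER}
    for iv in results.registry.interventions:
        counts[iv.objective.value] += 1

    records = []
    for obj in _OBJECTIVE_ORDER:
        sd = float(df[df["objective"] == obj][col].sum())
        cost = sd * markup_factor
        records.append(
            {
                "objective": obj,
                "n_interventions": counts[obj],
                "cost": cost,
                "pct_gni": 100.0 * share_of_gni(cost, group),
                "share": cost / grand if grand else 0.0,
            }
        )
    records.append(
        {
            "objective": "total",
            "n_interventions": len(results.registry.interventions),
            "cost": grand,
            "pct_gni": 100.0 * share_of_gni(grand, group),
            "share": 1.0 if grand else 0.0,
        }
    )
    return pd.DataFrame.from_records(records).set_index("objective")
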