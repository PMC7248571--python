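"""Report rendering: two-significant-figure formatting and table builders.

Raw computations keep full floating-point precision; rounding to two
significant figures happens only here, at render time.
"""

from __future__ import annotations

import math
from typing import Mapping

import pandas as pd

from .engine import (
    CostResult,
    apply_markups,
    dedup_total,
    grand_total,
    package_total,
    per_capita,
    share_of_gni,
)

__all__ = [
    "round_sig",
    "fmt_sig",
    "package_report",
    "totals_report",
]


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (0 and non-finite pass through)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def fmt_sig(x: float, sig: int = 2) -> str:
    """Human-readable two-significant-figure string ('79', '0.92', '1.6e+05')."""
    r = round_sig(x, sig)
    if r == 0:
        return "0"
    magnitude = math.floor(math.log10(abs(r)))
    if -4 < magnitude < 6:
        decimals = max(0, sig - 1 - magnitude)
        return f"{r:.{decimals}f}"
    return f"{r:.{sig - 1}e}"


def package_report(results: CostResult, group_id: str) -> pd.DataFrame:
    """Per-package cost table for one group, plus a totals block.

    Package rows report service-delivery costs (per capita and absolute)
    and the package's share of the de-duplicated SD total; overlapping
    membership makes those shares sum to more than 100%. The totals block
    appends total SD, de-duplicated SD, health-system and grand-total
    rows.
    """
    group = results.registry.group(group_id)
    rows = []
    for pid, name in sorted(results.registry.packages.items()):
        rec: dict = {"package": pid, "name": name}
        for field in ("baseline", "incremental", "total"):
            cost = package_total(results, pid, groups=[group_id], field=field)
            rec[f"{field}_sd"] = cost
            rec[f"{field}_sd_per_capita"] = per_capita(cost, group)
        dedup = dedup_total(results, groups=[group_id], field="total")
        rec["share_of_dedup_total"] = rec["total_sd"] / dedup if dedup else 0.0
        rows.append(rec)
    df = pd.DataFrame(rows)

    dedup = dedup_total(results, groups=[group_id], field="total")
    health_system, grand = apply_markups(dedup, results.markups)
    totals = pd.DataFrame(
        [
            {
                "package": None,
                "name": "Total service delivery costs",
                "total_sd": float(
                    sum(
                        package_total(results, pid, groups=[group_id])
                        for pid in results.registry.packages
                    )
                ),
            },
            {
                "package": None,
                "name": "De-duplicated service delivery costs",
                "total_sd": dedup,
                "share_of_dedup_total": dedup / grand if grand else 0.0,
            },
            {
                "package": None,
                "name": "Total health system costs",
                "total_sd": health_system,
                "share_of_dedup_total": health_system / grand if grand else 0.0,
            },
            {
                "package": None,
                "name": "Total cost (service delivery + health system)",
                "total_sd": grand,
                "share_of_dedup_total": 1.0 if grand else 0.0,
            },
        ]
    )
    return pd.concat([df, totals], ignore_index=True)


def totals_report(
    results_by_set: Mapping[str, CostResult], sig: int | None = 2
) -> dict:
    """Headline totals per package set per group: absolute (billions),
    per-capita and %-GNI figures for incremental and total cost.

    ``results_by_set`` maps a label (e.g. ``"euhc"``, ``"hpp"``) to the
    corresponding :class:`CostResult`. ``sig=None`` disables rounding.
    """
    rnd = (lambda x: x) if sig is None else (lambda x: round_sig(x, sig))
    out: dict = {}
    for label, results in results_by_set.items():
        per_group = {}
        for group in results.registry.groups:
            entry = {}
            for field in ("incremental", "total"):
                cost = grand_total(results, groups=[group.id], field=field)
                entry[f"{field}_annual_cost_billions"] = rnd(cost / 1e9)
                entry[f"{field}_annual_cost_per_capita"] = rnd(
                    per_capita(cost, group)
                )
                entry[f"{field}_share_of_gni_pct"] = rnd(
                    100.0 * share_of_gni(cost, group)
                )
            per_group[group.id] = entry
        out[label] = per_group
    return out
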