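"""One-way (tornado) and probabilistic (Monte Carlo) sensitivity analysis.

Both analyses re-evaluate the full costing engine — standardised unit
costs × populations × coverage gap, de-duplication, markups — at
perturbed parameter settings. For speed the engine's arithmetic is
vectorised over draws via :class:`EngineCache`, which is property-tested
against the row-by-row engine.

Random-number contract: a single root seed; each uncertain parameter
draws from its own stream derived from ``(seed, crc32(target))``, so
adding or removing a parameter never perturbs the draws of the others.
Credible intervals are empirical quantiles with linear interpolation.
"""

from __future__ import annotations

import dataclasses
import zlib
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .engine import CoveragePolicy, MarkupConfig, Selector, compute_costs
from .registry import Intervention, Objective, Registry
from .standardize import PriceIndexSeries, standardized_annual_cost

__all__ = [
    "UncertainParam",
    "PsaConfig",
    "PsaSummary",
    "OneWayResult",
    "EngineCache",
    "one_way",
    "tornado",
    "run_psa",
    "default_params",
    "ONE_WAY_FAMILIES",
]

ONE_WAY_FAMILIES = (
    "unit_cost",
    "baseline_coverage",
    "facility_markup",
    "above_facility_markup",
    "population_in_need",
    "fertility_proxy",
)

_FAMILIES = ("uniform", "triangular", "lognormal")

_METRIC_FIELDS = ("baseline", "incremental", "total")


@dataclasses.dataclass(frozen=True)
class UncertainParam:
    """A model input with a plausible range, entering the PSA.

    ``target`` is a parameter path:

    * ``facility_markup`` / ``above_facility_markup`` / ``target_coverage``
      — absolute value of a global parameter;
    * ``facility_markup_mult`` / ``above_facility_markup_mult`` —
      multiplier on the global parameter;
    * ``<base>:<intervention_id>[:<group_id>]`` with base one of
      ``unit_cost``, ``baseline_coverage``, ``population_in_need``
      (absolute) or the same with a ``_mult`` suffix (multiplier applied
      to the registry value). Omitting the group applies to all groups.
    """

    target: str
    point: float
    low: float
    high: float
    family: str = "uniform"

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown distribution family {self.family!r}")
        if not self.low <= self.point <= self.high:
            raise ValueError(
                f"{self.target}: need low <= point <= high, got "
                f"({self.low}, {self.point}, {self.high})"
            )
        if self.family == "lognormal" and self.low <= 0:
            raise ValueError(f"{self.target}: lognormal requires low > 0")


@dataclasses.dataclass(frozen=True)
class PsaConfig:
    n_sims: int = 10_000
    seed: int = 0
    percentiles: tuple[float, float] = (2.5, 97.5)

    def __post_init__(self) -> None:
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")


@dataclasses.dataclass(frozen=True)
class PsaSummary:
    """Point estimate with credible-interval endpoints (lo <= hi always)."""

    point: float
    lo: float
    hi: float
    draws: np.ndarray | None = None


@dataclasses.dataclass(frozen=True)
class OneWayResult:
    family: str
    metric_low: float
    metric_high: float

    @property
    def swing(self) -> float:
        return abs(self.metric_high - self.metric_low)


# ---------------------------------------------------------------------------
# vectorised engine

class EngineCache:
    """Registry flattened to arrays so perturbed re-evaluation is cheap.

    ``unit_mult[i, j]`` maps a raw unit-cost value to its standardised,
    annualised USD/beneficiary-year for intervention i in group j; the
    standardisation pipeline is linear in the value, so perturbed costs
    are ``value × unit_mult``.
    """

    def __init__(self, registry: Registry, indices: PriceIndexSeries | None = None):
        self.registry = registry
        self.iv_ids = [iv.id for iv in registry.interventions]
        self.group_ids = [g.id for g in registry.groups]
        self.iv_index = {iid: i for i, iid in enumerate(self.iv_ids)}
        self.group_index = {gid: j for j, gid in enumerate(self.group_ids)}
        n, m = len(self.iv_ids), len(self.group_ids)
        self.unit_value = np.zeros((n, m))
        self.unit_mult = np.zeros((n, m))
        self.pop = np.zeros((n, m))
        self.bcov = np.zeros((n, m))
        for i, iv in enumerate(registry.interventions):
            for j, g in enumerate(registry.groups):
                rec = iv.records[g.id]
                self.unit_value[i, j] = rec.unit_cost.value
                one = dataclasses.replace(rec.unit_cost, value=1.0)
                self.unit_mult[i, j] = standardized_annual_cost(
                    one, rec.traded_fraction, g.gni_per_capita, indices
                )
                self.pop[i, j] = rec.population_in_need
                self.bcov[i, j] = rec.baseline_coverage
        self.under5 = np.array(
            [
                iv.objective is Objective.UNDER5_MORTALITY
                for iv in registry.interventions
            ]
        )

    def evaluate(
        self,
        metric: str,
        unit_value: np.ndarray | None = None,
        pop: np.ndarray | None = None,
        bcov: np.ndarray | None = None,
        target: float | np.ndarray = 0.80,
        clamp: bool = True,
        facility: float | np.ndarray = 0.45,
        above: float | np.ndarray = 0.298,
    ) -> np.ndarray | float:
        """Evaluate a scalar metric; inputs may carry a leading draw axis."""
        unit_value = self.unit_value if unit_value is None else unit_value
        pop = self.pop if pop is None else pop
        bcov = np.clip(self.bcov if bcov is None else bcov, 0.0, 1.0)
        field, grand, group = _parse_metric(metric)
        unit_annual = unit_value * self.unit_mult
        baseline = unit_annual * pop * bcov
        target_arr = np.asarray(target)
        if target_arr.ndim:  # per-draw targets broadcast over (i, j)
            target_arr = target_arr[..., None, None]
        cov_total = np.maximum(bcov, target_arr) if clamp else np.broadcast_to(
            target_arr, baseline.shape
        ) * np.ones_like(baseline)
        total = unit_annual * pop * cov_total
        if field == "baseline":
            chosen = baseline
        elif field == "total":
            chosen = total
        else:
            chosen = total - baseline
        if group is None:
            dedup = chosen.sum(axis=(-2, -1))
        else:
            dedup = chosen[..., :, self.group_index[group]].sum(axis=-1)
        if not grand:
            return dedup
        return dedup * (1.0 + np.asarray(facility) + np.asarray(above))


def _parse_metric(metric: str) -> tuple[str, bool, str | None]:
    """'incremental_grand_total[:group]' → (field, include_markups, group)."""
    group = None
    if ":" in metric:
        metric, group = metric.split(":", 1)
    if metric.endswith("_grand_total"):
        field, grand = metric[: -len("_grand_total")], True
    elif metric.endswith("_dedup"):
        field, grand = metric[: -len("_dedup")], False
    else:
        raise ValueError(f"unknown metric {metric!r}")
    if field not in _METRIC_FIELDS:
        raise ValueError(f"unknown metric field {field!r}")
    return field, grand, group


# ---------------------------------------------------------------------------
# one-way analysis

def one_way(
    registry: Registry,
    policy: CoveragePolicy | None = None,
    markups: MarkupConfig | None = None,
    family: str = "unit_cost",
    low_mult: float = 0.5,
    high_mult: float = 1.5,
    metric: str = "incremental_grand_total",
    indices: PriceIndexSeries | None = None,
    select: Selector | str | None = None,
) -> OneWayResult:
    """Re-run the engine with one parameter family scaled low and high.

    Coverage-type perturbations are clipped to [0, 1];
    ``fertility_proxy`` scales populations in need of interventions whose
    objective is under-5 mortality (birth-cohort-driven need).
    """
    if family not in ONE_WAY_FAMILIES:
        raise ValueError(f"unknown one-way family {family!r}")
    if low_mult <= 0 or high_mult <= 0:
        raise ValueError("multipliers must be > 0")
    policy = policy or CoveragePolicy()
    markups = markups or MarkupConfig()
    if select is not None:
        registry = registry.hpp_subset if select == "hpp" else registry.subset(select)
    cache = EngineCache(registry, indices)

    def evaluate(mult: float) -> float:
        kwargs: dict = {}
        if family == "unit_cost":
            kwargs["unit_value"] = cache.unit_value * mult
        elif family == "baseline_coverage":
            kwargs["bcov"] = np.clip(cache.bcov * mult, 0.0, 1.0)
        elif family == "population_in_need":
            kwargs["pop"] = cache.pop * mult
        elif family == "fertility_proxy":
            scale = np.where(cache.under5, mult, 1.0)[:, None]
            kwargs["pop"] = cache.pop * scale
        facility = markups.facility_markup * (mult if family == "facility_markup" else 1.0)
        above = markups.above_facility_markup * (
            mult if family == "above_facility_markup" else 1.0
        )
        return float(
            cache.evaluate(
                metric,
                target=policy.target_coverage,
                clamp=policy.clamp_negative_increments,
                facility=facility,
                above=above,
                **kwargs,
            )
        )

    return OneWayResult(family, evaluate(low_mult), evaluate(high_mult))


def tornado(
    registry: Registry,
    policy: CoveragePolicy | None = None,
    markups: MarkupConfig | None = None,
    multipliers: dict[str, tuple[float, float]] | None = None,
    metric: str = "incremental_grand_total",
    indices: PriceIndexSeries | None = None,
) -> pd.DataFrame:
    """One-way results for every family, sorted by swing (largest first)."""
    defaults = {
        "unit_cost": (0.5, 1.5),
        "baseline_coverage": (0.8, 1.2),
        "facility_markup": (0.75, 1.25),
        "above_facility_markup": (0.75, 1.25),
        "population_in_need": (0.9, 1.1),
        "fertility_proxy": (0.9, 1.1),
    }
    multipliers = {**defaults, **(multipliers or {})}
    records = []
    for family, (lo, hi) in multipliers.items():
        res = one_way(registry, policy, markups, family, lo, hi, metric, indices)
        records.append(
            {
                "parameter": family,
                "low": res.metric_low,
                "high": res.metric_high,
                "swing": res.swing,
            }
        )
    df = pd.DataFrame.from_records(records)
    return df.sort_values("swing", ascending=False, ignore_index=True)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis

def _param_rng(seed: int, target: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(target.encode("utf-8"))])
    )


def _sample(param: UncertainParam, rng: np.random.Generator, n: int) -> np.ndarray:
    if param.low == param.high:
        return np.full(n, param.point)
    if param.family == "uniform":
        return rng.uniform(param.low, param.high, size=n)
    if param.family == "triangular":
        return rng.triangular(param.low, param.point, param.high, size=n)
    # lognormal: median at the point, (low, high) spanning the central 95%
    mu = np.log(param.point)
    sigma = (np.log(param.high) - np.log(param.low)) / (2.0 * 1.959963984540054)
    return rng.lognormal(mu, sigma, size=n)


def _parse_target(
    target: str, cache: EngineCache
) -> tuple[str, bool, int | None, int | None]:
    """→ (base, is_multiplier, iv_index or None, group_index or None)."""
    parts = target.split(":")
    base = parts[0]
    mult = base.endswith("_mult")
    if mult:
        base = base[: -len("_mult")]
    if base in ("facility_markup", "above_facility_markup", "target_coverage"):
        if len(parts) != 1:
            raise ValueError(f"global parameter {target!r} takes no qualifier")
        return base, mult, None, None
    if base not in ("unit_cost", "baseline_coverage", "population_in_need"):
        raise ValueError(f"unknown parameter target {target!r}")
    if len(parts) < 2 or len(parts) > 3:
        raise ValueError(f"target {target!r} needs intervention[:group] qualifier")
    iv = None if parts[1] == "*" else cache.iv_index[parts[1]]
    gj = cache.group_index[parts[2]] if len(parts) == 3 else None
    return base, mult, iv, gj


_ARRAY_OF = {
    "unit_cost": "unit_value",
    "baseline_coverage": "bcov",
    "population_in_need": "pop",
}


def run_psa(
    registry: Registry,
    policy: CoveragePolicy | None = None,
    markups: MarkupConfig | None = None,
    params: Sequence[UncertainParam] = (),
    config: PsaConfig | None = None,
    metric: str = "incremental_grand_total",
    indices: PriceIndexSeries | None = None,
    select: Selector | str | None = None,
    keep_draws: bool = False,
    chunk_size: int = 2048,
) -> PsaSummary:
    """Monte Carlo propagation of parameter ranges through the full engine.

    Each of ``config.n_sims`` joint draws samples every parameter
    independently from its own seeded stream, re-evaluates the engine,
    and records the metric; the credible interval is the empirical
    (2.5th, 97.5th) percentile pair by default. The point estimate is the
    metric with every parameter at its ``point`` value. Identical seeds
    give bit-identical summaries.
    """
    policy = policy or CoveragePolicy()
    markups = markups or MarkupConfig()
    config = config or PsaConfig()
    if select is not None:
        registry = registry.hpp_subset if select == "hpp" else registry.subset(select)
    cache = EngineCache(registry, indices)
    parsed = [(p, _parse_target(p.target, cache)) for p in params]

    def evaluate(values: list[np.ndarray], n: int) -> np.ndarray:
        arrays = {
            "unit_value": np.broadcast_to(
                cache.unit_value, (n, *cache.unit_value.shape)
            ).copy(),
            "bcov": np.broadcast_to(cache.bcov, (n, *cache.bcov.shape)).copy(),
            "pop": np.broadcast_to(cache.pop, (n, *cache.pop.shape)).copy(),
        }
        facility = np.full(n, markups.facility_markup)
        above = np.full(n, markups.above_facility_markup)
        target = np.full(n, policy.target_coverage)
        for (param, (base, mult, iv, gj)), vals in zip(parsed, values):
            if base == "facility_markup":
                facility = facility * vals if mult else vals
            elif base == "above_facility_markup":
                above = above * vals if mult else vals
            elif base == "target_coverage":
                target = np.clip(target * vals if mult else vals, 0.0, 1.0)
            else:
                arr = arrays[_ARRAY_OF[base]]
                isel = slice(None) if iv is None else iv
                jsel = slice(None) if gj is None else gj
                if mult:
                    arr[:, isel, jsel] *= vals.reshape(
                        (n,) + (1,) * (arr[:, isel, jsel].ndim - 1)
                    )
                else:
                    arr[:, isel, jsel] = vals.reshape(
                        (n,) + (1,) * (arr[:, isel, jsel].ndim - 1)
                    )
        arrays["bcov"] = np.clip(arrays["bcov"], 0.0, 1.0)
        arrays["pop"] = np.maximum(arrays["pop"], 0.0)
        return np.asarray(
            cache.evaluate(
                metric,
                unit_value=arrays["unit_value"],
                pop=arrays["pop"],
                bcov=arrays["bcov"],
                target=target,
                clamp=policy.clamp_negative_increments,
                facility=facility,
                above=above,
            )
        )

    point = float(evaluate([np.full(1, p.point) for p, _ in parsed], 1)[0])

    all_draws = [
        _sample(p, _param_rng(config.seed, p.target), config.n_sims)
        for p, _ in parsed
    ]
    out = np.empty(config.n_sims)
    for start in range(0, config.n_sims, chunk_size):
        stop = min(start + chunk_size, config.n_sims)
        chunk = [d[start:stop] for d in all_draws]
        out[start:stop] = evaluate(chunk, stop - start)
    lo, hi = np.percentile(out, list(config.percentiles), method="linear")
    return PsaSummary(
        point=point,
        lo=float(lo),
        hi=float(hi),
        draws=out if keep_draws else None,
    )


def default_params(
    registry: Registry,
    unit_cost_rel: float = 0.5,
    coverage_rel: float = 0.2,
    markup_rel: float = 0.25,
    family: str = "uniform",
) -> list[UncertainParam]:
    """Stand-in plausible ranges: one multiplier per family per intervention
    (±50% unit cost, ±20% coverage) plus global markup multipliers (±25%).
    All user-overridable; these are documented defaults, not estimates.
    """
    params = [
        UncertainParam(
            f"unit_cost_mult:{iv.id}", 1.0, 1.0 - unit_cost_rel, 1.0 + unit_cost_rel,
            family,
        )
        for iv in registry.interventions
    ]
    params += [
        UncertainParam(
            f"baseline_coverage_mult:{iv.id}", 1.0, 1.0 - coverage_rel,
            1.0 + coverage_rel, family,
        )
        for iv in registry.interventions
    ]
    params += [
        UncertainParam(
            "facility_markup_mult", 1.0, 1.0 - markup_rel, 1.0 + markup_rel, family
        ),
        UncertainParam(
            "above_facility_markup_mult", 1.0, 1.0 - markup_rel, 1.0 + markup_rel,
            family,
        ),
    ]
    return params
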