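"""Domain types, validation and tabular I/O for the intervention registry.

The registry holds one :class:`Intervention` per essential-package
intervention, each carrying per-country-group cost and coverage records,
plus the stylised :class:`CountryGroup` definitions and the package-id →
display-name map.

Two on-disk layouts are supported:

* **CSV** — ``registry.csv`` with one row per (intervention, group);
  classification columns are repeated on every row and must agree across
  an intervention's rows. Sibling files ``groups.csv`` (id, population,
  gni_total) and ``packages.csv`` (id, name) live in the same directory.
* **JSON** — a single document with ``groups``, ``packages`` and
  ``interventions`` keys.

Proportions are stored as decimals in [0, 1], never percentages.
Monetary amounts are raw floating-point USD; rounding happens only at
report time.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
from pathlib import Path
from typing import Callable, Iterable, Mapping

import pandas as pd

__all__ = [
    "Platform",
    "Timing",
    "Objective",
    "CostBasis",
    "CountryGroup",
    "UnitCostRecord",
    "GroupRecord",
    "Intervention",
    "Registry",
    "RegistryError",
    "load_registry",
    "validate_registry",
    "write_registry",
]


class Platform(str, enum.Enum):
    """Physical/organisational delivery channel."""

    POPULATION_BASED = "population_based"
    COMMUNITY = "community"
    HEALTH_CENTRE = "health_centre"
    FIRST_LEVEL_HOSPITAL = "first_level_hospital"
    REFERRAL_SPECIALTY_HOSPITAL = "referral_specialty_hospital"


class Timing(str, enum.Enum):
    """Client–provider interaction pattern."""

    URGENT = "urgent"
    CHRONIC = "chronic"
    TIME_BOUND = "time_bound"


class Objective(str, enum.Enum):
    """Primary outcome an intervention targets.

    ``UNALLOCATED`` is reserved for pathology-type interventions whose
    cost supports every objective and fits none.
    """

    UNDER5_MORTALITY = "under5_mortality"
    MORTALITY_5_69_CMPN = "mortality_5_69_cmpn"
    MORTALITY_5_69_NCDI = "mortality_5_69_ncdi"
    DISABILITY = "disability"
    NON_HEALTH = "non_health"
    UNALLOCATED = "unallocated"


class CostBasis(str, enum.Enum):
    PER_PATIENT_YEAR = "per_patient_year"
    PER_EPISODE = "per_episode"


PRICE_YEAR_RANGE = (1990, 2016)


class RegistryError(ValueError):
    """Raised when a registry file violates the schema or an invariant."""

    def __init__(self, diagnostics: list[str] | str):
        if isinstance(diagnostics, str):
            diagnostics = [diagnostics]
        self.diagnostics = diagnostics
        super().__init__("; ".join(diagnostics))


@dataclasses.dataclass(frozen=True)
class CountryGroup:
    """Stylised income group (e.g. LIC, lower-MIC)."""

    id: str
    population: float  # persons
    gni_total: float  # USD / year

    @property
    def gni_per_capita(self) -> float:
        return self.gni_total / self.population


@dataclasses.dataclass(frozen=True)
class UnitCostRecord:
    """Raw source-study unit cost, before standardisation.

    ``value`` is per beneficiary per basis period: per patient-year for
    chronic-style interventions, per episode for acute ones (in which
    case ``episodes_per_beneficiary_year`` converts to an annual rate).
    """

    value: float
    currency: str = "USD"
    price_year: int = 2016
    source_gni_per_capita: float = 0.0
    cost_basis: CostBasis = CostBasis.PER_PATIENT_YEAR
    episodes_per_beneficiary_year: float | None = None


@dataclasses.dataclass(frozen=True)
class GroupRecord:
    """Per-country-group inputs for one intervention."""

    unit_cost: UnitCostRecord
    traded_fraction: float  # proportion of unit cost that is traded goods
    population_in_need: float  # persons / year
    baseline_coverage: float  # proportion in [0, 1]


@dataclasses.dataclass(frozen=True)
class Intervention:
    id: str
    name: str
    packages: frozenset[int]
    platform: Platform
    timing: Timing
    objective: Objective
    hpp: bool
    records: Mapping[str, GroupRecord]
    pathology: bool = False


@dataclasses.dataclass(frozen=True)
class Registry:
    interventions: tuple[Intervention, ...]
    groups: tuple[CountryGroup, ...]
    packages: Mapping[int, str]

    def group(self, group_id: str) -> CountryGroup:
        for g in self.groups:
            if g.id == group_id:
                return g
        raise KeyError(f"unknown country group {group_id!r}")

    def intervention(self, intervention_id: str) -> Intervention:
        for iv in self.interventions:
            if iv.id == intervention_id:
                return iv
        raise KeyError(f"unknown intervention {intervention_id!r}")

    def subset(self, predicate: Callable[[Intervention], bool]) -> "Registry":
        """Registry restricted to interventions satisfying ``predicate``."""
        return dataclasses.replace(
            self,
            interventions=tuple(iv for iv in self.interventions if predicate(iv)),
        )

    @property
    def hpp_subset(self) -> "Registry":
        return self.subset(lambda iv: iv.hpp)


# ---------------------------------------------------------------------------
# validation

def _check(cond: bool, msg: str, out: list[str]) -> None:
    if not cond:
        out.append(msg)


def validate_registry(registry: Registry) -> list[str]:
    """Return one diagnostic string per invariant violation (empty if valid)."""
    diags: list[str] = []
    _check(len(registry.interventions) > 0, "registry has no interventions", diags)
    _check(len(registry.groups) > 0, "registry has no country groups", diags)

    seen: set[str] = set()
    for iv in registry.interventions:
        if iv.id in seen:
            diags.append(f"duplicate intervention id {iv.id!r}")
        seen.add(iv.id)

    for g in registry.groups:
        _check(g.population > 0, f"group {g.id!r}: population must be > 0", diags)
        _check(g.gni_total > 0, f"group {g.id!r}: gni_total must be > 0", diags)

    group_ids = {g.id for g in registry.groups}
    for iv in registry.interventions:
        where = f"intervention {iv.id!r}"
        _check(len(iv.packages) > 0, f"{where}: packages must be non-empty", diags)
        for pid in iv.packages:
            _check(
                pid in registry.packages,
                f"{where}: package id {pid} not declared in package table",
                diags,
            )
        if iv.objective is Objective.UNALLOCATED:
            _check(
                iv.pathology,
                f"{where}: objective 'unallocated' requires the pathology flag",
                diags,
            )
        missing = group_ids - set(iv.records)
        for gid in sorted(missing):
            diags.append(f"{where}: missing record for group {gid!r}")
        for gid in sorted(set(iv.records) - group_ids):
            diags.append(f"{where}: record for undeclared group {gid!r}")
        for gid, rec in iv.records.items():
            loc = f"{where}, group {gid!r}"
            uc = rec.unit_cost
            _check(uc.value >= 0, f"{loc}: unit cost value must be >= 0", diags)
            _check(
                PRICE_YEAR_RANGE[0] <= uc.price_year <= PRICE_YEAR_RANGE[1],
                f"{loc}: price_year {uc.price_year} outside {PRICE_YEAR_RANGE}",
                diags,
            )
            _check(
                uc.source_gni_per_capita > 0,
                f"{loc}: source_gni_per_capita must be > 0",
                diags,
            )
            if uc.cost_basis is CostBasis.PER_EPISODE:
                _check(
                    uc.episodes_per_beneficiary_year is not None
                    and uc.episodes_per_beneficiary_year > 0,
                    f"{loc}: per_episode cost requires episodes_per_beneficiary_year > 0",
                    diags,
                )
            _check(
                0.0 <= rec.baseline_coverage <= 1.0,
                f"{loc}: baseline_coverage {rec.baseline_coverage} outside [0, 1]",
                diags,
            )
            _check(
                0.0 <= rec.traded_fraction <= 1.0,
                f"{loc}: traded_fraction {rec.traded_fraction} outside [0, 1]",
                diags,
            )
            _check(
                rec.population_in_need >= 0,
                f"{loc}: population_in_need must be >= 0",
                diags,
            )
    return diags


# ---------------------------------------------------------------------------
# I/O helpers

_CSV_COLUMNS = [
    "intervention_id",
    "name",
    "packages",
    "platform",
    "timing",
    "objective",
    "hpp",
    "pathology",
    "group",
    "unit_cost_value",
    "unit_cost_currency",
    "unit_cost_price_year",
    "unit_cost_source_gni_pc",
    "unit_cost_basis",
    "episodes_per_beneficiary_year",
    "traded_fraction",
    "population_in_need",
    "baseline_coverage",
]

_BOOL = {"true": True, "false": False, "1": True, "0": False}


def _parse_bool(raw: object, where: str, diags: list[str]) -> bool:
    key = str(raw).strip().lower()
    if key not in _BOOL:
        diags.append(f"{where}: expected boolean, got {raw!r}")
        return False
    return _BOOL[key]


def _parse_float(raw: object, where: str, diags: list[str]) -> float:
    try:
        return float(raw)
    except (TypeError, ValueError):
        diags.append(f"{where}: expected number, got {raw!r}")
        return math.nan


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        return format
    return "json" if path.suffix.lower() == ".json" else "csv"


def load_registry(path: str | Path, format: str | None = None) -> Registry:
    """Load and fully validate a registry from CSV or JSON.

    Raises :class:`RegistryError` carrying one diagnostic per schema or
    invariant violation, each naming the offending row and field.
    """
    path = Path(path)
    if not path.exists():
        raise RegistryError(f"registry file not found: {path}")
    fmt = _infer_format(path, format)
    if fmt == "json":
        registry = _load_json(path)
    elif fmt == "csv":
        registry = _load_csv(path)
    else:
        raise RegistryError(f"unknown registry format {fmt!r}")
    diags = validate_registry(registry)
    if diags:
        raise RegistryError(diags)
    return registry


def _load_json(path: Path) -> Registry:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    diags: list[str] = []
    groups = tuple(
        CountryGroup(str(g["id"]), float(g["population"]), float(g["gni_total"]))
        for g in doc.get("groups", [])
    )
    packages = {int(k): str(v) for k, v in doc.get("packages", {}).items()}
    interventions = []
    for i, rec in enumerate(doc.get("interventions", [])):
        where = f"interventions[{i}]"
        try:
            records = {
                gid: GroupRecord(
                    unit_cost=UnitCostRecord(
                        value=float(r["unit_cost"]["value"]),
                        currency=str(r["unit_cost"].get("currency", "USD")),
                        price_year=int(r["unit_cost"].get("price_year", 2016)),
                        source_gni_per_capita=float(
                            r["unit_cost"]["source_gni_per_capita"]
                        ),
                        cost_basis=CostBasis(
                            r["unit_cost"].get("cost_basis", "per_patient_year")
                        ),
                        episodes_per_beneficiary_year=(
                            None
                            if r["unit_cost"].get("episodes_per_beneficiary_year")
                            is None
                            else float(
                                r["unit_cost"]["episodes_per_beneficiary_year"]
                            )
                        ),
                    ),
                    traded_fraction=float(r["traded_fraction"]),
                    population_in_need=float(r["population_in_need"]),
                    baseline_coverage=float(r["baseline_coverage"]),
                )
                for gid, r in rec.get("records", {}).items()
            }
            interventions.append(
                Intervention(
                    id=str(rec["id"]),
                    name=str(rec["name"]),
                    packages=frozenset(int(p) for p in rec["packages"]),
                    platform=Platform(rec["platform"]),
                    timing=Timing(rec["timing"]),
                    objective=Objective(rec["objective"]),
                    hpp=bool(rec["hpp"]),
                    pathology=bool(rec.get("pathology", False)),
                    records=records,
                )
            )
        except (KeyError, ValueError, TypeError) as exc:
            diags.append(f"{where}: {exc!r}")
    if diags:
        raise RegistryError(diags)
    return Registry(tuple(interventions), groups, packages)


def _load_csv(path: Path) -> Registry:
    diags: list[str] = []
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing_cols:
        raise RegistryError(
            [f"registry csv missing column {c!r}" for c in missing_cols]
        )

    groups_path = path.parent / "groups.csv"
    packages_path = path.parent / "packages.csv"
    if not groups_path.exists():
        raise RegistryError(f"groups file not found: {groups_path}")
    if not packages_path.exists():
        raise RegistryError(f"packages file not found: {packages_path}")
    gdf = pd.read_csv(groups_path, dtype=str)
    groups = tuple(
        CountryGroup(
            str(r["id"]),
            _parse_float(r["population"], f"groups.csv row {i}: population", diags),
            _parse_float(r["gni_total"], f"groups.csv row {i}: gni_total", diags),
        )
        for i, r in gdf.iterrows()
    )
    pdf = pd.read_csv(packages_path, dtype=str)
    packages = {int(r["id"]): str(r["name"]) for _, r in pdf.iterrows()}

    interventions: list[Intervention] = []
    for iv_id, rows in df.groupby("intervention_id", sort=False):
        first = rows.iloc[0]
        where = f"intervention {iv_id!r}"
        for col in ("name", "packages", "platform", "timing", "objective", "hpp"):
            if rows[col].nunique() > 1:
                diags.append(f"{where}: column {col!r} inconsistent across rows")
        try:
            pkg_ids = frozenset(
                int(p) for p in str(first["packages"]).split(";") if p.strip()
            )
        except ValueError:
            diags.append(f"{where}: unparseable packages field {first['packages']!r}")
            pkg_ids = frozenset()
        try:
            platform = Platform(first["platform"])
            timing = Timing(first["timing"])
            objective = Objective(first["objective"])
        except ValueError as exc:
            diags.append(f"{where}: {exc}")
            continue
        records: dict[str, GroupRecord] = {}
        for ridx, row in rows.iterrows():
            loc = f"{where} row {ridx}"
            gid = str(row["group"])
            if gid in records:
                diags.append(f"{loc}: duplicate record for group {gid!r}")
            eps_raw = str(row["episodes_per_beneficiary_year"]).strip()
            try:
                basis = CostBasis(row["unit_cost_basis"])
            except ValueError as exc:
                diags.append(f"{loc}: {exc}")
                continue
            records[gid] = GroupRecord(
                unit_cost=UnitCostRecord(
                    value=_parse_float(
                        row["unit_cost_value"], f"{loc}: unit_cost_value", diags
                    ),
                    currency=str(row["unit_cost_currency"]),
                    price_year=int(
                        _parse_float(
                            row["unit_cost_price_year"],
                            f"{loc}: unit_cost_price_year",
                            diags,
                        )
                    ),
                    source_gni_per_capita=_parse_float(
                        row["unit_cost_source_gni_pc"],
                        f"{loc}: unit_cost_source_gni_pc",
                        diags,
                    ),
                    cost_basis=basis,
                    episodes_per_beneficiary_year=(
                        None
                        if eps_raw == ""
                        else _parse_float(
                            eps_raw, f"{loc}: episodes_per_beneficiary_year", diags
                        )
                    ),
                ),
                traded_fraction=_parse_float(
                    row["traded_fraction"], f"{loc}: traded_fraction", diags
                ),
                population_in_need=_parse_float(
                    row["population_in_need"], f"{loc}: population_in_need", diags
                ),
                baseline_coverage=_parse_float(
                    row["baseline_coverage"], f"{loc}: baseline_coverage", diags
                ),
            )
        interventions.append(
            Intervention(
                id=str(iv_id),
                name=str(first["name"]),
                packages=pkg_ids,
                platform=platform,
                timing=timing,
                objective=objective,
                hpp=_parse_bool(first["hpp"], f"{where}: hpp", diags),
                pathology=_parse_bool(
                    first["pathology"], f"{where}: pathology", diags
                ),
                records=records,
            )
        )
    if diags:
        raise RegistryError(diags)
    return Registry(tuple(interventions), groups, packages)


def write_registry(
    registry: Registry, path: str | Path, format: str | None = None
) -> None:
    """Write a registry; ``load_registry(write_registry(r)) == r`` field-for-field."""
    path = Path(path)
    fmt = _infer_format(path, format)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "json":
        _write_json(registry, path)
    elif fmt == "csv":
        _write_csv(registry, path)
    else:
        raise RegistryError(f"unknown registry format {fmt!r}")


def _write_json(registry: Registry, path: Path) -> None:
    doc = {
        "groups": [
            {"id": g.id, "population": g.population, "gni_total": g.gni_total}
            for g in registry.groups
        ],
        "packages": {str(k): v for k, v in sorted(registry.packages.items())},
        "interventions": [
            {
                "id": iv.id,
                "name": iv.name,
                "packages": sorted(iv.packages),
                "platform": iv.platform.value,
                "timing": iv.timing.value,
                "objective": iv.objective.value,
                "hpp": iv.hpp,
                "pathology": iv.pathology,
                "records": {
                    gid: {
                        "unit_cost": {
                            "value": rec.unit_cost.value,
                            "currency": rec.unit_cost.currency,
                            "price_year": rec.unit_cost.price_year,
                            "source_gni_per_capita": rec.unit_cost.source_gni_per_capita,
                            "cost_basis": rec.unit_cost.cost_basis.value,
                            "episodes_per_beneficiary_year": rec.unit_cost.episodes_per_beneficiary_year,
                        },
                        "traded_fraction": rec.traded_fraction,
                        "population_in_need": rec.population_in_need,
                        "baseline_coverage": rec.baseline_coverage,
                    }
                    for gid, rec in sorted(iv.records.items())
                },
            }
            for iv in registry.interventions
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1, ensure_ascii=False)
        fh.write("\n")


def _write_csv(registry: Registry, path: Path) -> None:
    rows = []
    for iv in registry.interventions:
        for gid, rec in sorted(iv.records.items()):
            uc = rec.unit_cost
            rows.append(
                {
                    "intervention_id": iv.id,
                    "name": iv.name,
                    "packages": ";".join(str(p) for p in sorted(iv.packages)),
                    "platform": iv.platform.value,
                    "timing": iv.timing.value,
                    "objective": iv.objective.value,
                    "hpp": str(iv.hpp).lower(),
                    "pathology": str(iv.pathology).lower(),
                    "group": gid,
                    "unit_cost_value": repr(uc.value),
                    "unit_cost_currency": uc.currency,
                    "unit_cost_price_year": uc.price_year,
                    "unit_cost_source_gni_pc": repr(uc.source_gni_per_capita),
                    "unit_cost_basis": uc.cost_basis.value,
                    "episodes_per_beneficiary_year": (
                        ""
                        if uc.episodes_per_beneficiary_year is None
                        else repr(uc.episodes_per_beneficiary_year)
                    ),
                    "traded_fraction": repr(rec.traded_fraction),
                    "population_in_need": repr(rec.population_in_need),
                    "baseline_coverage": repr(rec.baseline_coverage),
                }
            )
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)
    gdf = pd.DataFrame(
        [
            {"id": g.id, "population": repr(g.population), "gni_total": repr(g.gni_total)}
            for g in registry.groups
        ]
    )
    gdf.to_csv(path.parent / "groups.csv", index=False)
    pdf = pd.DataFrame(
        [{"id": k, "name": v} for k, v in sorted(registry.packages.items())]
    )
    pdf.to_csv(path.parent / "packages.csv", index=False)
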