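"""Domain types, indicator registry and tabular readers/writers.

The registry describes a three-level aggregation hierarchy
(indicators -> tracer areas -> tracer domains) loaded from a YAML
config so alternative indicator sets are drop-in replacements for the
shipped default.  District tables are plain CSV; percentages are kept
on the 0-100 scale throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "IndicatorDef",
    "IndicatorRegistry",
    "DistrictRecord",
    "IndexResult",
    "load_registry",
    "default_registry",
    "read_district_table",
    "read_subgroup_table",
    "write_district_table",
    "write_subgroup_table",
    "write_results",
    "read_results",
]

ORIENTATIONS = ("coverage", "adverse_incidence")


@dataclass(frozen=True)
class IndicatorDef:
    """One tracer indicator and its position in the hierarchy."""

    id: str
    name: str
    domain: str
    area: str
    orientation: str = "coverage"
    in_equity_subset: bool = False

    def __post_init__(self) -> None:
        if self.orientation not in ORIENTATIONS:
            raise ValueError(
                f"indicator {self.id!r}: orientation must be one of "
                f"{ORIENTATIONS}, got {self.orientation!r}"
            )


class IndicatorRegistry:
    """Ordered collection of indicators with their area/domain tree.

    Parameters
    ----------
    indicators
        Indicator definitions in configuration order.  Each indicator
        belongs to exactly one area, and each area to exactly one domain.
    equity_subset
        Indicator ids with subgroup-disaggregated data available.  Every
        id must exist in `indicators`.
    """

    def __init__(
        self,
        indicators: Iterable[IndicatorDef],
        equity_subset: Iterable[str] = (),
    ) -> None:
        self.indicators: list[IndicatorDef] = list(indicators)
        self._by_id: dict[str, IndicatorDef] = {}
        self.areas: dict[str, list[str]] = {}
        self.domains: dict[str, list[str]] = {}
        area_domain: dict[str, str] = {}
        for ind in self.indicators:
            if ind.id in self._by_id:
                raise ValueError(f"duplicate indicator id: {ind.id!r}")
            self._by_id[ind.id] = ind
            if ind.area in area_domain and area_domain[ind.area] != ind.domain:
                raise ValueError(
                    f"area {ind.area!r} assigned to two domains: "
                    f"{area_domain[ind.area]!r} and {ind.domain!r}"
                )
            area_domain[ind.area] = ind.domain
            self.areas.setdefault(ind.area, []).append(ind.id)
            if ind.area not in self.domains.setdefault(ind.domain, []):
                self.domains[ind.domain].append(ind.area)
        self.equity_subset: list[str] = list(equity_subset)
        for eid in self.equity_subset:
            if eid not in self._by_id:
                raise ValueError(f"equity subset id not in registry: {eid!r}")

    # -- lookups -------------------------------------------------------
    @property
    def indicator_ids(self) -> list[str]:
        return [ind.id for ind in self.indicators]

    def __len__(self) -> int:
        return len(self.indicators)

    def __contains__(self, indicator_id: str) -> bool:
        return indicator_id in self._by_id

    def get(self, indicator_id: str) -> IndicatorDef:
        return self._by_id[indicator_id]

    def domain_of(self, indicator_id: str) -> str:
        return self._by_id[indicator_id].domain

    def area_of(self, indicator_id: str) -> str:
        return self._by_id[indicator_id].area

    def adverse_ids(self) -> list[str]:
        return [i.id for i in self.indicators if i.orientation == "adverse_incidence"]

    def drop(self, indicator_id: str) -> "IndicatorRegistry":
        """Registry without one indicator; empty areas/domains disappear."""
        if indicator_id not in self._by_id:
            raise KeyError(indicator_id)
        kept = [i for i in self.indicators if i.id != indicator_id]
        if not kept:
            raise ValueError("cannot drop the last indicator")
        equity = [e for e in self.equity_subset if e != indicator_id]
        return IndicatorRegistry(kept, equity)


@dataclass
class DistrictRecord:
    """One district's indicator values, state membership and subgroups.

    `values` holds only the present cells (absent key == missing).  The
    `subgroups` map is keyed by ``(dimension, subgroup_label)`` and holds
    equity-subset indicator values for that subgroup.  `imputed` records
    provenance of filled cells.
    """

    district_id: str
    state_id: str
    values: dict[str, float] = field(default_factory=dict)
    mpi: float | None = None
    subgroups: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)
    imputed: set[str] = field(default_factory=set)

    def missing(self, indicator_ids: Iterable[str]) -> list[str]:
        return [i for i in indicator_ids if i not in self.values]

    def is_complete(self, indicator_ids: Iterable[str]) -> bool:
        return not self.missing(indicator_ids)

    def copy(self) -> "DistrictRecord":
        return DistrictRecord(
            district_id=self.district_id,
            state_id=self.state_id,
            values=dict(self.values),
            mpi=self.mpi,
            subgroups={k: dict(v) for k, v in self.subgroups.items()},
            imputed=set(self.imputed),
        )


@dataclass
class IndexResult:
    """Per-district composite index with its decomposition."""

    district_id: str
    uhcd: float
    domain_scores: dict[str, float]
    area_scores: dict[str, float]
    service_coverage: float
    financial_risk_protection: float
    tercile: str | None = None


# ---------------------------------------------------------------------
# registry config
# ---------------------------------------------------------------------

def _registry_from_config(cfg: Mapping) -> IndicatorRegistry:
    equity = set(cfg.get("equity_subset") or [])
    indicators: list[IndicatorDef] = []
    for dom in cfg.get("domains", []):
        dkey = dom["key"]
        for area in dom.get("areas", []):
            akey = area["key"]
            for ind in area.get("indicators", []):
                indicators.append(
                    IndicatorDef(
                        id=ind["id"],
                        name=ind.get("name", ind["id"]),
                        domain=dkey,
                        area=akey,
                        orientation=ind.get("orientation", "coverage"),
                        in_equity_subset=ind["id"] in equity,
                    )
                )
    reg = IndicatorRegistry(indicators, cfg.get("equity_subset") or [])
    return reg


def load_registry(config_path: str | Path) -> IndicatorRegistry:
    """Load an indicator registry from a YAML config file.

    The config has a ``domains`` list (each with ``areas``, each with
    ``indicators``) and an optional ``equity_subset`` id list.  Indicator
    order in the file is preserved.
    """
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping) or "domains" not in cfg:
        raise ValueError(f"{config_path}: not a registry config (no 'domains' key)")
    return _registry_from_config(cfg)


def default_registry() -> IndicatorRegistry:
    """The shipped 24-indicator / 13-area / 5-domain registry."""
    ref = resources.files("uhcd.data").joinpath("registry.yaml")
    with resources.as_file(ref) as path:
        return load_registry(path)


# ---------------------------------------------------------------------
# district tables
# ---------------------------------------------------------------------

_META_COLS = ("district_id", "state_id", "mpi")


def _check_range(value: float, district: str, indicator: str) -> float:
    if not (0.0 <= value <= 100.0):
        raise ValueError(
            f"district {district!r}, indicator {indicator!r}: "
            f"value {value} outside [0, 100]"
        )
    return float(value)


def read_district_table(
    path: str | Path, registry: IndicatorRegistry
) -> list[DistrictRecord]:
    """Read a district CSV into records.

    Expected header: ``district_id,state_id,<indicator ids...>[,mpi]``.
    Empty cells are missing values.  Unknown indicator columns trigger a
    warning and are ignored; out-of-range values and missing district ids
    are errors.
    """
    df = pd.read_csv(path, dtype={"district_id": str, "state_id": str})
    if "district_id" not in df.columns or "state_id" not in df.columns:
        raise ValueError(f"{path}: table must have district_id and state_id columns")
    known = set(registry.indicator_ids)
    for col in df.columns:
        if col not in known and col not in _META_COLS:
            warnings.warn(f"{path}: ignoring unknown indicator column {col!r}")
    ind_cols = [c for c in df.columns if c in known]
    records: list[DistrictRecord] = []
    for i, row in df.iterrows():
        did = row["district_id"]
        if pd.isna(did) or str(did).strip() == "":
            raise ValueError(f"{path}: row {i}: missing district_id")
        values = {}
        for col in ind_cols:
            v = row[col]
            if pd.isna(v):
                continue
            values[col] = _check_range(float(v), str(did), col)
        mpi = None
        if "mpi" in df.columns and not pd.isna(row["mpi"]):
            mpi = float(row["mpi"])
            if not (0.0 <= mpi <= 1.0):
                raise ValueError(f"district {did!r}: mpi {mpi} outside [0, 1]")
        records.append(
            DistrictRecord(
                district_id=str(did),
                state_id=str(row["state_id"]),
                values=values,
                mpi=mpi,
            )
        )
    return records


def write_district_table(
    records: Iterable[DistrictRecord],
    registry: IndicatorRegistry,
    path: str | Path,
) -> None:
    """Write records to CSV with the canonical column order."""
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "district_id": rec.district_id,
            "state_id": rec.state_id,
        }
        for iid in registry.indicator_ids:
            row[iid] = rec.values.get(iid, np.nan)
        row["mpi"] = np.nan if rec.mpi is None else rec.mpi
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_subgroup_table(
    path: str | Path,
    registry: IndicatorRegistry,
    records: Iterable[DistrictRecord] | None = None,
) -> list[DistrictRecord] | pd.DataFrame:
    """Read a subgroup CSV (``district_id,dimension,subgroup,<equity ids>``).

    If `records` is given, subgroup maps are attached in place and the
    updated records are returned; otherwise the raw frame is returned.
    """
    df = pd.read_csv(path, dtype={"district_id": str, "dimension": str, "subgroup": str})
    eq_cols = [c for c in df.columns if c in set(registry.equity_subset)]
    if records is None:
        return df
    by_id = {r.district_id: r for r in records}
    for _, row in df.iterrows():
        rec = by_id.get(row["district_id"])
        if rec is None:
            raise ValueError(f"{path}: unknown district {row['district_id']!r}")
        vals = {}
        for col in eq_cols:
            if not pd.isna(row[col]):
                vals[col] = _check_range(float(row[col]), rec.district_id, col)
        rec.subgroups[(row["dimension"], row["subgroup"])] = vals
    return list(by_id.values())


def write_subgroup_table(
    records: Iterable[DistrictRecord],
    registry: IndicatorRegistry,
    path: str | Path,
) -> None:
    rows = []
    for rec in records:
        for (dim, label), vals in rec.subgroups.items():
            row: dict[str, object] = {
                "district_id": rec.district_id,
                "dimension": dim,
                "subgroup": label,
            }
            for iid in registry.equity_subset:
                row[iid] = vals.get(iid, np.nan)
            rows.append(row)
    cols = ["district_id", "dimension", "subgroup"] + list(registry.equity_subset)
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def write_results(results: Iterable[IndexResult], path: str | Path) -> None:
    """Write index results to CSV, one row per district.

    Columns: district_id, uhcd, service_coverage,
    financial_risk_protection, tercile, then one ``domain_<key>`` and one
    ``area_<key>`` column per hierarchy node.  Full float precision is
    kept so a write/read round-trip preserves at least 6 significant
    digits.
    """
    results = list(results)
    if not results:
        raise ValueError("no results to write")
    seen: set[str] = set()
    rows = []
    for res in results:
        if res.district_id in seen:
            raise ValueError(f"duplicate district_id in results: {res.district_id!r}")
        seen.add(res.district_id)
        row: dict[str, object] = {
            "district_id": res.district_id,
            "uhcd": res.uhcd,
            "service_coverage": res.service_coverage,
            "financial_risk_protection": res.financial_risk_protection,
            "tercile": res.tercile or "",
        }
        for dkey, score in res.domain_scores.items():
            row[f"domain_{dkey}"] = score
        for akey, score in res.area_scores.items():
            row[f"area_{akey}"] = score
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_results(path: str | Path) -> list[IndexResult]:
    """Inverse of :func:`write_results`."""
    df = pd.read_csv(path, dtype={"district_id": str, "tercile": str})
    out = []
    for _, row in df.iterrows():
        domain_scores = {
            c[len("domain_"):]: float(row[c])
            for c in df.columns
            if c.startswith("domain_")
        }
        area_scores = {
            c[len("area_"):]: float(row[c]) for c in df.columns if c.startswith("area_")
        }
        tercile = row.get("tercile")
        if pd.isna(tercile) or tercile == "":
            tercile = None
        out.append(
            IndexResult(
                district_id=row["district_id"],
                uhcd=float(row["uhcd"]),
                domain_scores=domain_scores,
                area_scores=area_scores,
                service_coverage=float(row["service_coverage"]),
                financial_risk_protection=float(row["financial_risk_protection"]),
                tercile=tercile,
            )
        )
    return out
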