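"""Composite index construction.

The index aggregates oriented indicator values (0-100) by geometric
means at three levels: indicators within a tracer area, areas within a
tracer domain, and the five domains into the overall index.  A small
positive floor is applied before every geometric mean so that a single
zero cannot annihilate the index; the floor is configurable and carried
through run logs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import DistrictRecord, IndexResult, IndicatorRegistry

__all__ = [
    "AggregationSpec",
    "orient",
    "geometric_mean",
    "compute_index",
    "compute_indices",
    "classify_terciles",
    "summarize",
]

METHODS = ("geometric", "arithmetic", "flat_geometric")


@dataclass(frozen=True)
class AggregationSpec:
    """How scores are pooled at each level of the hierarchy.

    ``geometric`` (default) pools with geometric means at every level;
    ``arithmetic`` uses plain means; ``flat_geometric`` computes the
    overall index as a single geometric mean of all oriented indicators
    (the hierarchy is still reported for reference).
    """

    method: str = "geometric"
    floor: float = 0.1

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.method in ("geometric", "flat_geometric") and not (0 < self.floor < 1):
            raise ValueError(f"floor must be in (0, 1), got {self.floor}")


def orient(value: float, orientation: str) -> float:
    """Map a raw indicator value to the higher-is-better scale.

    Coverage indicators pass through; adverse incidences are
    complemented (100 - value).
    """
    if not (0.0 <= value <= 100.0):
        raise ValueError(f"value {value} outside [0, 100]")
    if orientation == "coverage":
        return float(value)
    if orientation == "adverse_incidence":
        return 100.0 - float(value)
    raise ValueError(f"unknown orientation {orientation!r}")


def geometric_mean(values: Sequence[float], floor: float = 0.1) -> float:
    """Floored geometric mean of percentages.

    Each value is raised to at least `floor` before taking logs, so the
    result lies in [floor, 100].
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("geometric_mean of an empty list")
    if np.any(arr < 0) or np.any(arr > 100 * (1 + 1e-12)):
        raise ValueError("values outside [0, 100]")
    arr = np.clip(arr, floor, 100.0)
    return min(float(np.exp(np.mean(np.log(arr)))), 100.0)


def _pool(values: Sequence[float], spec: AggregationSpec) -> float:
    if spec.method == "arithmetic":
        return float(np.mean(list(values)))
    return geometric_mean(values, spec.floor)


def oriented_values(record: DistrictRecord, registry: IndicatorRegistry) -> dict[str, float]:
    """All registry indicators of a record on the higher-is-better scale.

    Raises if any registry indicator is missing (imputation is a
    prerequisite of index construction).
    """
    out = {}
    for ind in registry.indicators:
        if ind.id not in record.values:
            raise ValueError(
                f"district {record.district_id!r}: missing indicator {ind.id!r} "
                "(run imputation first)"
            )
        out[ind.id] = orient(record.values[ind.id], ind.orientation)
    return out


def compute_index(
    record: DistrictRecord,
    registry: IndicatorRegistry,
    spec: AggregationSpec = AggregationSpec(),
) -> IndexResult:
    """Build the hierarchical composite index for one district.

    Area scores pool the oriented indicators of the area, domain scores
    pool their area scores, and the overall index pools the domain
    scores.  The service-coverage component pools every non-FRP domain
    (FRP = financial risk protection, identified as the domain whose
    indicators include the adverse incidences); the FRP component is
    that domain's score.
    """
    oriented = oriented_values(record, registry)
    area_scores = {
        akey: _pool([oriented[i] for i in ids], spec)
        for akey, ids in registry.areas.items()
    }
    domain_scores = {
        dkey: _pool([area_scores[a] for a in areas], spec)
        for dkey, areas in registry.domains.items()
    }
    frp_domains = {registry.domain_of(i) for i in registry.adverse_ids()}
    frp_key = next(iter(frp_domains)) if len(frp_domains) == 1 else None
    sc_keys = [d for d in registry.domains if d != frp_key]

    if spec.method == "flat_geometric":
        all_vals = [oriented[i] for i in registry.indicator_ids]
        uhcd = geometric_mean(all_vals, spec.floor)
        sc_vals = [oriented[i] for i in registry.indicator_ids
                   if registry.domain_of(i) != frp_key]
        service_coverage = geometric_mean(sc_vals, spec.floor) if sc_vals else uhcd
    else:
        uhcd = _pool(list(domain_scores.values()), spec)
        service_coverage = (
            _pool([domain_scores[d] for d in sc_keys], spec) if sc_keys else uhcd
        )
    frp = domain_scores[frp_key] if frp_key is not None else uhcd
    return IndexResult(
        district_id=record.district_id,
        uhcd=uhcd,
        domain_scores=domain_scores,
        area_scores=area_scores,
        service_coverage=service_coverage,
        financial_risk_protection=frp,
    )


def compute_indices(
    records: Iterable[DistrictRecord],
    registry: IndicatorRegistry,
    spec: AggregationSpec = AggregationSpec(),
    terciles: bool = True,
) -> list[IndexResult]:
    """Index every district and (optionally) attach tercile labels."""
    results = [compute_index(rec, registry, spec) for rec in records]
    if terciles and len(results) >= 3:
        labels = classify_terciles({r.district_id: r.uhcd for r in results})
        for r in results:
            r.tercile = labels[r.district_id]
    return results


def classify_terciles(indices: Mapping[str, float]) -> dict[str, str]:
    """Split districts into low/medium/high thirds by index value.

    Districts are sorted ascending (ties broken by district id) and cut
    into three contiguous rank groups with sizes as equal as possible;
    when n is not divisible by 3 the lowest groups take the extra
    members.
    """
    n = len(indices)
    if n < 3:
        raise ValueError("tercile classification needs at least 3 districts")
    order = sorted(indices, key=lambda d: (indices[d], d))
    base, rem = divmod(n, 3)
    sizes = [base + (1 if g < rem else 0) for g in range(3)]
    labels = {}
    pos = 0
    for size, name in zip(sizes, ("low", "medium", "high")):
        for did in order[pos:pos + size]:
            labels[did] = name
        pos += size
    return labels


def summarize(
    results: Iterable[IndexResult],
    threshold: float = 50.0,
) -> pd.DataFrame:
    """Summary statistics by measure (overall index, components, domains).

    One row per measure with count, median, IQR (linear-interpolation
    quantiles), sample SD (0 for a single district), min, max, and the
    share of districts strictly above `threshold` (with its
    numerator/denominator).
    """
    results = list(results)
    if not results:
        raise ValueError("summarize needs at least one result")
    measures: dict[str, list[float]] = {
        "uhcd": [r.uhcd for r in results],
        "service_coverage": [r.service_coverage for r in results],
    }
    for dkey in results[0].domain_scores:
        measures[f"domain_{dkey}"] = [r.domain_scores[dkey] for r in results]
    measures["financial_risk_protection"] = [
        r.financial_risk_protection for r in results
    ]
    rows = []
    for name, vals in measures.items():
        arr = np.asarray(vals, dtype=float)
        n = arr.size
        n_above = int(np.sum(arr > threshold))
        rows.append(
            {
                "measure": name,
                "n": n,
                "median": float(np.median(arr)),
                "iqr_low": float(np.quantile(arr, 0.25)),
                "iqr_high": float(np.quantile(arr, 0.75)),
                "sd": float(np.std(arr, ddof=1)) if n > 1 else 0.0,
                "min": float(arr.min()),
                "max": float(arr.max()),
                "threshold": threshold,
                "n_above": n_above,
                "n_total": n,
                "share_above_pct": round(100.0 * n_above / n, 1),
            }
        )
    return pd.DataFrame(rows)
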