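"""Subgroup index construction and rank-based inequality measures.

The subgroup index scales a district's overall index by the ratio of
the subgroup's geometric mean over the 14 equity-subset indicators to
the district's.  The concentration index and the achievement index
operate on fractional ranks with the worst-off unit first; with
aversion v = 2 the achievement index equals mean * (1 - C).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

from .index import AggregationSpec, geometric_mean
from .model import DistrictRecord, IndicatorRegistry

__all__ = [
    "EquityResult",
    "subgroup_index",
    "fractional_rank",
    "concentration_index",
    "achievement_index",
    "district_subgroup_results",
]


@dataclass
class EquityResult:
    district_id: str
    dimension: str
    subgroup: str
    ratio: float
    subgroup_uhcd: float
    gap: float  # district uhcd - subgroup uhcd (positive = subgroup worse off)


def _hierarchical_gm(
    values: Mapping[str, float], registry: IndicatorRegistry, floor: float
) -> float:
    """Area/domain-structured GM restricted to the given indicator ids."""
    area_scores = {}
    for akey, ids in registry.areas.items():
        present = [values[i] for i in ids if i in values]
        if present:
            area_scores[akey] = geometric_mean(present, floor)
    domain_scores = []
    for dkey, areas in registry.domains.items():
        present = [area_scores[a] for a in areas if a in area_scores]
        if present:
            domain_scores.append(geometric_mean(present, floor))
    return geometric_mean(domain_scores, floor)


def subgroup_index(
    sub_values: Mapping[str, float],
    dist_values: Mapping[str, float],
    district_uhcd: float,
    floor: float = 0.1,
    district_id: str = "",
    dimension: str = "",
    subgroup: str = "",
    hierarchical: bool = False,
    registry: IndicatorRegistry | None = None,
) -> EquityResult:
    """Subgroup composite index via the geometric-mean ratio.

    Both value maps must cover the same equity-subset ids.  The ratio
    GM(subgroup)/GM(district) multiplies the district index; the result
    is capped at 100 (advantaged subgroups can have ratios above 1).  By
    default the GMs are flat over the subset; `hierarchical` pools
    through the registry's area/domain tree instead.
    """
    sub_ids, dist_ids = set(sub_values), set(dist_values)
    if sub_ids != dist_ids:
        only_sub = sorted(sub_ids - dist_ids)
        only_dist = sorted(dist_ids - sub_ids)
        raise ValueError(
            f"mismatched indicator sets: only in subgroup {only_sub}, "
            f"only in district {only_dist}"
        )
    if hierarchical:
        if registry is None:
            raise ValueError("hierarchical subgroup index needs a registry")
        gm_sub = _hierarchical_gm(sub_values, registry, floor)
        gm_dist = _hierarchical_gm(dist_values, registry, floor)
    else:
        gm_sub = geometric_mean(list(sub_values.values()), floor)
        gm_dist = geometric_mean(list(dist_values.values()), floor)
    ratio = gm_sub / gm_dist
    sub_uhcd = min(ratio * district_uhcd, 100.0)
    return EquityResult(
        district_id=district_id,
        dimension=dimension,
        subgroup=subgroup,
        ratio=ratio,
        subgroup_uhcd=sub_uhcd,
        gap=district_uhcd - sub_uhcd,
    )


def fractional_rank(
    order_values: Mapping[str, float], ascending_means_worst: bool = True
) -> dict[str, float]:
    """Fractional ranks R_i = (rank_i - 0.5) / n in (0, 1), worst-off first.

    With `ascending_means_worst` the smallest ranking value is treated
    as worst off (rank closest to 0); flip the flag to reverse.  Ties
    share the mean of their positions.
    """
    keys = list(order_values)
    if len(keys) < 2:
        raise ValueError("fractional ranks need at least 2 units")
    vals = np.array([order_values[k] for k in keys], dtype=float)
    if not ascending_means_worst:
        vals = -vals
    ranks = stats.rankdata(vals, method="average")
    frac = (ranks - 0.5) / len(keys)
    return dict(zip(keys, frac))


def _align(values: Mapping[str, float], ranks: Mapping[str, float]):
    if set(values) != set(ranks):
        raise ValueError("value and rank maps cover different units")
    keys = list(values)
    x = np.array([values[k] for k in keys], dtype=float)
    r = np.array([ranks[k] for k in keys], dtype=float)
    return x, r


def concentration_index(
    values: Mapping[str, float], fractional_ranks: Mapping[str, float]
) -> float:
    """Concentration index C = (2 / (n mu)) * sum(x_i R_i) - 1.

    With fractional ranks (i - 0.5)/n this equals 2 cov(x, R)/mu using
    the population covariance, so no additional 1/n correction is
    applied.  C > 0 means the quantity concentrates among the
    better-off (ranked last); C = 0 under no rank-value association.
    """
    x, r = _align(values, fractional_ranks)
    mu = x.mean()
    if mu <= 0:
        raise ValueError("concentration index requires a positive mean")
    n = x.size
    return float(2.0 / (n * mu) * np.sum(x * r) - 1.0)


def achievement_index(
    values: Mapping[str, float],
    fractional_ranks: Mapping[str, float],
    v: float = 2.0,
) -> float:
    """Rank-weighted achievement index A(v) = sum(w x) / sum(w).

    Weights w_i = v (1 - R_i)^(v-1) give the worst-off (R near 0) the
    largest weight.  v = 1 collapses to the arithmetic mean; v = 2
    satisfies A = mu (1 - C).
    """
    if v < 1:
        raise ValueError("inequality aversion v must be >= 1")
    x, r = _align(values, fractional_ranks)
    w = v * (1.0 - r) ** (v - 1.0)
    return float(np.sum(w * x) / np.sum(w))


def district_subgroup_results(
    records,
    results_by_id: Mapping[str, "object"],
    registry: IndicatorRegistry,
    spec: AggregationSpec = AggregationSpec(),
    hierarchical: bool = False,
) -> list[EquityResult]:
    """Subgroup indices for every (district, dimension, subgroup) present."""
    out: list[EquityResult] = []
    eq = registry.equity_subset
    for rec in records:
        res = results_by_id.get(rec.district_id)
        if res is None or not rec.subgroups:
            continue
        dist_vals = {i: rec.values[i] for i in eq if i in rec.values}
        for (dim, label), sub_vals in sorted(rec.subgroups.items()):
            usable = {i: sub_vals[i] for i in dist_vals if i in sub_vals}
            if len(usable) != len(dist_vals):
                continue
            out.append(
                subgroup_index(
                    usable,
                    dist_vals,
                    res.uhcd,
                    floor=spec.floor,
                    district_id=rec.district_id,
                    dimension=dim,
                    subgroup=label,
                    hierarchical=hierarchical,
                    registry=registry,
                )
            )
    return out
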