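"""Rank-stability analysis under alternative index specifications.

Variants: arithmetic-mean aggregation, a flat overall geometric mean,
and an inequality-adjusted index where each equity-subset indicator's
population value is replaced by its achievement index over the wealth
quintile profile.  Leave-one-out drops each indicator in turn.  All
comparisons are Spearman rank correlations against the baseline
hierarchical-geometric ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

from .equity import achievement_index
from .index import AggregationSpec, compute_index
from .model import DistrictRecord, IndicatorRegistry
from .simulate import WEALTH_QUINTILES

__all__ = [
    "SensitivityReport",
    "spearman_rho",
    "rank_map",
    "run_variant",
    "leave_one_out",
    "run_sensitivity",
]

logger = logging.getLogger(__name__)

VARIANTS = ("arithmetic", "flat_geometric", "achievement_adjusted")


@dataclass
class SensitivityReport:
    baseline: dict[str, float]
    variants: dict[str, dict[str, float]] = field(default_factory=dict)
    rho: dict[str, float] = field(default_factory=dict)
    dropped_indicator_rhos: dict[str, float] = field(default_factory=dict)

    @property
    def min_drop_rho(self) -> tuple[str, float] | None:
        if not self.dropped_indicator_rhos:
            return None
        iid = min(self.dropped_indicator_rhos, key=self.dropped_indicator_rhos.get)
        return iid, self.dropped_indicator_rhos[iid]


def rank_map(values: Mapping[str, float]) -> dict[str, float]:
    """Mid-ranks 1..n (ties averaged)."""
    keys = list(values)
    ranks = stats.rankdata([values[k] for k in keys], method="average")
    return dict(zip(keys, ranks))


def spearman_rho(
    rank_basis_a: Mapping[str, float], rank_basis_b: Mapping[str, float]
) -> float:
    """Spearman correlation of two rankings over the same district set."""
    if set(rank_basis_a) != set(rank_basis_b):
        only_a = sorted(set(rank_basis_a) - set(rank_basis_b))
        only_b = sorted(set(rank_basis_b) - set(rank_basis_a))
        raise ValueError(
            f"district sets differ: only in first {only_a[:5]}, "
            f"only in second {only_b[:5]}"
        )
    keys = list(rank_basis_a)
    if len(keys) < 3:
        raise ValueError("Spearman correlation needs at least 3 districts")
    a = stats.rankdata([rank_basis_a[k] for k in keys], method="average")
    b = stats.rankdata([rank_basis_b[k] for k in keys], method="average")
    if np.array_equal(a, b):  # identical orderings (incl. all-tied) -> exactly 1
        return 1.0
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("Spearman correlation undefined: one ranking is constant")
    rho, _ = stats.spearmanr(a, b)
    return float(rho)


def _achievement_adjusted_record(
    rec: DistrictRecord, registry: IndicatorRegistry, v: float
) -> DistrictRecord:
    """Replace equity-subset values with achievement indices over the
    wealth-quintile profile; indicators without a profile keep the
    district value."""
    adj = rec.copy()
    n_fallback = 0
    for iid in registry.equity_subset:
        profile = []
        for q in WEALTH_QUINTILES:
            sub = rec.subgroups.get(("wealth", q))
            if sub is not None and iid in sub:
                profile.append(sub[iid])
        if len(profile) < 2:
            n_fallback += 1
            continue
        m = len(profile)
        # poorest quintile first -> fractional ranks (i - 0.5)/m
        vals = {f"g{i}": x for i, x in enumerate(profile)}
        ranks = {f"g{i}": (i + 0.5) / m for i in range(m)}
        adj.values[iid] = float(np.clip(achievement_index(vals, ranks, v), 0.0, 100.0))
    if n_fallback:
        logger.info(
            "district %s: %d equity indicators lack wealth profiles, kept baseline",
            rec.district_id,
            n_fallback,
        )
    return adj


def run_variant(
    records: Iterable[DistrictRecord],
    registry: IndicatorRegistry,
    variant: str,
    floor: float = 0.1,
    aversion: float = 2.0,
) -> dict[str, float]:
    """Index value per district under one alternative specification."""
    records = list(records)
    if variant in ("arithmetic", "flat_geometric"):
        spec = AggregationSpec(method=variant, floor=floor)
        return {
            r.district_id: compute_index(r, registry, spec).uhcd for r in records
        }
    if variant == "achievement_adjusted":
        if not any(
            ("wealth", q) in r.subgroups for r in records for q in WEALTH_QUINTILES
        ):
            raise ValueError(
                "achievement_adjusted variant requires wealth subgroup data"
            )
        spec = AggregationSpec(method="geometric", floor=floor)
        out = {}
        for rec in records:
            adj = _achievement_adjusted_record(rec, registry, aversion)
            out[rec.district_id] = compute_index(adj, registry, spec).uhcd
        return out
    raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")


def leave_one_out(
    records: Iterable[DistrictRecord],
    registry: IndicatorRegistry,
    baseline_ranking: Mapping[str, float],
    floor: float = 0.1,
) -> dict[str, float]:
    """Spearman rho against baseline after dropping each indicator."""
    records = list(records)
    spec = AggregationSpec(method="geometric", floor=floor)
    out = {}
    for iid in registry.indicator_ids:
        reduced = registry.drop(iid)
        values = {
            r.district_id: compute_index(r, reduced, spec).uhcd for r in records
        }
        out[iid] = spearman_rho(values, baseline_ranking)
    return out


def run_sensitivity(
    records: Iterable[DistrictRecord],
    registry: IndicatorRegistry,
    floor: float = 0.1,
    aversion: float = 2.0,
    variants: Iterable[str] = VARIANTS,
) -> SensitivityReport:
    """Full battery: variants plus leave-one-out, all vs the baseline."""
    records = list(records)
    spec = AggregationSpec(method="geometric", floor=floor)
    baseline = {
        r.district_id: compute_index(r, registry, spec).uhcd for r in records
    }
    report = SensitivityReport(baseline=baseline)
    for variant in variants:
        if variant == "achievement_adjusted" and not any(
            r.subgroups for r in records
        ):
            logger.info("skipping achievement_adjusted variant: no subgroup data")
            continue
        values = run_variant(records, registry, variant, floor, aversion)
        report.variants[variant] = values
        report.rho[variant] = spearman_rho(values, baseline)
    report.dropped_indicator_rhos = leave_one_out(records, registry, baseline, floor)
    return report
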