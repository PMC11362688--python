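"""Missing-value imputation for district tables.

Three mechanisms, applied in this order by :func:`impute_all`:
single-step inheritance from a parent district (redistricting gaps),
stratified single-draw hot-deck (block gaps in service capacity), and
OLS regression with state intercepts (financial-protection incidences).
Imputation never alters a present cell and stamps provenance flags.
"""

from __future__ import annotations

import logging
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .model import DistrictRecord, IndicatorRegistry

__all__ = ["inherit_from_parent", "hot_deck", "regression_impute", "impute_all"]

logger = logging.getLogger(__name__)


def inherit_from_parent(
    records: Iterable[DistrictRecord],
    parent_map: Mapping[str, str],
    indicator_ids: Sequence[str],
) -> list[DistrictRecord]:
    """Copy a parent district's values into its child's missing cells.

    Single-step only: the parent itself must hold every listed indicator
    the child lacks.  Cyclic parent maps are rejected.
    """
    records = list(records)
    by_id = {r.district_id: r for r in records}
    for child in parent_map:
        seen = {child}
        cur = child
        while cur in parent_map:
            cur = parent_map[cur]
            if cur in seen:
                raise ValueError(f"cyclic parent_map involving {cur!r}")
            seen.add(cur)
    for child_id, parent_id in parent_map.items():
        if child_id not in by_id:
            continue
        if parent_id not in by_id:
            raise ValueError(
                f"child {child_id!r}: parent district {parent_id!r} not in table"
            )
        child, parent = by_id[child_id], by_id[parent_id]
        for iid in indicator_ids:
            if iid in child.values:
                continue
            if iid not in parent.values:
                raise ValueError(
                    f"child {child_id!r}: parent {parent_id!r} also missing "
                    f"{iid!r} (single-step inheritance only)"
                )
            child.values[iid] = parent.values[iid]
            child.imputed.add(iid)
    return records


def hot_deck(
    records: Iterable[DistrictRecord],
    target_ids: Sequence[str],
    strata_key: Callable[[DistrictRecord], str] | None = None,
    seed: int = 0,
    fallback_to_global: bool = False,
) -> list[DistrictRecord]:
    """Stratified single-draw hot-deck imputation.

    Recipients (districts missing any target indicator) each draw one
    donor uniformly at random — with replacement across recipients —
    from the complete donors in their stratum, and copy the donor's
    values into their missing cells.  Default strata are states.  A
    stratum holding recipients but no donors is an error unless
    `fallback_to_global` allows drawing from the global donor pool.
    """
    records = list(records)
    if strata_key is None:
        strata_key = lambda r: r.state_id  # noqa: E731
    rng = np.random.default_rng(seed)
    donors_by_stratum: dict[str, list[DistrictRecord]] = {}
    global_donors: list[DistrictRecord] = []
    for rec in records:
        if rec.is_complete(target_ids):
            donors_by_stratum.setdefault(strata_key(rec), []).append(rec)
            global_donors.append(rec)
    for rec in records:
        miss = rec.missing(target_ids)
        if not miss:
            continue
        stratum = strata_key(rec)
        pool = donors_by_stratum.get(stratum, [])
        if not pool:
            if not fallback_to_global:
                raise ValueError(
                    f"hot-deck stratum {stratum!r} has recipients but no "
                    "complete donors (use fallback_to_global to widen the pool)"
                )
            pool = global_donors
            if not pool:
                raise ValueError("hot-deck: no complete donors anywhere")
        donor = pool[int(rng.integers(len(pool)))]
        for iid in miss:
            rec.values[iid] = donor.values[iid]
            rec.imputed.add(iid)
    return records


def _domain_means(
    rec: DistrictRecord, registry: IndicatorRegistry, domains: Sequence[str]
) -> dict[str, float] | None:
    """Mean oriented value of each listed domain over present indicators."""
    out = {}
    for dkey in domains:
        ids = [i for a in registry.domains[dkey] for i in registry.areas[a]]
        vals = []
        for iid in ids:
            if iid in rec.values:
                v = rec.values[iid]
                if registry.get(iid).orientation == "adverse_incidence":
                    v = 100.0 - v
                vals.append(v)
        if not vals:
            return None
        out[f"_mean_{dkey}"] = float(np.mean(vals))
    return out


def regression_impute(
    records: Iterable[DistrictRecord],
    registry: IndicatorRegistry,
    target_ids: Sequence[str] | None = None,
    covariate_ids: Sequence[str] | None = None,
    details: dict | None = None,
) -> list[DistrictRecord]:
    """OLS imputation of target indicators with state fixed intercepts.

    Defaults: targets are the adverse-incidence indicators (catastrophic
    expenditure and impoverishment); covariates are insurance coverage
    plus the per-district mean of each non-target domain.  Missing
    targets receive the fitted value, clamped to [0, 100].  Coefficients
    are logged and copied into `details` when a dict is passed.
    """
    records = list(records)
    if target_ids is None:
        target_ids = registry.adverse_ids()
    frp_domains = {registry.domain_of(t) for t in target_ids if t in registry}
    mean_domains = [d for d in registry.domains if d not in frp_domains]

    def covariates(rec: DistrictRecord) -> dict[str, float] | None:
        feats: dict[str, float] = {}
        if covariate_ids is not None:
            for cid in covariate_ids:
                if cid not in rec.values:
                    return None
                feats[cid] = rec.values[cid]
            return feats
        if "insurance" in rec.values:
            feats["insurance"] = rec.values["insurance"]
        elif "insurance" in registry:
            return None
        dm = _domain_means(rec, registry, mean_domains)
        if dm is None:
            return None
        feats.update(dm)
        return feats

    states = sorted({r.state_id for r in records})
    state_pos = {s: i for i, s in enumerate(states)}

    for target in target_ids:
        feat_rows, y_vals, fit_recs, predict_recs = [], [], [], []
        fnames: list[str] | None = None
        for rec in records:
            feats = covariates(rec)
            if feats is None:
                continue
            if fnames is None:
                fnames = sorted(feats)
            row = (rec, [feats[f] for f in fnames])
            if target in rec.values:
                feat_rows.append(row[1])
                y_vals.append(rec.values[target])
                fit_recs.append(rec)
            else:
                predict_recs.append(row)
        if not predict_recs:
            continue

        def design(rec, feats_vec, keep):
            dummies = [0.0] * (len(states) - 1)
            if state_pos[rec.state_id] > 0:
                dummies[state_pos[rec.state_id] - 1] = 1.0
            return [1.0] + [feats_vec[i] for i in keep] + dummies

        keep = list(range(len(fnames or [])))
        X = np.asarray(
            [design(r, f, keep) for r, f in zip(fit_recs, feat_rows)], dtype=float
        )
        y = np.asarray(y_vals, dtype=float)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            if covariate_ids is not None:
                raise ValueError(
                    f"regression imputation of {target!r}: rank-deficient design "
                    f"(rank {np.linalg.matrix_rank(X)} < {X.shape[1]} columns); "
                    "reduce covariates"
                )
            # default covariates can be collinear (e.g. degenerate synthetic
            # data): keep a maximal independent feature subset
            base = np.asarray(
                [design(r, f, []) for r, f in zip(fit_recs, feat_rows)], dtype=float
            )
            keep = []
            rank = np.linalg.matrix_rank(base)
            for i in range(len(fnames)):
                trial = np.column_stack(
                    [base] + [np.asarray(feat_rows)[:, j] for j in keep + [i]]
                )
                r = np.linalg.matrix_rank(trial)
                if r > rank + len(keep):
                    keep.append(i)
            dropped = [fnames[i] for i in range(len(fnames)) if i not in keep]
            logger.info(
                "regression_impute %s: dropped collinear covariates %s",
                target, dropped,
            )
            X = np.asarray(
                [design(r, f, keep) for r, f in zip(fit_recs, feat_rows)], dtype=float
            )
        n_params = X.shape[1] - (len(states) - 1)  # intercept + kept features
        if X.shape[0] < n_params + 1:
            raise ValueError(
                f"regression imputation of {target!r}: only {X.shape[0]} complete "
                f"cases for {n_params} parameters"
            )
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        coef_names = ["intercept"] + [fnames[i] for i in keep] + [
            f"state[{s}]" for s in states[1:]
        ]
        coefs = dict(zip(coef_names, [float(b) for b in beta]))
        logger.info("regression_impute %s: coefficients %s", target, coefs)
        if details is not None:
            details[target] = coefs
        for rec, feats_vec in predict_recs:
            fitted = float(np.asarray(design(rec, feats_vec, keep)) @ beta)
            rec.values[target] = float(np.clip(fitted, 0.0, 100.0))
            rec.imputed.add(target)
    return records


def impute_all(
    records: Iterable[DistrictRecord],
    registry: IndicatorRegistry,
    parent_map: Mapping[str, str] | None = None,
    seed: int = 0,
    hot_deck_targets: Sequence[str] | None = None,
    fallback_to_global: bool = False,
    details: dict | None = None,
) -> list[DistrictRecord]:
    """Full chain: inheritance, then hot-deck, then regression.

    Hot-deck targets default to every non-adverse registry indicator
    still missing anywhere; regression handles the adverse incidences.
    """
    records = list(records)
    if parent_map:
        records = inherit_from_parent(records, parent_map, registry.indicator_ids)
    adverse = set(registry.adverse_ids())
    if hot_deck_targets is None:
        missing_any: set[str] = set()
        for rec in records:
            missing_any.update(rec.missing(registry.indicator_ids))
        hot_deck_targets = [
            i for i in registry.indicator_ids if i in missing_any and i not in adverse
        ]
    if hot_deck_targets:
        records = hot_deck(
            records, hot_deck_targets, seed=seed, fallback_to_global=fallback_to_global
        )
    still_missing = any(rec.missing(registry.indicator_ids) for rec in records)
    if still_missing:
        records = regression_impute(records, registry, details=details)
    return records
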