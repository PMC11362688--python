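"""Synthetic district tables with state-clustered structure.

Generates district x indicator tables that mimic the statistical shape
the downstream analysis assumes: a shared latent district quality that
decomposes into state and district normal effects, domain-level target
levels, a poverty index negatively correlated with quality, wealth- and
dimension-graded subgroups, and structured missingness.  Everything is
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .model import DistrictRecord, IndicatorRegistry

__all__ = [
    "SimulationConfig",
    "simulate_districts",
    "simulate_subgroups",
    "inject_missingness",
    "DISADVANTAGED",
]

CLAMP_LO, CLAMP_HI = 0.1, 99.9

#: default central level per domain (oriented scale)
DEFAULT_DOMAIN_TARGETS = {
    "rmnch": 64.8,
    "infectious": 82.8,
    "ncd": 9.8,
    "capacity": 54.9,
    "frp": 66.6,
}

#: disadvantaged subgroup label per inequality dimension
DISADVANTAGED = {
    "wealth": "q1",
    "residence": "rural",
    "religion": "minority",
    "social_group": "marginalized",
}

WEALTH_QUINTILES = ("q1", "q2", "q3", "q4", "q5")


@dataclass
class SimulationConfig:
    """Knobs for the synthetic generator.

    `sigma_between` / `sigma_within` are the SDs (percentage points) of
    the state and district latent effects.  `domain_targets` sets the
    central oriented level per domain; `offset_spread` spaces indicator
    offsets evenly in ``[-spread, +spread]`` within each domain unless
    `indicator_offsets` overrides them.  `mpi_corr` is the target
    correlation between latent quality and the simulated poverty index
    (negative: poorer districts have lower quality).
    """

    n_states: int = 33
    districts_per_state: int | Sequence[int] | None = None
    sigma_between: float = np.sqrt(31.5)
    sigma_within: float = np.sqrt(13.9)
    domain_targets: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DOMAIN_TARGETS)
    )
    offset_spread: float = 4.0
    indicator_offsets: dict[str, float] | None = None
    sigma_indicator: float = 2.0
    wealth_gap: float = 7.0
    residence_gap: float = 3.0
    religion_gap: float = 2.0
    social_group_gap: float = 3.0
    subgroup_noise: float = 1.0
    mpi_corr: float = -0.5
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_between < 0 or self.sigma_within < 0 or self.sigma_indicator < 0:
            raise ValueError("standard deviations must be >= 0")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        for dom, t in self.domain_targets.items():
            if not (0.0 < t < 100.0):
                raise ValueError(f"domain target for {dom!r} must be in (0, 100)")
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")

    def district_counts(self) -> list[int]:
        """Districts per state; default splits 687 as evenly as possible."""
        if self.districts_per_state is None:
            total = 687
            base, rem = divmod(total, self.n_states)
            return [base + (1 if j < rem else 0) for j in range(self.n_states)]
        if isinstance(self.districts_per_state, int):
            return [self.districts_per_state] * self.n_states
        counts = list(self.districts_per_state)
        if len(counts) != self.n_states:
            raise ValueError(
                f"districts_per_state has {len(counts)} entries for "
                f"{self.n_states} states"
            )
        return counts

    def to_dict(self) -> dict:
        def plain(v):
            if isinstance(v, np.generic):
                return v.item()
            if isinstance(v, (list, tuple)):
                return [plain(x) for x in v]
            if isinstance(v, dict):
                return {k: plain(x) for k, x in v.items()}
            return v

        return {k: plain(v) for k, v in asdict(self).items()}


def _offsets(config: SimulationConfig, registry: IndicatorRegistry) -> dict[str, float]:
    if config.indicator_offsets is not None:
        return {i: float(config.indicator_offsets.get(i, 0.0))
                for i in registry.indicator_ids}
    out: dict[str, float] = {}
    for dkey, areas in registry.domains.items():
        ids = [i for a in areas for i in registry.areas[a]]
        if len(ids) == 1:
            offs = [0.0]
        else:
            offs = np.linspace(-config.offset_spread, config.offset_spread, len(ids))
        out.update(dict(zip(ids, offs)))
    return out


def _tune_mpi(quality: np.ndarray, target_corr: float, rng: np.random.Generator) -> np.ndarray:
    """Poverty index in [0, 1], rank-decreasing in quality, with the noise
    scale bisected so the achieved correlation is close to `target_corr`."""
    n = quality.size
    base = 1.0 - (stats.rankdata(quality) - 0.5) / n  # in (0, 1), high q -> low mpi
    noise = rng.standard_normal(n)

    def corr_at(lam: float) -> float:
        mpi = np.clip(base + lam * noise, 0.0, 1.0)
        if np.std(mpi) == 0:
            return 0.0
        return float(np.corrcoef(mpi, quality)[0, 1])

    if corr_at(0.0) >= target_corr:  # already weaker than target
        return np.clip(base, 0.0, 1.0)
    lo, hi = 0.0, 0.05
    while corr_at(hi) < target_corr and hi < 1e3:
        hi *= 2.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if corr_at(mid) < target_corr:
            lo = mid
        else:
            hi = mid
    lam = 0.5 * (lo + hi)
    return np.clip(base + lam * noise, 0.0, 1.0)


def simulate_districts(
    config: SimulationConfig,
    registry: IndicatorRegistry,
    return_latent: bool = False,
) -> list[DistrictRecord] | tuple[list[DistrictRecord], dict[str, float]]:
    """Generate one record per district.

    Each indicator value is ``clamp(domain target + state effect +
    district effect + indicator offset + cell noise)`` on the oriented
    scale, clamped to [0.1, 99.9]; the per-cell noise (SD
    `sigma_indicator`, set 0 for a purely latent-driven table) keeps
    district profiles from being perfectly parallel, so rank-stability
    comparisons are non-degenerate.  Adverse-incidence indicators are
    stored as incidences
    (100 - oriented value) so downstream orientation is exercised.  With
    `return_latent` the shared latent quality (state + district effect)
    is also returned, keyed by district id.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    counts = config.district_counts()
    offsets = _offsets(config, registry)
    for dkey in registry.domains:
        if dkey not in config.domain_targets:
            raise ValueError(f"no domain target for registry domain {dkey!r}")

    state_eff = rng.normal(0.0, config.sigma_between, size=config.n_states)
    records: list[DistrictRecord] = []
    latent: dict[str, float] = {}
    for j in range(config.n_states):
        sid = f"S{j + 1:02d}"
        dist_eff = rng.normal(0.0, config.sigma_within, size=counts[j])
        for k in range(counts[j]):
            did = f"{sid}_D{k + 1:03d}"
            q = state_eff[j] + dist_eff[k]
            latent[did] = float(q)
            cell_noise = (
                rng.normal(0.0, config.sigma_indicator, size=len(registry))
                if config.sigma_indicator > 0
                else np.zeros(len(registry))
            )
            values = {}
            for ind, eps in zip(registry.indicators, cell_noise):
                oriented = float(
                    np.clip(
                        config.domain_targets[ind.domain] + q + offsets[ind.id] + eps,
                        CLAMP_LO,
                        CLAMP_HI,
                    )
                )
                values[ind.id] = (
                    100.0 - oriented
                    if ind.orientation == "adverse_incidence"
                    else oriented
                )
            records.append(DistrictRecord(district_id=did, state_id=sid, values=values))

    qual = np.array([latent[r.district_id] for r in records])
    mpi = _tune_mpi(qual, config.mpi_corr, rng)
    for rec, m in zip(records, mpi):
        rec.mpi = float(m)

    if return_latent:
        return records, latent
    return records


def simulate_subgroups(
    records: Iterable[DistrictRecord],
    config: SimulationConfig,
    registry: IndicatorRegistry,
) -> list[DistrictRecord]:
    """Fill subgroup maps for the equity-subset indicators (in place).

    Wealth quintiles get a linear gradient from ``-wealth_gap`` (q1,
    poorest) to ``+wealth_gap`` (q5); the other dimensions get their
    single disadvantaged subgroup at the configured (smaller) shortfall.
    Gaussian noise of SD `subgroup_noise` is added per cell and values
    are clamped to [0.1, 99.9].
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    records = list(records)
    eq = list(registry.equity_subset)
    offsets_by_group: list[tuple[str, str, float]] = []
    wsteps = np.linspace(-config.wealth_gap, config.wealth_gap, len(WEALTH_QUINTILES))
    for label, off in zip(WEALTH_QUINTILES, wsteps):
        offsets_by_group.append(("wealth", label, float(off)))
    offsets_by_group.append(("residence", "rural", -config.residence_gap))
    offsets_by_group.append(("religion", "minority", -config.religion_gap))
    offsets_by_group.append(("social_group", "marginalized", -config.social_group_gap))

    for rec in records:
        miss = rec.missing(eq)
        if miss:
            raise ValueError(
                f"district {rec.district_id!r}: equity-subset values missing "
                f"({miss[0]!r}, ...) — simulate subgroups before injecting missingness"
            )
        for dim, label, off in offsets_by_group:
            noise = (
                rng.normal(0.0, config.subgroup_noise, size=len(eq))
                if config.subgroup_noise > 0
                else np.zeros(len(eq))
            )
            rec.subgroups[(dim, label)] = {
                iid: float(np.clip(rec.values[iid] + off + e, CLAMP_LO, CLAMP_HI))
                for iid, e in zip(eq, noise)
            }
    return records


def inject_missingness(
    records: Iterable[DistrictRecord],
    pattern: str,
    rate: float,
    seed: int,
    registry: IndicatorRegistry,
) -> list[DistrictRecord]:
    """Blank cells to exercise imputation.  Returns copies.

    ``MCAR`` blanks each indicator cell independently with probability
    `rate`; ``by_domain`` removes the whole service-capacity block
    (domain ``capacity``) for a round(rate * n) subset of districts.
    """
    if not (0.0 <= rate < 1.0):
        raise ValueError("rate must be in [0, 1)")
    if pattern not in ("MCAR", "by_domain"):
        raise ValueError(f"unknown missingness pattern {pattern!r}")
    records = [r.copy() for r in records]
    if rate == 0.0:
        return records
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    ids = registry.indicator_ids
    if pattern == "MCAR":
        for rec in records:
            mask = rng.random(len(ids)) < rate
            for iid, m in zip(ids, mask):
                if m:
                    rec.values.pop(iid, None)
    else:
        cap_ids = _domain_ids(registry, "capacity")
        n_sel = int(round(rate * len(records)))
        chosen = rng.choice(len(records), size=n_sel, replace=False)
        for idx in chosen:
            for iid in cap_ids:
                records[idx].values.pop(iid, None)
    return records


def _domain_ids(registry: IndicatorRegistry, domain: str) -> list[str]:
    return [i for a in registry.domains.get(domain, []) for i in registry.areas[a]]
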