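"""Two-level null-model variance decomposition and related summaries.

The model is y_ij = b0 + u_j + e_ij with u_j ~ N(0, s2_between) at the
state level and e_ij ~ N(0, s2_within).  The primary estimator is
restricted maximum likelihood (closed-form profiled criterion for the
one-way layout, optimized over the two variances); a method-of-moments
one-way ANOVA estimator with the unbalanced-design correction serves as
an independent cross-check.  Standard errors come from the numerical
Hessian of the REML log-likelihood and confidence intervals use the
lognormal (multiplicative) large-sample form sigma2 * exp(+-1.96 SE /
sigma2), the convention standard mixed-model software prints.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import optimize, stats

__all__ = [
    "VarianceDecomposition",
    "fit_null_model",
    "method_of_moments",
    "variance_shares",
    "state_cv",
    "mpi_correlation",
]

_Z95 = 1.959963984540054


@dataclass
class VarianceDecomposition:
    sigma2_between: float
    se_between: float | None
    ci_between: tuple[float, float] | None
    sigma2_within: float
    se_within: float | None
    ci_within: tuple[float, float] | None
    share_between: float
    share_within: float


def _group_stats(values: Mapping[str, float], state_of: Mapping[str, str]):
    groups: dict[str, list[float]] = {}
    for did, y in values.items():
        groups.setdefault(state_of[did], []).append(float(y))
    ns = np.array([len(v) for v in groups.values()], dtype=float)
    means = np.array([np.mean(v) for v in groups.values()])
    ssw = float(sum(np.sum((np.asarray(v) - np.mean(v)) ** 2) for v in groups.values()))
    return ns, means, ssw


def _neg2_reml(s2b: float, s2w: float, ns, means, ssw) -> float:
    s2b = max(s2b, 1e-12)  # optimizer may probe the zero boundary
    s2w = max(s2w, 1e-12)
    lam = s2w + ns * s2b  # marginal variance factor per group mean
    w = ns / lam
    mu = float(np.sum(w * means) / np.sum(w))
    val = (
        np.sum((ns - 1.0)) * np.log(s2w)
        + np.sum(np.log(lam))
        + ssw / s2w
        + float(np.sum(ns * (means - mu) ** 2 / lam))
        + np.log(np.sum(w))
    )
    return float(val)


def _lognormal_ci(s2: float, se: float) -> tuple[float, float] | None:
    """sigma2 * exp(+-1.96 SE / sigma2); undefined near the zero boundary."""
    if s2 <= 0 or se / s2 > 50:
        return None
    return (
        s2 * float(np.exp(-_Z95 * se / s2)),
        s2 * float(np.exp(_Z95 * se / s2)),
    )


def method_of_moments(
    values: Mapping[str, float], state_of: Mapping[str, str]
) -> tuple[float, float]:
    """One-way ANOVA estimator with the unbalanced n0 correction.

    Returns (s2_between, s2_within); a negative between-component is
    truncated at 0.
    """
    ns, means, ssw = _group_stats(values, state_of)
    k = ns.size
    if k < 2:
        raise ValueError("between-state variance needs at least 2 states")
    N = float(ns.sum())
    grand = float(np.sum(ns * means) / N)
    msw = ssw / (N - k)
    msb = float(np.sum(ns * (means - grand) ** 2) / (k - 1))
    n0 = (N - float(np.sum(ns**2)) / N) / (k - 1)
    s2b = max(0.0, (msb - msw) / n0)
    return s2b, msw


def fit_null_model(
    values: Mapping[str, float], state_of: Mapping[str, str]
) -> VarianceDecomposition:
    """REML fit of the intercept-plus-state-effects null model.

    `values` maps district -> index value and `state_of` maps district
    -> state.  Estimated variances are never negative; SEs/CIs are
    omitted (None) for a component estimated on the zero boundary.
    """
    missing = [d for d in values if d not in state_of]
    if missing:
        raise ValueError(f"district {missing[0]!r} has no state assignment")
    ns, means, ssw = _group_stats(values, state_of)
    if ns.size < 2:
        raise ValueError("between-state variance is unidentified with one state")
    if not np.any(ns >= 2):
        raise ValueError("need at least one state with 2+ districts")

    s2b0, s2w0 = method_of_moments(values, state_of)
    total = s2b0 + s2w0
    x0 = np.log([max(s2b0, 1e-3 * max(total, 1.0)), max(s2w0, 1e-8)])

    def objective(theta):
        return _neg2_reml(np.exp(theta[0]), np.exp(theta[1]), ns, means, ssw)

    res = optimize.minimize(objective, x0, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
    s2b, s2w = float(np.exp(res.x[0])), float(np.exp(res.x[1]))
    if s2b < 1e-8 * max(s2w, 1.0):  # boundary solution
        s2b = 0.0

    se_b = se_w = None
    ci_b = ci_w = None
    # observed information on the variance scale (central differences)
    if s2b > 0:
        h_b, h_w = 1e-4 * max(s2b, 1.0), 1e-4 * max(s2w, 1.0)

        def f(b, w):
            return 0.5 * _neg2_reml(b, w, ns, means, ssw)

        H = np.empty((2, 2))
        H[0, 0] = (f(s2b + h_b, s2w) - 2 * f(s2b, s2w) + f(s2b - h_b, s2w)) / h_b**2
        H[1, 1] = (f(s2b, s2w + h_w) - 2 * f(s2b, s2w) + f(s2b, s2w - h_w)) / h_w**2
        H[0, 1] = H[1, 0] = (
            f(s2b + h_b, s2w + h_w)
            - f(s2b + h_b, s2w - h_w)
            - f(s2b - h_b, s2w + h_w)
            + f(s2b - h_b, s2w - h_w)
        ) / (4 * h_b * h_w)
        try:
            cov = np.linalg.inv(H)
            if cov[0, 0] > 0 and cov[1, 1] > 0:
                se_b = float(np.sqrt(cov[0, 0]))
                se_w = float(np.sqrt(cov[1, 1]))
                ci_b = _lognormal_ci(s2b, se_b)
                ci_w = _lognormal_ci(s2w, se_w)
        except np.linalg.LinAlgError:
            pass
    share_b, share_w = variance_shares(s2b, s2w)
    return VarianceDecomposition(
        sigma2_between=s2b,
        se_between=se_b,
        ci_between=ci_b,
        sigma2_within=s2w,
        se_within=se_w,
        ci_within=ci_w,
        share_between=share_b,
        share_within=share_w,
    )


def variance_shares(
    sigma2_between: float, sigma2_within: float
) -> tuple[float, float]:
    """Percentage of total variance attributable to each component."""
    if sigma2_between < 0 or sigma2_within < 0:
        raise ValueError("variance components must be >= 0")
    total = sigma2_between + sigma2_within
    if total == 0:
        raise ValueError("both variance components are zero")
    return 100.0 * sigma2_between / total, 100.0 * sigma2_within / total


def state_cv(
    values: Mapping[str, float], state_of: Mapping[str, str]
) -> dict[str, float]:
    """Per-state coefficient of variation, 100 * sample SD / mean.

    States with a single district cannot have a sample SD and are
    omitted from the table.
    """
    groups: dict[str, list[float]] = {}
    for did, y in values.items():
        groups.setdefault(state_of[did], []).append(float(y))
    out = {}
    for sid, vals in sorted(groups.items()):
        if len(vals) < 2:
            continue
        arr = np.asarray(vals)
        out[sid] = float(100.0 * np.std(arr, ddof=1) / np.mean(arr))
    return out


def mpi_correlation(
    uhcd: Mapping[str, float],
    mpi: Mapping[str, float],
    method: str = "pearson",
) -> tuple[float, float]:
    """Correlation between the index and the poverty measure.

    Districts missing either value are excluded.  Returns (r, two-sided
    p-value); Spearman is available as an option.
    """
    common = [
        d
        for d in uhcd
        if d in mpi
        and uhcd[d] is not None
        and mpi[d] is not None
        and not (np.isnan(uhcd[d]) or np.isnan(mpi[d]))
    ]
    if len(common) < 3:
        raise ValueError("correlation needs at least 3 districts with both values")
    x = np.array([uhcd[d] for d in common])
    y = np.array([mpi[d] for d in common])
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the variables")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)
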