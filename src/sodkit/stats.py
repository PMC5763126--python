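"""Inferential statistics: one-way ANOVA, Student-Newman-Keuls post hoc,
pairwise Wilcoxon rank-sum tests, and survival-proportion summaries.

The SNK procedure sorts the group means and tests ranges stepwise from
widest to narrowest against studentized-range critical values
q(alpha, p, df) * sqrt(MSE/n~); once a range is non-significant every
range nested inside it is declared non-significant without testing
(stepwise closure). The studentized-range quantile is computed here by
numerical inversion of the distribution's CDF — a double integral over
the range density and the chi distribution of the pooled-SD scale —
since no closed form exists.

For two groups SNK reduces exactly to the pooled-variance t-test via
the identity q(alpha, 2, nu) = sqrt(2) * t_{1-alpha/2, nu}.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special
from scipy import stats as sps
from scipy.optimize import brentq
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnovaResult",
    "SNKResult",
    "one_way_anova",
    "studentized_range_cdf",
    "studentized_range_quantile",
    "snk_posthoc",
    "pairwise_wilcoxon",
    "survival_proportions",
]

GroupData = Mapping[str, Sequence[float]]


def _as_groups(groups: GroupData) -> dict[str, np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    out = {}
    for label, values in groups.items():
        arr = np.asarray(list(values), dtype=float)
        if arr.size == 0:
            raise ValueError(f"group {label!r} is empty")
        out[str(label)] = arr
    return out


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaResult:
    f: float
    p: float
    df_between: int
    df_within: int
    ms_within: float
    group_means: dict[str, float]
    group_ns: dict[str, int]


def one_way_anova(groups: GroupData) -> AnovaResult:
    """Classical fixed-effects one-way ANOVA (between/within mean squares)."""
    data = _as_groups(groups)
    k = len(data)
    n_total = sum(a.size for a in data.values())
    if n_total <= k:
        raise ValueError("total sample size must exceed the number of groups")
    if all(a.size == 1 for a in data.values()):
        raise ValueError("cannot run ANOVA with one observation per group")
    grand = np.concatenate(list(data.values())).mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in data.values())
    ssw = sum(((a - a.mean()) ** 2).sum() for a in data.values())
    dfb, dfw = k - 1, n_total - k
    if ssw <= 0:
        raise ValueError("zero within-group variance: ANOVA is degenerate")
    msb, msw = ssb / dfb, ssw / dfw
    f = msb / msw
    p = float(sps.f.sf(f, dfb, dfw))
    return AnovaResult(
        f=float(f),
        p=p,
        df_between=dfb,
        df_within=dfw,
        ms_within=float(msw),
        group_means={g: float(a.mean()) for g, a in data.items()},
        group_ns={g: int(a.size) for g, a in data.items()},
    )


# ---------------------------------------------------------------------------
# Studentized range distribution
# ---------------------------------------------------------------------------

_Z_NODES, _Z_WEIGHTS = np.polynomial.legendre.leggauss(200)
_S_NODES, _S_WEIGHTS = np.polynomial.legendre.leggauss(120)

#: Degrees of freedom at or above which the scale is treated as known.
_DF_INFINITE = 1e6


def _range_cdf_infinite(x: np.ndarray, k: int) -> np.ndarray:
    """P(range of k iid standard normals < x), vectorised over x."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    lo, hi = -9.0, 9.0
    z = 0.5 * (hi - lo) * _Z_NODES + 0.5 * (hi + lo)
    w = 0.5 * (hi - lo) * _Z_WEIGHTS
    phi = np.exp(-0.5 * z * z) / math.sqrt(2 * math.pi)
    cdf_z = special.ndtr(z)
    # matrix (len(x), len(z))
    inner = cdf_z[None, :] - special.ndtr(z[None, :] - x[:, None])
    inner = np.clip(inner, 0.0, 1.0)
    vals = k * (w * phi * inner ** (k - 1)).sum(axis=1)
    return np.clip(np.where(x <= 0, 0.0, vals), 0.0, 1.0)


def studentized_range_cdf(q: float, k: int, df: float) -> float:
    """CDF of the studentized range Q = range / (pooled SD) at ``q``.

    Computed as the outer Gauss-Legendre integral over the chi-scaled
    pooled-SD density of the inner normal-range probability.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if q <= 0:
        return 0.0
    if not math.isfinite(df) or df >= _DF_INFINITE:
        return float(_range_cdf_infinite(np.array([q]), k)[0])
    if df < 1:
        raise ValueError("df must be >= 1")
    # s = sqrt(chi2_df / df): density concentrated near 1, sd ~ 1/sqrt(2 df)
    sigma = 1.0 / math.sqrt(2.0 * df)
    lo, hi = max(1e-12, 1.0 - 14.0 * sigma), 1.0 + 14.0 * sigma
    s = 0.5 * (hi - lo) * _S_NODES + 0.5 * (hi + lo)
    w = 0.5 * (hi - lo) * _S_WEIGHTS
    log_dens = (
        (df / 2.0) * math.log(df)
        - special.gammaln(df / 2.0)
        - (df / 2.0 - 1.0) * math.log(2.0)
        + (df - 1.0) * np.log(s)
        - df * s * s / 2.0
    )
    dens = np.exp(log_dens)
    inner = _range_cdf_infinite(q * s, k)
    return float(np.clip((w * dens * inner).sum(), 0.0, 1.0))


from functools import lru_cache


@lru_cache(maxsize=4096)
def studentized_range_quantile(alpha: float, k: int, df: float) -> float:
    """Upper-``alpha`` critical value q(alpha, k, df) of the studentized
    range, by bisection/Brent inversion of :func:`studentized_range_cdf`."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if k < 2:
        raise ValueError("k must be >= 2")
    target = 1.0 - alpha
    hi = 10.0
    while studentized_range_cdf(hi, k, df) < target:
        hi *= 2.0
        if hi > 1e4:
            raise RuntimeError(
                f"studentized-range inversion failed to bracket q at "
                f"alpha={alpha}, k={k}, df={df} (cdf({hi / 2}) < {target})"
            )
    return float(
        brentq(lambda q: studentized_range_cdf(q, k, df) - target, 1e-9, hi,
               xtol=1e-8, rtol=1e-10)
    )


# ---------------------------------------------------------------------------
# Student-Newman-Keuls
# ---------------------------------------------------------------------------

@dataclass
class SNKResult:
    """Outcome of the SNK stepwise multiple-comparison procedure."""

    order: list[str]                 # labels sorted by ascending mean
    means: dict[str, float]
    significant: pd.DataFrame       # symmetric bool matrix, original labels
    q_critical: dict[int, float]    # span p -> q(alpha, p, df)
    alpha: float
    df_error: int
    ms_error: float

    def pairs(self) -> list[tuple[str, str, bool]]:
        out = []
        for a, b in itertools.combinations(self.significant.index, 2):
            out.append((a, b, bool(self.significant.loc[a, b])))
        return out


def snk_posthoc(groups: GroupData, alpha: float = 0.05) -> SNKResult:
    """Student-Newman-Keuls post hoc comparison of all group pairs.

    Ranges are tested widest-first; a pair spanning p ordered means is
    significant iff |mean_hi - mean_lo| > q(alpha, p, df_err) *
    sqrt(MSE/n~) *and* no enclosing range was declared non-significant.
    For unbalanced groups n~ is the harmonic mean of the two group
    sizes, which at k=2 makes the decision identical to the
    pooled-variance t-test.
    """
    anova = one_way_anova(groups)
    data = _as_groups(groups)
    if anova.ms_within <= 0:
        raise ValueError("zero error mean square: SNK undefined")
    labels = sorted(data, key=lambda g: (float(np.mean(data[g])), g))
    means = {g: float(np.mean(data[g])) for g in labels}
    ns = {g: len(data[g]) for g in labels}
    k = len(labels)
    df = anova.df_within
    mse = anova.ms_within

    q_crit = {p: studentized_range_quantile(alpha, p, df) for p in range(2, k + 1)}

    sig = np.zeros((k, k), dtype=bool)
    closed = np.zeros((k, k), dtype=bool)  # declared ns by closure (final)

    def close_range(i: int, j: int) -> None:
        for a in range(i, j + 1):
            for b in range(a + 1, j + 1):
                closed[a, b] = closed[b, a] = True
                sig[a, b] = sig[b, a] = False

    def test_range(i: int, j: int) -> None:
        if j - i < 1 or closed[i, j]:
            return
        p = j - i + 1
        n_harm = 2.0 / (1.0 / ns[labels[i]] + 1.0 / ns[labels[j]])
        crit = q_crit[p] * math.sqrt(mse / n_harm)
        if means[labels[j]] - means[labels[i]] > crit:
            sig[i, j] = sig[j, i] = True
            test_range(i, j - 1)
            test_range(i + 1, j)
        else:
            close_range(i, j)

    test_range(0, k - 1)

    frame = pd.DataFrame(sig, index=labels, columns=labels)
    original = list(groups)
    frame = frame.loc[original, original]
    return SNKResult(
        order=labels,
        means=means,
        significant=frame,
        q_critical=q_crit,
        alpha=alpha,
        df_error=df,
        ms_error=mse,
    )


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum and survival proportions
# ---------------------------------------------------------------------------

def _rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p: exact enumeration when both n <= 8
    and there are no ties, tie-corrected normal approximation otherwise."""
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == pooled.size
    method = "exact" if (x.size <= 8 and y.size <= 8 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def pairwise_wilcoxon(groups: GroupData) -> dict[str, pd.DataFrame]:
    """Two-sided Wilcoxon rank-sum p for every pair of groups.

    Returns ``{"raw": ..., "holm": ...}`` symmetric p-value matrices
    (diagonal 1.0). Raw p-values are the headline output; the Holm
    matrix adjusts across all pairs.
    """
    data = _as_groups(groups)
    labels = list(data)
    raw = pd.DataFrame(1.0, index=labels, columns=labels)
    pairs = list(itertools.combinations(labels, 2))
    pvals = []
    for a, b in pairs:
        p = _rank_sum_p(data[a], data[b])
        raw.loc[a, b] = raw.loc[b, a] = p
        pvals.append(p)
    holm = pd.DataFrame(1.0, index=labels, columns=labels)
    if pvals:
        adj = multipletests(pvals, method="holm")[1]
        for (a, b), p in zip(pairs, adj):
            holm.loc[a, b] = holm.loc[b, a] = float(p)
    return {"raw": raw, "holm": holm}


def survival_proportions(
    counts: Mapping[str, Sequence[tuple[int, int]]]
) -> pd.DataFrame:
    """Mean +/- SE of per-experiment survival proportions per treatment.

    ``counts`` maps treatment label -> [(alive, total), ...] (one pair
    per independent experiment). SE = sd/sqrt(n) across experiments; a
    single experiment yields SE = 0 with ``se_undefined`` flagged.
    """
    rows = []
    for label, pairs in counts.items():
        props = []
        for alive, total in pairs:
            if total <= 0:
                raise ValueError(f"{label}: total must be > 0")
            if alive > total or alive < 0:
                raise ValueError(f"{label}: alive {alive} outside [0, {total}]")
            props.append(alive / total)
        arr = np.asarray(props, dtype=float)
        single = arr.size < 2
        rows.append(
            {
                "treatment": label,
                "n_experiments": int(arr.size),
                "proportion_mean": float(arr.mean()),
                "proportion_se": 0.0 if single else float(arr.std(ddof=1) / np.sqrt(arr.size)),
                "se_undefined": bool(single),
            }
        )
    return pd.DataFrame(rows).set_index("treatment")
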