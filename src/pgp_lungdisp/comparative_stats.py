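"""Group comparisons, correlations and rank-order impact analyses.

Thin, typed wrappers around :mod:`scipy.stats` plus the two pieces scipy does
not provide in the form needed here: an exact-permutation two-sided p-value
for Spearman's coefficient at small n, and rank-impact tables pairing a
physico-chemical metric with the knockout effect size per compound.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "CorrelationResult",
    "summarize",
    "unpaired_t",
    "pearson",
    "spearman",
    "rank_impact_table",
    "group_fold_change",
    "round_printed",
]


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean: float
    sd: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class CorrelationResult:
    coefficient: float
    p_value: float
    n: int
    method: str


def summarize(values: Sequence[float], label: str, ci: float = 0.95) -> GroupSummary:
    """Mean, SD and a t-distribution confidence interval (n-1 df)."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError(f"group {label!r}: need n >= 2 for a summary (got {n})")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    half = stats.t.ppf(0.5 + ci / 2.0, n - 1) * sd / math.sqrt(n)
    return GroupSummary(
        label=label, n=n, mean=mean, sd=sd, ci_low=mean - half, ci_high=mean + half
    )


def unpaired_t(
    a: Sequence[float], b: Sequence[float], equal_var: bool = True
) -> tuple[float, float]:
    """Two-sided t-test for independent samples (Welch via equal_var=False)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        raise ValueError("zero pooled variance with unequal means is degenerate")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_pair(x, y)
    r = stats.pearsonr(x, y)
    return CorrelationResult(
        coefficient=float(r.statistic), p_value=float(r.pvalue), n=len(x),
        method="pearson",
    )


def spearman(
    x: Sequence[float], y: Sequence[float], exact: bool = False
) -> CorrelationResult:
    """Spearman rank correlation with average ranks for ties.

    The default p-value uses the t approximation.  With ``exact=True``
    (n <= 10) the two-sided p is computed by full enumeration of the n!
    rank permutations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_pair(x, y)
    if np.var(stats.rankdata(x)) == 0 or np.var(stats.rankdata(y)) == 0:
        raise ValueError("zero rank variance")
    rho = float(stats.spearmanr(x, y).statistic)
    if exact:
        p = _exact_spearman_p(x, y, rho)
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return CorrelationResult(coefficient=rho, p_value=p, n=len(x), method="spearman")


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    n = len(x)
    if n > 10:
        raise ValueError("exact permutation p limited to n <= 10")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx_c = rx - rx.mean()
    denom_x = math.sqrt(float(rx_c @ rx_c))
    ry_c = ry - ry.mean()
    denom_y = math.sqrt(float(ry_c @ ry_c))
    count = total = 0
    threshold = abs(rho_obs) - 1e-12
    for perm in itertools.permutations(range(n)):
        rho = float(rx_c @ (ry_c[list(perm)])) / (denom_x * denom_y)
        if abs(rho) >= threshold:
            count += 1
        total += 1
    return count / total


def _check_pair(x: np.ndarray, y: np.ndarray) -> None:
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and aligned")
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance")


def rank_impact_table(
    metric: Mapping[str, float],
    impact: Mapping[str, float],
    significant: Mapping[str, bool] | None = None,
) -> pd.DataFrame:
    """Rank-order table pairing a per-compound metric with the knockout impact.

    Both variables are converted to ranks (1 = smallest, average ranks for
    ties).  ``significant`` carries the per-compound flag used to annotate
    compounds whose knockout effect did not reach significance.  Output rows
    are sorted by compound name, so input ordering is irrelevant.
    """
    if set(metric) != set(impact):
        raise ValueError("metric and impact must cover the same compounds")
    if significant is not None and set(significant) != set(metric):
        raise ValueError("significance flags must cover the same compounds")
    names = sorted(metric)
    m = np.array([metric[n] for n in names], dtype=float)
    i = np.array([impact[n] for n in names], dtype=float)
    df = pd.DataFrame(
        {
            "compound": names,
            "metric_rank": stats.rankdata(m),
            "impact_rank": stats.rankdata(i),
        }
    )
    if significant is not None:
        df["significant"] = [bool(significant[n]) for n in names]
    return df


def group_fold_change(
    ratios: Mapping[str, float],
    groups: Mapping[str, str],
    exclude: Iterable[str] = (),
    ci: float = 0.95,
) -> dict[str, GroupSummary]:
    """Per-group mean fold-change (KO:WT) with 95% CI, with optional exclusions."""
    if set(ratios) != set(groups):
        raise ValueError("ratios and groups must cover the same compounds")
    excluded = set(exclude)
    unknown = excluded - set(ratios)
    if unknown:
        raise KeyError(f"exclusion list names unknown compounds: {sorted(unknown)}")
    out: dict[str, GroupSummary] = {}
    for label in sorted(set(groups.values())):
        vals = [
            ratios[n] for n in ratios if groups[n] == label and n not in excluded
        ]
        if any(v <= 0 for v in vals):
            raise ValueError(f"group {label!r}: fold-changes must be positive")
        if not vals:
            raise ValueError(f"group {label!r} is empty after exclusions")
        out[label] = summarize(vals, label, ci=ci)
    return out


def round_printed(x: float, decimals: int) -> float:
    """Round exactly as tabulated values are printed (half away from zero)."""
    q = 10.0**decimals
    return math.copysign(math.floor(abs(x) * q + 0.5) / q, x)
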