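"""Rank-based statistics for behavioral comparisons.

Pairwise comparisons use the two-sided Wilcoxon rank-sum (Mann-Whitney)
test — exact by enumeration for small tie-free samples, otherwise the
tie- and continuity-corrected normal approximation — with median
differences and percentile-bootstrap 95% confidence intervals as effect
sizes.  Multi-group comparisons use the Kruskal-Wallis test followed by
Dunn's pairwise z-tests on pooled ranks with Benjamini-Hochberg
adjustment across the post-hoc family.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, DataError, InsufficientDataError

logger = logging.getLogger("wormassay")

#: Exact Wilcoxon enumeration is used up to this combined sample size
#: (tie-free samples only).
EXACT_MAX_N = 12


@dataclass
class StatResult:
    """One comparison's test outcome.

    ``effect_size`` is the median difference (group1 - group2) in the
    units of the measure, with a percentile-bootstrap 95% CI.
    ``adjusted_p`` is present only within a multiplicity-adjusted
    family.
    """

    comparison: str
    method: str
    statistic: float
    p_value: float
    n1: int
    n2: int
    effect_size: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    adjusted_p: float | None = None
    seed: int | None = None
    significant: bool | None = None

    def __post_init__(self) -> None:
        if self.ci_low is not None and self.ci_high is not None:
            if self.ci_low > self.ci_high:
                raise DataError("bootstrap CI bounds out of order")
        if self.adjusted_p is not None and self.adjusted_p < self.p_value - 1e-12:
            raise DataError("adjusted p-value below raw p-value")


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return len(np.unique(pooled)) < len(pooled)


def wilcoxon_rank_sum(x, y, mode: str = "auto",
                      comparison: str = "x vs y") -> StatResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    ``mode='auto'`` uses the exact permutation distribution when
    n1 + n2 <= 12 and there are no ties, else the tie-corrected normal
    approximation with continuity correction.  Samples that are
    identical constants across both groups yield p = 1 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise InsufficientDataError("both samples must be non-empty")
    if mode not in ("exact", "approx", "auto"):
        raise ConfigError(f"unknown mode {mode!r}")
    if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
        warnings.warn("degenerate data: all values identical; p = 1")
        return StatResult(comparison=comparison, method="wilcoxon-degenerate",
                          statistic=len(x) * len(y) / 2.0, p_value=1.0,
                          n1=len(x), n2=len(y))
    ties = _has_ties(x, y)
    if mode == "exact" or (mode == "auto" and len(x) + len(y) <= EXACT_MAX_N
                           and not ties):
        if ties:
            warnings.warn("ties present: falling back to the corrected "
                          "normal approximation")
        else:
            res = sps.mannwhitneyu(x, y, alternative="two-sided",
                                   method="exact")
            return StatResult(comparison=comparison, method="wilcoxon-exact",
                              statistic=float(res.statistic),
                              p_value=float(res.pvalue),
                              n1=len(x), n2=len(y))
    res = sps.mannwhitneyu(x, y, alternative="two-sided",
                           method="asymptotic", use_continuity=True)
    return StatResult(comparison=comparison, method="wilcoxon-approx",
                      statistic=float(res.statistic),
                      p_value=float(res.pvalue), n1=len(x), n2=len(y))


def bootstrap_median_diff(x, y, n_boot: int = 10000,
                          seed: int = 0) -> tuple[float, float, float]:
    """Median difference median(x) - median(y) with a percentile 95%
    bootstrap confidence interval (each group resampled with
    replacement, one seeded stream)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise InsufficientDataError("need n >= 2 in both groups for the "
                                    "bootstrap")
    rng = np.random.default_rng(seed)
    effect = float(np.median(x) - np.median(y))
    bx = np.median(x[rng.integers(0, len(x), size=(n_boot, len(x)))], axis=1)
    by = np.median(y[rng.integers(0, len(y), size=(n_boot, len(y)))], axis=1)
    lo, hi = np.percentile(bx - by, [2.5, 97.5])
    return effect, float(lo), float(hi)


def kruskal_wallis(groups, comparison: str = "omnibus") -> StatResult:
    """Kruskal-Wallis H test with tie correction (chi-squared p, k-1 df)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    groups = [g for g in groups if len(g) > 0]
    if len(groups) < 2:
        raise InsufficientDataError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        warnings.warn("degenerate data: all values identical; H = 0, p = 1")
        return StatResult(comparison=comparison, method="kruskal-wallis",
                          statistic=0.0, p_value=1.0,
                          n1=len(groups[0]), n2=len(pooled) - len(groups[0]))
    h, p = sps.kruskal(*groups)
    return StatResult(comparison=comparison, method="kruskal-wallis",
                      statistic=float(h), p_value=float(p),
                      n1=len(groups[0]), n2=len(pooled) - len(groups[0]))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def dunn_posthoc(groups, labels=None, adjust: str = "bh") -> list[StatResult]:
    """Dunn's post-hoc pairwise z-tests on pooled ranks, with tie
    correction, two-sided p, and BH adjustment across all pairs."""
    if adjust != "bh":
        raise ConfigError(f"unsupported adjustment {adjust!r}")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in groups):
        raise InsufficientDataError("empty group in Dunn post-hoc")
    if len(groups) < 2:
        raise InsufficientDataError("need >= 2 groups")
    if labels is None:
        labels = [f"g{i}" for i in range(len(groups))]
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    bounds = np.cumsum([0] + [len(g) for g in groups])
    mean_ranks = [ranks[bounds[i]:bounds[i + 1]].mean()
                  for i in range(len(groups))]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts))
    base_var = n_total * (n_total + 1) / 12.0
    if n_total > 1:
        base_var -= tie_term / (12.0 * (n_total - 1))

    results = []
    degenerate = np.all(pooled == pooled[0])
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            if degenerate or base_var <= 0:
                z, p = 0.0, 1.0
            else:
                se = np.sqrt(base_var * (1.0 / len(groups[i])
                                         + 1.0 / len(groups[j])))
                z = (mean_ranks[i] - mean_ranks[j]) / se
                p = 2.0 * sps.norm.sf(abs(z))
            results.append(StatResult(
                comparison=f"{labels[i]} vs {labels[j]}", method="dunn",
                statistic=float(z), p_value=float(min(p, 1.0)),
                n1=len(groups[i]), n2=len(groups[j]),
            ))
    adj = bh_adjust([r.p_value for r in results])
    for r, a in zip(results, adj):
        r.adjusted_p = float(a)
    return results


def compare_conditions(table: pd.DataFrame, group_col: str, value_col: str,
                       alpha: float = 0.05, n_boot: int = 10000,
                       seed: int = 0, mode: str = "auto") -> list[StatResult]:
    """Dispatch the appropriate rank-based comparison for a tidy table.

    Two groups -> Wilcoxon rank-sum plus bootstrap median-difference CI;
    three or more -> Kruskal-Wallis omnibus plus Dunn/BH pairwise rows
    (each pair also carries a bootstrap effect size).  Rows with NaN
    measures are dropped.  Significance is flagged at ``alpha`` on the
    adjusted p where present, the raw p otherwise.
    """
    for col in (group_col, value_col):
        if col not in table.columns:
            raise ConfigError(f"column {col!r} not in table")
    df = table[[group_col, value_col]].dropna()
    labels = list(pd.unique(df[group_col]))
    groups = [df.loc[df[group_col] == lab, value_col].to_numpy(dtype=float)
              for lab in labels]
    if len(labels) < 2:
        logger.warning("compare_conditions: fewer than 2 groups; no tests run")
        return []
    results: list[StatResult] = []
    if len(labels) == 2:
        r = wilcoxon_rank_sum(groups[0], groups[1], mode=mode,
                              comparison=f"{labels[0]} vs {labels[1]}")
        if len(groups[0]) >= 2 and len(groups[1]) >= 2:
            eff, lo, hi = bootstrap_median_diff(groups[0], groups[1],
                                                n_boot=n_boot, seed=seed)
            r.effect_size, r.ci_low, r.ci_high, r.seed = eff, lo, hi, seed
        results.append(r)
    else:
        results.append(kruskal_wallis(groups, comparison="omnibus"))
        pairs = dunn_posthoc(groups, labels=labels)
        k = 0
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                r = pairs[k]
                k += 1
                if len(groups[i]) >= 2 and len(groups[j]) >= 2:
                    eff, lo, hi = bootstrap_median_diff(
                        groups[i], groups[j], n_boot=n_boot, seed=seed)
                    r.effect_size, r.ci_low, r.ci_high, r.seed = eff, lo, hi, seed
        results.extend(pairs)
    for r in results:
        p = r.adjusted_p if r.adjusted_p is not None else r.p_value
        r.significant = bool(p < alpha)
    return results


def results_to_frame(results: list[StatResult]) -> pd.DataFrame:
    """Tidy StatResult table with stable column order."""
    cols = ["comparison", "method", "statistic", "p_value", "adjusted_p",
            "effect_size", "ci_low", "ci_high", "n1", "n2", "seed",
            "significant"]
    return pd.DataFrame([r.__dict__ for r in results], columns=cols)
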