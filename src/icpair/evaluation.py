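"""Group-comparison, association and response-prediction statistics.

These are the generic statistics applied to a fitted risk index:
rank-based two-sample and k-sample tests, Fisher's exact test,
score-feature correlation sweeps with optional Benjamini-Hochberg
adjustment, the cytolytic-activity (CYT) score, and contingency
analysis of risk groups against treatment-response categories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "wilcoxon_rank_sum",
    "kruskal_wallis",
    "fisher_exact",
    "correlate",
    "cyt_score",
    "group_response_table",
    "GroupResponseResult",
]

logger = logging.getLogger(__name__)

#: pooled-size bound below which the exact permutation distribution is used
EXACT_LIMIT = 10


def wilcoxon_rank_sum(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Wilcoxon rank-sum test; returns (rank-sum W of x, p-value).

    Small samples (n1 + n2 <= 10) use the exact permutation distribution
    of the rank sum conditional on the observed (tie-averaged) ranks;
    larger samples use the tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"bad alternative {alternative!r}")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1, n = x.size, pooled.size
    w = float(ranks[:n1].sum())

    if n <= EXACT_LIMIT:
        sums = np.array([sum(ranks[list(idx)])
                         for idx in combinations(range(n), n1)])
        total = comb(n, n1)
        p_le = np.sum(sums <= w + 1e-9) / total
        p_ge = np.sum(sums >= w - 1e-9) / total
        if alternative == "less":
            p = p_le
        elif alternative == "greater":
            p = p_ge
        else:
            p = min(1.0, 2.0 * min(p_le, p_ge))
        return w, float(p)

    n2 = n - n1
    mean = n1 * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var == 0:
        return w, 1.0
    z = (w - mean) / np.sqrt(var)
    if alternative == "less":
        p = stats.norm.cdf(z)
    elif alternative == "greater":
        p = stats.norm.sf(z)
    else:
        p = 2.0 * stats.norm.sf(abs(z))
    return w, float(min(p, 1.0))


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square p (df = k - 1)."""
    if len(groups) == 1 and isinstance(groups[0], (list, tuple)) and \
            not np.isscalar(groups[0][0]):
        groups = tuple(groups[0])
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def fisher_exact(table) -> tuple[float, float]:
    """Fisher's exact test on a 2x2 table.

    Returns the sample odds ratio and the conditional two-sided p
    (sum of hypergeometric probabilities <= that of the observed table).
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0) or not np.all(t == np.floor(t)):
        raise ValueError("counts must be nonnegative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero margin in contingency table")
    res = stats.fisher_exact(t.astype(int), alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def correlate(scores: pd.Series, features: pd.DataFrame,
              method: str = "pearson", adjust: str = "none") -> pd.DataFrame:
    """Per-feature correlation of a score with a feature table.

    Constant features (correlation undefined) are excluded and listed in
    the result's ``.attrs['excluded']``.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"method must be pearson or spearman, got {method!r}")
    if adjust not in ("none", "BH"):
        raise ValueError(f"adjust must be 'none' or 'BH', got {adjust!r}")
    common = features.index.intersection(scores.index)
    if len(common) < 3:
        raise ValueError("need at least 3 paired observations")
    s = scores.loc[common].to_numpy(dtype=float)
    rows, excluded = [], []
    for name in features.columns:
        f = pd.to_numeric(features.loc[common, name], errors="coerce")
        mask = f.notna().to_numpy()
        if mask.sum() < 3 or f[mask].std() == 0 or np.std(s[mask]) == 0:
            excluded.append(name)
            continue
        fn = stats.pearsonr if method == "pearson" else stats.spearmanr
        r, p = fn(s[mask], f[mask].to_numpy())
        rows.append((name, float(r), float(p), int(mask.sum())))
    if excluded:
        logger.info("correlate: excluded %d constant/short features", len(excluded))
    out = pd.DataFrame(rows, columns=["feature", "r", "p_value", "n"]
                       ).set_index("feature")
    if adjust == "BH" and len(out):
        out["p_adjusted"] = stats.false_discovery_control(out["p_value"])
    else:
        out["p_adjusted"] = out["p_value"]
    out.attrs["method"] = method
    out.attrs["adjust"] = adjust
    out.attrs["excluded"] = excluded
    return out


def cyt_score(expression: pd.DataFrame,
              genes: tuple[str, str] = ("PRF1", "GZMA")) -> pd.Series:
    """Cytolytic activity: per-sample mean expression of PRF1 and GZMA."""
    missing = [g for g in genes if g not in expression.index]
    if missing:
        raise KeyError(f"CYT genes missing from expression matrix: {missing}")
    return expression.loc[list(genes)].mean(axis=0).rename("CYT")


@dataclass
class GroupResponseResult:
    table: pd.DataFrame        # groups x response categories, counts
    rates: pd.DataFrame        # per-group category fractions
    method: str                # 'fisher' or 'chi-square'
    statistic: float           # odds ratio (fisher) or chi2
    p_value: float


def group_response_table(groups, responses) -> GroupResponseResult:
    """Cross-tabulate risk groups against response categories and test.

    Fisher's exact test for 2x2 tables, chi-square otherwise.
    """
    groups = pd.Series(groups).reset_index(drop=True)
    responses = pd.Series(responses).reset_index(drop=True)
    if len(groups) != len(responses):
        raise ValueError("groups and responses differ in length")
    ok = responses.notna()
    table = pd.crosstab(groups[ok], responses[ok])
    if table.size == 0 or table.shape[1] == 0:
        raise ValueError("no response categories observed")
    rates = table.div(table.sum(axis=1), axis=0)
    if table.shape == (2, 2):
        stat, p = fisher_exact(table.to_numpy())
        method = "fisher"
    else:
        stat, p, _, _ = stats.chi2_contingency(table.to_numpy())
        stat, p, method = float(stat), float(p), "chi-square"
    return GroupResponseResult(table, rates, method, float(stat), float(p))
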