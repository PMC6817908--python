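"""Cross-layer statistics: methylation-expression coupling, promoter
scores, co-methylation, and tumor-vs-normal discrimination (AUROC)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .methyl import BetaMatrix, CpGMap


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    method: str


def _paired(a: pd.Series, b: pd.Series) -> tuple[np.ndarray, np.ndarray, int]:
    a = pd.Series(a).astype(float)
    b = pd.Series(b).astype(float)
    joined = pd.concat([a, b], axis=1, join="inner").dropna()
    return joined.iloc[:, 0].to_numpy(), joined.iloc[:, 1].to_numpy(), len(joined)


def methylation_expression_correlation(
    beta_row_or_score: pd.Series, expression_row: pd.Series, method: str = "pearson"
) -> CorrelationResult:
    """Pearson or Spearman correlation of paired methylation and expression.

    Samples are paired by id; incomplete pairs are dropped and the
    remaining n reported.  Fewer than 3 complete pairs is an error.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be pearson or spearman")
    x, y, n = _paired(beta_row_or_score, expression_row)
    if n < 3:
        raise ValueError(f"need >=3 complete pairs, got {n}")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    else:
        res = stats.spearmanr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=n, method=method)


def promoter_score(beta: BetaMatrix, interval, cpg_map: CpGMap | None = None) -> pd.Series:
    """Per-sample mean beta over an interval of probes (missing-aware).

    ``interval`` is either an iterable of probe ids, or a
    ``(start_probe, end_probe)`` pair resolved against ``cpg_map``.
    """
    if cpg_map is not None and len(interval) == 2 and all(isinstance(x, str) for x in interval):
        probes = cpg_map.interval_probes(*interval)
    else:
        probes = list(interval)
    if not probes:
        raise ValueError("empty probe interval")
    missing = [p for p in probes if p not in beta.values.index]
    if missing:
        raise KeyError(f"interval probes outside the beta matrix: {missing[:5]}")
    score = beta.values.loc[probes].mean(axis=0, skipna=True)
    score.name = "promoter_score"
    return score


def cross_promoter_correlation(
    score_a: pd.Series, score_b: pd.Series, method: str = "pearson"
) -> CorrelationResult:
    """Correlation of two promoters' per-sample methylation scores."""
    return methylation_expression_correlation(score_a, score_b, method=method)


@dataclass
class AurocResult:
    auroc: float
    p: float
    n_pos: int
    n_neg: int


def tumor_vs_normal_auroc(values, labels) -> AurocResult:
    """AUROC of a score for tumor (positive) vs normal, by pair counting.

    Counts, over all tumor-normal pairs, the fraction in which the tumor
    sample scores higher, with half credit for ties — the probability
    interpretation of the ROC area.  The p-value comes from the equivalent
    two-sided Mann-Whitney U test.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    pos = values[labels == "tumor"]
    neg = values[labels == "normal"]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    neg_sorted = np.sort(neg)
    below = np.searchsorted(neg_sorted, pos, side="left")
    below_or_eq = np.searchsorted(neg_sorted, pos, side="right")
    wins = below.sum() + 0.5 * (below_or_eq - below).sum()
    auroc = float(wins / (len(pos) * len(neg)))
    p = float(stats.mannwhitneyu(pos, neg, alternative="two-sided").pvalue)
    return AurocResult(auroc=auroc, p=p, n_pos=len(pos), n_neg=len(neg))
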