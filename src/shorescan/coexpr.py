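"""Consensus seed-gene co-expression screening across cohorts.

The screening cascade mirrors a multi-database meta-analysis: for each
cohort, every gene is correlated with a chosen seed gene; a per-histology
consensus keeps genes significant (BH q <= alpha) with a consistent sign in
every cohort of that histology; the per-histology sets are intersected
across histologies; and the surviving candidates are filtered for
differential expression between tumor and normal samples.  Every stage's
output is a subset of its input (monotone filtering).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._util import bh_adjust


@dataclass
class Cohort:
    """One expression cohort: log2 genes x samples plus sample groups."""

    name: str
    histology: str
    expression: pd.DataFrame
    groups: pd.Series  # sample -> 'tumor' | 'normal'

    def samples_in(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def tumor_expression(self) -> pd.DataFrame:
        cols = self.samples_in("tumor")
        return self.expression[cols] if cols else self.expression


@dataclass
class CohortCollection:
    cohorts: list[Cohort]

    def __post_init__(self):
        if not self.cohorts:
            raise ValueError("empty cohort collection")
        names = [c.name for c in self.cohorts]
        if len(set(names)) != len(names):
            raise ValueError("cohort names must be unique")

    @property
    def histologies(self) -> list[str]:
        seen = {}
        for c in self.cohorts:
            seen.setdefault(c.histology, None)
        return list(seen)

    def by_histology(self, histology: str) -> list[Cohort]:
        return [c for c in self.cohorts if c.histology == histology]

    def harmonize(self) -> tuple["CohortCollection", int]:
        """Restrict every cohort to the shared gene namespace.

        Returns the harmonized collection and the number of gene ids
        dropped for not matching across all cohorts (exact string match).
        """
        shared = set(self.cohorts[0].expression.index)
        total = set()
        for c in self.cohorts:
            total |= set(c.expression.index)
            shared &= set(c.expression.index)
        keep = [g for g in self.cohorts[0].expression.index if g in shared]
        out = [
            Cohort(c.name, c.histology, c.expression.loc[keep], c.groups) for c in self.cohorts
        ]
        return CohortCollection(out), len(total - shared)


def collapse_probes(expression: pd.DataFrame, probe_to_gene: pd.Series) -> tuple[pd.DataFrame, int]:
    """Collapse array probes to genes, keeping the maximum-variance probe.

    Returns the gene-level matrix and the number of probes discarded.
    """
    probes = expression.index.intersection(probe_to_gene.index)
    expr = expression.loc[probes]
    variances = expr.var(axis=1)
    best = variances.groupby(probe_to_gene.loc[probes]).idxmax()
    collapsed = expr.loc[best.to_numpy()]
    collapsed.index = best.index
    return collapsed, len(expression) - len(collapsed)


def _pearson_against_seed(mat: np.ndarray, seed: np.ndarray) -> np.ndarray:
    seed_c = seed - seed.mean()
    mat_c = mat - mat.mean(axis=1, keepdims=True)
    denom = np.sqrt((mat_c**2).sum(axis=1)) * np.sqrt((seed_c**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (mat_c @ seed_c) / denom
    return r


def correlate_seed_gene(
    matrix: pd.DataFrame, seed_gene_id: str, method: str = "pearson"
) -> pd.DataFrame:
    """Correlate every non-seed gene with the seed gene.

    Returns a table with columns r, p (two-sided, from the t-transform of
    r), q (BH over all testable genes) and n.  Zero-variance genes are
    flagged (``tested == False``) and excluded from the adjustment.
    """
    if seed_gene_id not in matrix.index:
        raise KeyError(f"seed gene {seed_gene_id!r} absent from matrix")
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples to correlate")
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be pearson or spearman")
    others = matrix.drop(index=seed_gene_id)
    X = others.to_numpy(dtype=float)
    y = matrix.loc[seed_gene_id].to_numpy(dtype=float)
    if method == "spearman":
        X = np.apply_along_axis(stats.rankdata, 1, X)
        y = stats.rankdata(y)
    n = X.shape[1]
    r = _pearson_against_seed(X, y)
    ok = np.isfinite(r)
    p = np.full(len(r), np.nan)
    # t-transform: t = r * sqrt((n-2)/(1-r^2)) on n-2 df
    rr = np.clip(r[ok], -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = rr * np.sqrt((n - 2) / np.maximum(1e-300, 1 - rr**2))
    p[ok] = 2 * stats.t.sf(np.abs(t), df=n - 2)
    table = pd.DataFrame(
        {"r": r, "p": p, "q": bh_adjust(p), "n": n, "tested": ok},
        index=others.index,
    )
    return table


def consensus_genes(
    tables: dict[str, pd.DataFrame],
    alpha: float = 0.05,
    require_sign: str = "positive",
) -> tuple[list[str], pd.DataFrame]:
    """Genes significant in EVERY cohort table, with consistent sign.

    A gene is included iff q <= alpha in every table and, when a sign is
    required, r has that sign in every table.  ``require_sign='any'``
    demands only that the sign agree across tables.  Returns the gene list
    (sorted) and a per-gene evidence table (r and q per cohort).
    """
    if not tables:
        raise ValueError("empty table list")
    if require_sign not in ("positive", "negative", "any"):
        raise ValueError("require_sign must be positive|negative|any")
    names = list(tables)
    genes = set(tables[names[0]].index)
    for t in tables.values():
        genes &= set(t.index)
    idx = pd.Index(sorted(genes), name="gene")
    R = pd.DataFrame({c: tables[c]["r"].reindex(idx) for c in names})
    Q = pd.DataFrame({c: tables[c]["q"].reindex(idx) for c in names})
    tested = pd.DataFrame({c: tables[c]["tested"].reindex(idx) for c in names}).all(axis=1)
    sig = tested & (Q <= alpha).all(axis=1)
    if require_sign == "positive":
        sign_ok = (R > 0).all(axis=1)
    elif require_sign == "negative":
        sign_ok = (R < 0).all(axis=1)
    else:
        sign_ok = (R > 0).all(axis=1) | (R < 0).all(axis=1)
    evidence = pd.concat(
        {f"r_{c}": R[c] for c in names} | {f"q_{c}": Q[c] for c in names}, axis=1
    )
    evidence["included"] = sig & sign_ok
    included = sorted(evidence.index[evidence["included"]])
    return included, evidence


def intersect_histologies(set_a, set_b) -> list[str]:
    """Exact intersection, order-stable by gene id."""
    return sorted(set(set_a) & set(set_b))


def differential_expression_filter(
    matrix: pd.DataFrame,
    group_labels: pd.Series,
    genes,
    alpha: float = 0.05,
) -> tuple[list[str], pd.DataFrame]:
    """Mann-Whitney tumor-vs-normal filter over a candidate gene set.

    Two-sided test per gene; BH adjustment restricted to the candidate set
    (mirroring the cascade order); genes with q <= alpha are retained and
    their effect direction (sign of the tumor-normal median difference)
    reported.
    """
    genes = list(genes)
    missing = [g for g in genes if g not in matrix.index]
    if missing:
        raise KeyError(f"genes absent from matrix: {missing[:5]}")
    tum_cols = list(group_labels.index[group_labels == "tumor"])
    nor_cols = list(group_labels.index[group_labels == "normal"])
    if len(tum_cols) < 2 or len(nor_cols) < 2:
        raise ValueError("each group needs at least 2 samples")
    if not genes:
        return [], pd.DataFrame(columns=["p", "q", "direction"])
    p = np.empty(len(genes))
    direction = []
    for i, g in enumerate(genes):
        t = matrix.loc[g, tum_cols].to_numpy(dtype=float)
        nvals = matrix.loc[g, nor_cols].to_numpy(dtype=float)
        combined = np.concatenate([t, nvals])
        if np.all(combined == combined[0]):
            p[i] = 1.0
        else:
            p[i] = stats.mannwhitneyu(t, nvals, alternative="two-sided").pvalue
        diff = np.median(t) - np.median(nvals)
        direction.append("up" if diff > 0 else ("down" if diff < 0 else "flat"))
    table = pd.DataFrame(
        {"p": p, "q": bh_adjust(p), "direction": direction}, index=pd.Index(genes, name="gene")
    )
    kept = sorted(table.index[table["q"] <= alpha])
    return kept, table


@dataclass
class SignatureResult:
    """Staged output of the screening cascade with per-stage provenance."""

    per_histology: dict[str, list[str]]
    common: list[str]
    de_filtered: list[str]
    stage_counts: dict[str, int]
    thresholds: dict
    evidence: dict[str, pd.DataFrame] = field(default_factory=dict, repr=False)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for hist, genes in self.per_histology.items():
            rows += [{"stage": f"consensus_{hist}", "gene": g} for g in genes]
        rows += [{"stage": "common", "gene": g} for g in self.common]
        rows += [{"stage": "de_filtered", "gene": g} for g in self.de_filtered]
        return pd.DataFrame(rows, columns=["stage", "gene"])


def run_signature_pipeline(
    collection: CohortCollection,
    seed_gene: str,
    method: str = "pearson",
    consensus_alpha: float = 0.05,
    require_sign: str = "positive",
    de_alpha: float = 0.05,
    de_cohort: str | None = None,
    correlation_group: str = "tumor",
) -> SignatureResult:
    """Run the full cascade: correlate -> consensus -> intersect -> DE filter.

    The correlation screen runs on the ``correlation_group`` samples of
    each cohort (tumor by default, matching tumor-series databases); the
    differential-expression filter uses ``de_cohort`` (default: the first
    cohort that carries both groups).
    """
    collection, dropped = collection.harmonize()
    per_hist: dict[str, list[str]] = {}
    evidence: dict[str, pd.DataFrame] = {}
    for hist in collection.histologies:
        tables = {}
        for cohort in collection.by_histology(hist):
            expr = cohort.tumor_expression() if correlation_group == "tumor" else cohort.expression
            try:
                tables[cohort.name] = correlate_seed_gene(expr, seed_gene, method=method)
            except (KeyError, ValueError) as exc:
                raise RuntimeError(f"stage correlate ({cohort.name}): {exc}") from exc
        try:
            genes, ev = consensus_genes(tables, alpha=consensus_alpha, require_sign=require_sign)
        except ValueError as exc:
            raise RuntimeError(f"stage consensus ({hist}): {exc}") from exc
        per_hist[hist] = genes
        evidence[hist] = ev
    hists = list(per_hist)
    common = per_hist[hists[0]]
    for h in hists[1:]:
        common = intersect_histologies(common, per_hist[h])
    ref = None
    for cohort in collection.cohorts:
        if de_cohort is not None and cohort.name == de_cohort:
            ref = cohort
            break
        if de_cohort is None and cohort.samples_in("tumor") and cohort.samples_in("normal"):
            ref = cohort
            break
    if ref is None:
        raise RuntimeError("stage de_filter: no cohort carries both tumor and normal samples")
    try:
        de_genes, de_table = differential_expression_filter(
            ref.expression, ref.groups, common, alpha=de_alpha
        )
    except (KeyError, ValueError) as exc:
        raise RuntimeError(f"stage de_filter ({ref.name}): {exc}") from exc
    evidence["de_filter"] = de_table
    counts = {f"consensus_{h}": len(g) for h, g in per_hist.items()}
    counts.update(common=len(common), de_filtered=len(de_genes), genes_dropped_in_harmonization=dropped)
    return SignatureResult(
        per_histology=per_hist,
        common=common,
        de_filtered=de_genes,
        stage_counts=counts,
        thresholds={
            "seed_gene": seed_gene,
            "method": method,
            "consensus_alpha": consensus_alpha,
            "require_sign": require_sign,
            "de_alpha": de_alpha,
            "de_cohort": ref.name,
            "correlation_group": correlation_group,
        },
        evidence=evidence,
    )
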