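"""Prognostic modelling: dichotomization, Kaplan-Meier and log-rank,
confounder-adjusted Cox models, elastic-net CpG selection with
cross-validated penalty choice, bootstrap internal validation, and the
nested likelihood-ratio test for marker combinations.

Endpoints follow the clinical convention: disease-free survival (DFS,
surgery to recurrence) and overall survival (OS, diagnosis to death or
last follow-up), in months, with 1 = event and 0 = censored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError, ConvergenceWarning
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import concordance_index
from scipy import stats
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

CONFOUNDERS = ("age", "sex", "smoking")


def dichotomize(values, rule: str = "median", threshold: float = 0.5):
    """Split a marker into two labelled groups, recording the cut value.

    Rules: ``mean`` and ``median`` (labels high/low, as used for
    expression markers) and ``beta_threshold`` (labels
    methylated/unmethylated at the given beta cut, default 0.5).  The
    boundary value is assigned to the upper class.
    """
    values = pd.Series(values).astype(float)
    if len(values) < 2:
        raise ValueError("need at least 2 samples to dichotomize")
    if values.nunique() == 1:
        raise ValueError("degenerate split: all values identical")
    if rule == "mean":
        cut, hi, lo = float(values.mean()), "high", "low"
    elif rule == "median":
        cut, hi, lo = float(values.median()), "high", "low"
    elif rule == "beta_threshold":
        if not 0 <= threshold <= 1:
            raise ValueError("beta threshold must lie in [0,1]")
        cut, hi, lo = float(threshold), "methylated", "unmethylated"
    else:
        raise ValueError("rule must be mean|median|beta_threshold")
    labels = pd.Series(np.where(values >= cut, hi, lo), index=values.index)
    return labels, cut


def kaplan_meier(times, events, groups=None) -> dict[str, pd.DataFrame]:
    """Product-limit survival curves, one per group.

    Each curve is a step-function table (time, survival, at_risk,
    censored) suitable for replotting; censoring marks are retained.
    """
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("negative survival times")
    events = np.asarray(events).astype(int)
    if groups is None:
        groups = np.repeat("all", len(times))
    groups = np.asarray(groups)
    out = {}
    for g in pd.unique(groups):
        mask = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        tab = kmf.event_table
        surv = kmf.survival_function_["KM_estimate"]
        out[str(g)] = pd.DataFrame(
            {
                "time": tab.index.to_numpy(dtype=float),
                "survival": surv.reindex(tab.index).to_numpy(),
                "at_risk": tab["at_risk"].to_numpy(),
                "events": tab["observed"].to_numpy(),
                "censored": tab["censored"].to_numpy(),
            }
        )
    return out


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank test: chi-square on 1 df of (O-E)^2/V."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"log-rank test needs exactly 2 groups, got {len(labels)}")
    a = groups == labels[0]
    res = _ll_logrank(times[a], times[~a], event_observed_A=events[a], event_observed_B=events[~a])
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxFit:
    """A fitted proportional-hazards model (Efron tie handling)."""

    summary: pd.DataFrame           # coef, se, HR, CI, p per term
    log_likelihood: float
    n: int
    n_events: int
    covariates: list[str]
    endpoint: str
    converged: bool
    sample_index: pd.Index = field(repr=False)
    fitter: CoxPHFitter = field(repr=False)

    def hazard_ratio(self, term: str) -> float:
        return float(np.exp(self.summary.loc[term, "coef"]))

    def predicted_survival(self, marker: str, marker_values, at: dict | None = None) -> pd.DataFrame:
        """Model-predicted survival curves over a continuous marker range.

        Other covariates are held at reference levels (their sample means
        unless overridden in ``at``) — the "continuous survival curve"
        rendering of a continuous methylation marker.
        """
        at = at or {}
        ref = {c: at.get(c, float(self.fitter._norm_mean.get(c, 0.0))) for c in self.covariates}
        rows = []
        for v in np.atleast_1d(marker_values):
            row = dict(ref)
            row[marker] = float(v)
            rows.append(row)
        X = pd.DataFrame(rows, index=[f"{marker}={v:g}" for v in np.atleast_1d(marker_values)])
        return self.fitter.predict_survival_function(X).T


def cox_fit(
    table: pd.DataFrame,
    marker,
    confounders=CONFOUNDERS,
    endpoint: str = "dfs",
) -> CoxFit:
    """Fit a Cox model of ``endpoint`` on marker(s) plus confounders.

    Uses the partial likelihood with Efron tie handling; the log partial
    likelihood is retained for nested likelihood-ratio testing.
    Degenerate input (constant marker, fewer events than parameters,
    complete separation) raises; a fit that stops without converging is
    returned flagged ``converged=False``.
    """
    markers = [marker] if isinstance(marker, str) else list(marker)
    covs = markers + [c for c in confounders if c in table.columns]
    missing = [c for c in markers if c not in table.columns]
    if missing:
        raise KeyError(f"marker column(s) absent: {missing}")
    tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
    if tcol not in table.columns or ecol not in table.columns:
        raise KeyError(f"table lacks {tcol}/{ecol}")
    df = table[covs + [tcol, ecol]].dropna()
    n_events = int(df[ecol].sum())
    if n_events < len(covs):
        raise ValueError(f"{n_events} events cannot support {len(covs)} parameters")
    for c in covs:
        if df[c].nunique() == 1:
            raise ValueError(f"covariate {c!r} is constant: no information")
    cph = CoxPHFitter()
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            cph.fit(df, duration_col=tcol, event_col=ecol)
        except ConvergenceError as exc:
            raise ValueError(f"Cox fit failed to converge (separation?): {exc}") from exc
        except ConvergenceWarning:
            converged = False
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col=tcol, event_col=ecol)
    summ = cph.summary[["coef", "se(coef)", "exp(coef)", "exp(coef) lower 95%", "exp(coef) upper 95%", "p"]]
    summ = summ.rename(
        columns={
            "se(coef)": "se",
            "exp(coef)": "hr",
            "exp(coef) lower 95%": "hr_ci_low",
            "exp(coef) upper 95%": "hr_ci_high",
        }
    )
    return CoxFit(
        summary=summ,
        log_likelihood=float(cph.log_likelihood_),
        n=len(df),
        n_events=n_events,
        covariates=covs,
        endpoint=endpoint,
        converged=converged,
        sample_index=df.index,
        fitter=cph,
    )


def nested_lrt(fit_full: CoxFit, fit_reduced: CoxFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested Cox models on the same samples.

    statistic = 2 * (logPL_full - logPL_reduced), chi-square with df equal
    to the parameter difference.  Identical models give exactly 0.
    """
    full, reduced = set(fit_full.covariates), set(fit_reduced.covariates)
    if not reduced <= full:
        raise ValueError("models are not nested: reduced covariates not a subset of full")
    if fit_full.endpoint != fit_reduced.endpoint:
        raise ValueError("models fit different endpoints")
    if not fit_full.sample_index.sort_values().equals(fit_reduced.sample_index.sort_values()):
        raise ValueError("models were fit on different sample sets")
    stat = 2.0 * (fit_full.log_likelihood - fit_reduced.log_likelihood)
    if stat < -1e-6:
        raise ValueError("full model has lower partial likelihood than reduced; fits disagree")
    stat = max(stat, 0.0)
    df = len(full) - len(reduced)
    p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    return float(stat), df, p


def _breslow_loglik(lp: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Breslow partial log-likelihood of a fixed linear predictor."""
    order = np.argsort(-time, kind="stable")
    lp, time, event = lp[order], time[order], event[order]
    log_risk = np.logaddexp.accumulate(lp)
    # with ties, every event at time t uses the risk set {time >= t}
    ll = 0.0
    i = 0
    n = len(lp)
    while i < n:
        j = i
        while j + 1 < n and time[j + 1] == time[i]:
            j += 1
        denom = log_risk[j]
        ll += float(lp[i : j + 1][event[i : j + 1] == 1].sum()) - denom * int(event[i : j + 1].sum())
        i = j + 1
    return ll


@dataclass
class SelectionResult:
    selected: list[str]
    chosen_alpha: float
    mixing: float
    cv_folds: int
    seed: int
    alphas: np.ndarray = field(repr=False)
    cv_loglik: pd.DataFrame = field(repr=False)


def elastic_net_cox_select(
    beta_candidates: pd.DataFrame,
    table: pd.DataFrame,
    endpoint: str = "dfs",
    confounders=CONFOUNDERS,
    mixing: float = 0.5,
    cv_folds: int = 10,
    seed: int = 0,
    alphas=None,
) -> tuple[SelectionResult, CoxFit | None]:
    """Elastic-net penalized Cox selection over candidate CpGs.

    Fits the penalty path (``mixing`` = L1 fraction), chooses the penalty
    by K-fold cross-validated Breslow partial likelihood under the
    one-standard-error rule, and refits the selected CpGs unpenalized with
    confounders.  Returns the selection plus the refit (None when nothing
    is selected).
    """
    X = beta_candidates.T  # samples x CpGs
    shared = X.index.intersection(table.index)
    X = X.loc[shared]
    tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
    surv = table.loc[shared, [tcol, ecol]].dropna()
    X = X.loc[surv.index]
    keep = X.columns[X.std(ddof=0) > 0]
    if len(keep) == 0:
        raise ValueError("all candidate CpGs have zero variance")
    X = X[keep]
    n_events = int(surv[ecol].sum())
    if n_events < cv_folds:
        raise ValueError(f"{n_events} events cannot support {cv_folds}-fold cross-validation")
    y = Surv.from_arrays(surv[ecol].astype(bool).to_numpy(), surv[tcol].to_numpy())
    Xs = (X - X.mean()) / X.std(ddof=0)
    base = CoxnetSurvivalAnalysis(l1_ratio=max(mixing, 1e-6), alphas=alphas, n_alphas=50, alpha_min_ratio=0.01)
    base.fit(Xs.to_numpy(), y)
    path_alphas = np.asarray(base.alphas_)

    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(Xs))
    folds = np.array_split(idx, cv_folds)
    cv = np.full((cv_folds, len(path_alphas)), np.nan)
    t_all = surv[tcol].to_numpy()
    e_all = surv[ecol].to_numpy().astype(int)
    for k, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(idx, test_idx)
        model = CoxnetSurvivalAnalysis(l1_ratio=max(mixing, 1e-6), alphas=path_alphas)
        try:
            model.fit(Xs.to_numpy()[train_idx], y[train_idx])
        except (ValueError, ArithmeticError):
            continue
        fitted = list(np.asarray(model.alphas_))
        for a_i, alpha in enumerate(path_alphas):
            if alpha not in fitted:
                continue
            coefs = model.coef_[:, fitted.index(alpha)]
            lp = Xs.to_numpy() @ coefs
            # CV partial likelihood by difference: full-data minus train-only
            cv[k, a_i] = _breslow_loglik(lp, t_all, e_all) - _breslow_loglik(
                lp[train_idx], t_all[train_idx], e_all[train_idx]
            )
    # fold-level log-likelihood levels differ by fold composition, so only
    # penalties evaluated in EVERY fold are comparable
    complete = ~np.isnan(cv).any(axis=0)
    if not complete.any():
        raise ValueError("cross-validation failed for every penalty")
    mean = np.where(complete, np.mean(cv, axis=0, where=~np.isnan(cv)), np.nan)
    best = int(np.nanargmax(mean))
    # one-standard-error rule on paired fold-wise differences from the best
    # penalty: fold-level offsets cancel, so the band reflects the actual
    # uncertainty of the comparison between penalties
    diffs = cv - cv[:, [best]]
    k_eff = np.sum(~np.isnan(diffs), axis=0).clip(1)
    se = np.nanstd(diffs, axis=0, ddof=1) / np.sqrt(k_eff)
    chosen = best
    for a_i in range(len(path_alphas)):  # alphas descend: first qualifying = sparsest
        if not np.isnan(mean[a_i]) and mean[a_i] >= mean[best] - se[a_i]:
            chosen = a_i
            break
    coefs = base.coef_[:, chosen]
    selected = [c for c, b in zip(X.columns, coefs) if b != 0]
    result = SelectionResult(
        selected=selected,
        chosen_alpha=float(path_alphas[chosen]),
        mixing=mixing,
        cv_folds=cv_folds,
        seed=seed,
        alphas=path_alphas,
        cv_loglik=pd.DataFrame({"alpha": path_alphas, "mean_cv_loglik": mean, "se": se}),
    )
    refit = None
    if selected:
        aug = table.loc[surv.index].copy()
        for c in selected:
            aug[c] = X[c]
        refit = cox_fit(aug, selected, confounders=confounders, endpoint=endpoint)
    return result, refit


def bootstrap_validate(
    table: pd.DataFrame,
    marker,
    confounders=CONFOUNDERS,
    endpoint: str = "dfs",
    B: int = 1000,
    seed: int = 0,
) -> dict:
    """Optimism-corrected concordance index by Harrell's bootstrap.

    apparent c-index on the full data, minus the mean over B bootstrap
    replicates of (c on the bootstrap sample - c of the bootstrap model
    applied to the original data).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    full_fit = cox_fit(table, marker, confounders=confounders, endpoint=endpoint)
    tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
    base = table.loc[full_fit.sample_index]
    apparent = float(full_fit.fitter.concordance_index_)
    rng = np.random.default_rng(seed)
    optimisms = []
    failures = 0
    for _ in range(B):
        boot = base.iloc[rng.integers(0, len(base), len(base))].reset_index(drop=True)
        try:
            bfit = cox_fit(boot, marker, confounders=confounders, endpoint=endpoint)
        except (ValueError, KeyError):
            failures += 1
            continue
        c_train = float(bfit.fitter.concordance_index_)
        lp = bfit.fitter.predict_partial_hazard(base[bfit.covariates])
        c_orig = concordance_index(base[tcol], -lp, base[ecol])
        optimisms.append(c_train - c_orig)
    if not optimisms:
        raise ValueError("every bootstrap replicate failed to fit")
    optimism = float(np.mean(optimisms))
    return {
        "apparent_c_index": apparent,
        "optimism": optimism,
        "corrected_c_index": apparent - optimism,
        "B_effective": len(optimisms),
        "B_failed": failures,
    }
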