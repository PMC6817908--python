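"""Reference synthetic experiments over the full pipeline.

Each function runs one property experiment end to end — generate data with
planted truth, run the relevant pipeline stage, measure recovery or
calibration — and returns plain numbers.  The study conditions (sample
sizes, effect sizes, numbers of replicates) are fixed here; only the seed
varies.  These are the experiments the analysis scripts report and the
acceptance machinery re-runs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._util import child_rng
from .config import SimulationConfig
from .coexpr import run_signature_pipeline
from .integrate import methylation_expression_correlation, tumor_vs_normal_auroc
from .methyl import cumulative_difference, detect_consistent_region, group_mean_profile, per_cpg_test
from .survival import cox_fit, kaplan_meier, logrank_test, nested_lrt
from .synthdata import (
    SEED_GENE,
    generate_expression_cohorts,
    generate_methylation,
    generate_survival,
    make_covariates,
)


def signature_recovery(seed: int = 0, n_seeds: int = 50) -> dict:
    """Planted-module recovery of the screening cascade.

    Six cohorts (three per histology, 100 tumor + 50 normal samples each),
    2000 genes, a 30-gene module at population r = 0.5 with a 1.5-SD
    tumor shift.  A seed passes when >= 90% of planted genes survive the
    cascade and <= 10% of the output is non-planted.
    """
    passes, recalls, precisions = [], [], []
    for k in range(n_seeds):
        cfg = SimulationConfig(rng_seed=int(child_rng(seed, "sigrec", k).integers(2**31)))
        collection, truth = generate_expression_cohorts(cfg)
        result = run_signature_pipeline(collection, SEED_GENE)
        planted = set(truth.planted_gene_ids)
        out = set(result.de_filtered)
        recall = len(out & planted) / len(planted)
        precision = 1.0 - (len(out - planted) / max(len(out), 1))
        recalls.append(recall)
        precisions.append(precision)
        passes.append(recall >= 0.9 and (len(out - planted) / max(len(out), 1)) <= 0.10)
    return {
        "pass_rate": float(np.mean(passes)),
        "mean_recall": float(np.mean(recalls)),
        "mean_precision": float(np.mean(precisions)),
        "n_seeds": n_seeds,
    }


def null_specificity(seed: int = 0, n_seeds: int = 20) -> dict:
    """With no planted structure the cascade should return nothing."""
    empty = []
    for k in range(n_seeds):
        cfg = SimulationConfig(
            target_module_r=0.0,
            de_effect=0.0,
            n_genes=1000,
            rng_seed=int(child_rng(seed, "nullspec", k).integers(2**31)),
        )
        collection, _ = generate_expression_cohorts(cfg)
        result = run_signature_pipeline(collection, SEED_GENE)
        empty.append(len(result.de_filtered) == 0)
    return {"empty_rate": float(np.mean(empty)), "n_seeds": n_seeds}


def region_localization(seed: int = 0, n_seeds: int = 100) -> dict:
    """Localization of the planted 5-CpG hypomethylated shore run.

    40 tumor / 40 normal samples over a 60-probe promoter map with a
    20-pp planted run.  A seed passes when exactly one region is called
    with both bounds within one probe of the truth.  The island segment
    of the cumulative curve must stay inside a 4-SE noise band.
    """
    localized, island_flat = [], []
    for k in range(n_seeds):
        cfg = SimulationConfig(
            n_samples_tumor=40,
            n_samples_normal=40,
            rng_seed=int(child_rng(seed, "region", k).integers(2**31)),
        )
        sim = generate_methylation(cfg)
        profile = group_mean_profile(sim.beta, sim.cpg_map)
        cum = cumulative_difference(profile, sim.cpg_map)
        tests = per_cpg_test(sim.beta, sim.cpg_map)
        calls = detect_consistent_region(cum, tests["q"], sim.cpg_map)
        lo, hi = sim.truth.planted_region_bounds
        localized.append(
            len(calls) == 1
            and abs(calls[0].start_index - lo) <= 1
            and abs(calls[0].end_index - hi) <= 1
        )
        # island increment vs its sampling noise (pp scale); probes share a
        # per-sample latent factor, so the SE must come from per-sample
        # island means, not per-probe variances
        island = [i for i, p in enumerate(sim.cpg_map.probe_ids)
                  if sim.cpg_map.region_of(p) == "island"]
        tum = sim.beta.values[sim.beta.samples_in("tumor")].iloc[island] * 100
        nor = sim.beta.values[sim.beta.samples_in("normal")].iloc[island] * 100
        m_t, m_n = tum.mean(axis=0), nor.mean(axis=0)  # per-sample island means
        se = len(island) * np.sqrt(m_t.var(ddof=1) / len(m_t) + m_n.var(ddof=1) / len(m_n))
        increment = cum["cumulative"].iloc[island[-1]] - cum["cumulative"].iloc[island[0] - 1]
        island_flat.append(abs(increment) <= 4 * se)
    return {
        "localized_rate": float(np.mean(localized)),
        "island_flat_rate": float(np.mean(island_flat)),
        "n_seeds": n_seeds,
    }


def per_cpg_calibration(seed: int = 0, n_probes: int = 2000, n_per_group: int = 40) -> dict:
    """Type-I error of the per-CpG test on independent null probes."""
    from scipy.special import expit

    rng = child_rng(seed, "calib")
    mu = 0.6  # logit of ~0.65
    vals = expit(mu + 0.5 * rng.standard_normal((n_probes, 2 * n_per_group)))
    cols = [f"T{i}" for i in range(n_per_group)] + [f"N{i}" for i in range(n_per_group)]
    from .methyl import BetaMatrix

    beta = BetaMatrix(
        pd.DataFrame(vals, index=[f"cg{i:08d}" for i in range(n_probes)], columns=cols),
        pd.Series(["tumor"] * n_per_group + ["normal"] * n_per_group, index=cols),
    )
    tests = per_cpg_test(beta)
    frac = float((tests["p"] < 0.05).mean())
    return {"frac_p_below_05": frac, "n_probes": n_probes}


def auroc_closed_form(seed: int = 0, n_reps: int = 20, n: int = 500, d: float = 1.19) -> dict:
    """Binormal AUROC against the closed form Phi(d / sqrt(2)).

    Also checks the pair-counting implementation against the Mann-Whitney
    U correspondence exactly on a small sample with ties.
    """
    rng = child_rng(seed, "auroc")
    aurocs = []
    for _ in range(n_reps):
        tum = rng.standard_normal(n) + d
        nor = rng.standard_normal(n)
        vals = np.concatenate([tum, nor])
        labels = np.array(["tumor"] * n + ["normal"] * n)
        aurocs.append(tumor_vs_normal_auroc(vals, labels).auroc)
    # exact oracle equality on small data with ties
    small = np.round(rng.normal(size=60), 1)
    lab = np.array(["tumor"] * 30 + ["normal"] * 30)
    ours = tumor_vs_normal_auroc(small, lab).auroc
    U = stats.mannwhitneyu(small[:30], small[30:], alternative="two-sided").statistic
    oracle_equal = bool(abs(ours - U / 900.0) < 1e-12)
    expected = float(stats.norm.cdf(d / np.sqrt(2)))
    return {
        "mean_auroc": float(np.mean(aurocs)),
        "expected_auroc": expected,
        "pair_count_equals_U": oracle_equal,
        "n_reps": n_reps,
    }


def coupling_recovery(seed: int = 0, n_reps: int = 10, n_tumor: int = 200) -> dict:
    """Recovery of the planted inverse methylation-expression coupling."""
    rs = []
    for k in range(n_reps):
        cfg = SimulationConfig(
            n_samples_tumor=n_tumor,
            n_samples_normal=20,
            rng_seed=int(child_rng(seed, "coupling", k).integers(2**31)),
        )
        sim = generate_methylation(cfg)
        lo, hi = sim.truth.planted_region_bounds
        probes = sim.cpg_map.probe_ids[lo : hi + 1]
        score = sim.beta.values.loc[probes, sim.beta.samples_in("tumor")].mean(axis=0)
        rs.append(methylation_expression_correlation(score, sim.coupled_expression).r)
    return {"mean_r": float(np.mean(rs)), "target": -0.5, "n_reps": n_reps}


def cox_recovery(seed: int = 0, n_seeds: int = 30, n: int = 300) -> dict:
    """Cox hazard-ratio recovery for a planted HR of 2 with ~60% events."""
    in_band, hrs, event_fracs = [], [], []
    for k in range(n_seeds):
        cfg = SimulationConfig(rng_seed=int(child_rng(seed, "coxrec", k).integers(2**31)))
        cov = make_covariates(n, cfg)
        table = generate_survival(cov, cfg)
        fit = cox_fit(table, "status", endpoint="dfs")
        hr = fit.hazard_ratio("status")
        hrs.append(hr)
        in_band.append(1.6 <= hr <= 2.5)
        event_fracs.append(table["dfs_event"].mean())
    return {
        "in_band_rate": float(np.mean(in_band)),
        "mean_hr": float(np.mean(hrs)),
        "mean_event_frac": float(np.mean(event_fracs)),
        "n_seeds": n_seeds,
    }


def logrank_null_calibration(seed: int = 0, n_reps: int = 200, n: int = 200) -> dict:
    """Type-I error of the log-rank test under a null group label."""
    rejections = []
    for k in range(n_reps):
        cfg = SimulationConfig(
            hazard_log_hr=0.0,
            confounder_effects={},
            rng_seed=int(child_rng(seed, "lrnull", k).integers(2**31)),
        )
        cov = make_covariates(n, cfg)
        table = generate_survival(cov, cfg)
        _, p = logrank_test(table["dfs_time"], table["dfs_event"], cov["status"].to_numpy())
        rejections.append(p < 0.05)
    return {"rejection_rate": float(np.mean(rejections)), "n_reps": n_reps}


def lrt_null_calibration(seed: int = 0, n_sims: int = 500, n: int = 150) -> dict:
    """Nested-LRT calibration when the second marker carries no effect."""
    rejections = []
    for k in range(n_sims):
        rng = child_rng(seed, "lrtnull", k)
        cfg = SimulationConfig(rng_seed=int(rng.integers(2**31)))
        cov = make_covariates(n, cfg)
        table = generate_survival(cov, cfg)
        table["null_marker"] = rng.standard_normal(n)
        full = cox_fit(table, ["status", "null_marker"], confounders=(), endpoint="dfs")
        reduced = cox_fit(table, ["status"], confounders=(), endpoint="dfs")
        _, _, p = nested_lrt(full, reduced)
        rejections.append(p < 0.05)
    return {"rejection_rate": float(np.mean(rejections)), "n_sims": n_sims}


def hand_oracles() -> dict:
    """The package's statistics on hand-checkable toys."""
    from .coexpr import correlate_seed_gene, differential_expression_filter
    from .methyl import CpGMap

    expr = pd.DataFrame(
        [[1, 2, 3, 4], [1, 3, 2, 4]], index=["SEED", "g1"], columns=list("abcd"), dtype=float
    )
    pearson_r = float(correlate_seed_gene(expr, "SEED").loc["g1", "r"])

    mat = pd.DataFrame([[1, 2, 3, 4, 5, 6]], index=["g1"], columns=list("abcdef"), dtype=float)
    groups = pd.Series(["tumor"] * 3 + ["normal"] * 3, index=list("abcdef"))
    _, de = differential_expression_filter(mat, groups, ["g1"], alpha=0.05)
    mw_p = float(de.loc["g1", "p"])

    stat, _ = logrank_test([1, 3, 2, 4], [1, 1, 1, 1], ["A", "A", "B", "B"])

    km = kaplan_meier([1, 2, 3], [1, 0, 1])["all"].set_index("time")["survival"]

    frame = pd.DataFrame(
        {"chrom": "chr1", "pos": np.arange(5) * 10, "region": ["north_shore"] * 2 + ["island"] * 2 + ["south_shore"]},
        index=pd.Index([f"cg{i:08d}" for i in range(5)], name="probe_id"),
    )
    cmap = CpGMap(frame)
    profile = pd.DataFrame(
        {"mean_pct_normal": [60, 55, 10, 10, 58], "mean_pct_tumor": [40, 35, 10, 10, 48]},
        index=cmap.probe_ids, dtype=float,
    )
    cum = cumulative_difference(profile, cmap)["cumulative"].tolist()

    return {
        "pearson_toy_r": pearson_r,
        "mannwhitney_toy_p": mw_p,
        "logrank_toy_stat": float(stat),
        "km_toy_surv_after_first_event": float(km.loc[1.0]),
        "km_toy_surv_final": float(km.loc[3.0]),
        "cumulative_toy_final": float(cum[-1]),
        "cumulative_toy_curve": cum,
    }
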