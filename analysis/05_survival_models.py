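#!/usr/bin/env python
"""Prognostic modelling of the planted methylation marker.

Dichotomizes tumors at beta = 0.5 on the planted-region score, compares
the groups by Kaplan-Meier/log-rank, fits a confounder-adjusted Cox model
of DFS on methylation status, selects prognostic CpGs by elastic-net Cox,
validates the status model by Harrell's optimism-corrected bootstrap, and
tests whether the second promoter adds prognostic information on top of
the first (nested likelihood-ratio test).
"""

import argparse

import numpy as np

from shorescan.config import SimulationConfig
from shorescan.integrate import promoter_score
from shorescan.methyl import classify_methylation
from shorescan.survival import (
    bootstrap_validate,
    cox_fit,
    elastic_net_cox_select,
    kaplan_meier,
    logrank_test,
    nested_lrt,
)
from shorescan.synthdata import simulate_bundle

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--cox-out", default="results/cox_dfs.tsv")
args = parser.parse_args()

config = SimulationConfig(n_samples_tumor=300, rng_seed=args.seed)
bundle = simulate_bundle(config)
meth, table = bundle.methylation, bundle.survival

lo, hi = bundle.truth.planted_region_bounds
region = meth.cpg_map.probe_ids[lo : hi + 1]
score = promoter_score(meth.beta, region)[table.index]
labels = classify_methylation(score)

stat, p = logrank_test(table["dfs_time"], table["dfs_event"], labels.to_numpy())
km = kaplan_meier(table["dfs_time"], table["dfs_event"], labels.to_numpy())
medians = {g: curve.loc[curve["survival"] <= 0.5, "time"].min() for g, curve in km.items()}
print(f"log-rank by beta>=0.5 status: chi2 = {stat:.2f}, p = {p:.3g}; "
      f"median DFS (months): {({g: round(float(m), 1) for g, m in medians.items()})}")

fit = cox_fit(table, "status", endpoint="dfs")
row = fit.summary.loc["status"]
print(f"Cox DFS, status adjusted for age/sex/smoking: HR = {row['hr']:.2f} "
      f"[{row['hr_ci_low']:.2f}, {row['hr_ci_high']:.2f}], p = {row['p']:.2g} "
      f"(planted HR = {np.exp(bundle.truth.true_log_hr):.1f}; "
      f"{fit.n_events} events / {fit.n})")
fit.summary.to_csv(args.cox_out, sep="\t")

selection, refit = elastic_net_cox_select(
    meth.beta.values[list(table.index)], table, endpoint="dfs", seed=args.seed
)
print(f"elastic-net Cox over {meth.beta.values.shape[0]} promoter CpGs: "
      f"selected {selection.selected or 'nothing'} at alpha = {selection.chosen_alpha:.3g}")

val = bootstrap_validate(table, "status", endpoint="dfs", B=200, seed=args.seed)
print(f"bootstrap validation (B = {val['B_effective']}): apparent c = "
      f"{val['apparent_c_index']:.3f}, optimism-corrected c = {val['corrected_c_index']:.3f}")

table = table.copy()
table["score_a"] = promoter_score(meth.beta, meth.cpg_map.probe_ids)[table.index]
table["score_b"] = promoter_score(meth.beta_b, meth.cpg_map_b.probe_ids)[table.index]
both = cox_fit(table, ["score_a", "score_b"], endpoint="dfs")
one = cox_fit(table, ["score_a"], endpoint="dfs")
lrt_stat, df, lrt_p = nested_lrt(both, one)
print(f"nested LRT (promoter B on top of promoter A): chi2({df}) = {lrt_stat:.2f}, "
      f"p = {lrt_p:.2f} -- co-methylated promoters carry largely redundant "
      f"prognostic information")
print(f"wrote {args.cox_out}")
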