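"""End-to-end orchestration: simulate/load -> signature screen ->
methylation region calling -> integration -> prognostic models.

Every stage writes its tables as soon as they exist, so a failing stage
leaves earlier outputs on disk; the JSON summary records every threshold
that actually applied (no silent defaults) plus per-stage counts.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig
from .coexpr import run_signature_pipeline
from .integrate import (
    cross_promoter_correlation,
    methylation_expression_correlation,
    promoter_score,
    tumor_vs_normal_auroc,
)
from .methyl import (
    classify_methylation,
    cumulative_difference,
    detect_consistent_region,
    group_mean_profile,
    per_cpg_test,
    write_region_calls,
)
from .survival import bootstrap_validate, cox_fit, elastic_net_cox_select, kaplan_meier, logrank_test, nested_lrt
from .synthdata import load_fixture_bundle, simulate_bundle, write_fixture_bundle

STAGES = ("simulate", "signature", "methylation", "integrate", "survival")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig, stages=None) -> dict:
    """Run the requested stages (default: all) and return the JSON summary."""
    config.validate()
    stages = list(stages or STAGES)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "version": __version__,
        "thresholds": config.thresholds(),
        "stages": {},
    }
    t0 = time.time()

    def _finish(stage, payload):
        summary["stages"][stage] = payload
        (out / "summary.json").write_text(json.dumps(summary, indent=1, default=str))

    # --- data source -------------------------------------------------
    try:
        if config.simulation is not None:
            sim = config.simulation.replace(rng_seed=config.seed)
            bundle = simulate_bundle(sim)
            if "simulate" in stages:
                write_fixture_bundle(bundle, out / "bundle", overwrite=True)
                _finish("simulate", {"files": "bundle/", "rng_seed": sim.rng_seed,
                                     "simulation": {k: str(v) for k, v in vars(sim).items()}})
        else:
            bundle = load_fixture_bundle(config.expression_dir or config.methylation_dir)
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError("simulate", exc) from exc

    meth = bundle.methylation
    truth = bundle.truth

    if "signature" in stages:
        try:
            sig = run_signature_pipeline(
                bundle.collection,
                seed_gene=config.seed_gene,
                method=config.correlation_method,
                consensus_alpha=config.consensus_alpha,
                require_sign=config.require_sign,
                de_alpha=config.de_alpha,
            )
            sig.to_frame().to_csv(out / "signature_stages.tsv", sep="\t", index=False)
            _finish("signature", {"stage_counts": sig.stage_counts, "thresholds": sig.thresholds,
                                  "de_filtered": sig.de_filtered})
        except Exception as exc:  # noqa: BLE001
            raise StageError("signature", exc) from exc

    region_calls = []
    if "methylation" in stages:
        try:
            profile = group_mean_profile(meth.beta, meth.cpg_map)
            cum = cumulative_difference(profile, meth.cpg_map)
            tests = per_cpg_test(meth.beta, meth.cpg_map).loc[cum.index]
            region_calls = detect_consistent_region(
                cum, tests["q"], meth.cpg_map,
                min_run=config.min_run, min_delta_pp=config.min_delta_pp, q_max=config.q_max,
            )
            curve = cum.join(tests[["p", "q"]])
            curve.to_csv(out / "cumulative_curve.tsv", sep="\t")
            write_region_calls(region_calls, meth.cpg_map, out / "region_calls.bed", out / "region_calls.tsv")
            _finish("methylation", {
                "probes": len(cum),
                "excluded_probes": profile.attrs.get("excluded", []),
                "region_calls": [
                    {"start_probe": c.probe_ids[0], "end_probe": c.probe_ids[-1],
                     "run_length": c.run_length, "mean_delta_pp": c.mean_delta,
                     "regions": c.regions_spanned}
                    for c in region_calls
                ],
            })
        except Exception as exc:  # noqa: BLE001
            raise StageError("methylation", exc) from exc

    start, end = truth.planted_region_bounds
    region_probes = meth.cpg_map.probe_ids[start : end + 1]
    score_a = promoter_score(meth.beta, region_probes)

    if "integrate" in stages:
        try:
            tumor_score = score_a[meth.beta.samples_in("tumor")]
            coupling = methylation_expression_correlation(tumor_score, meth.coupled_expression)
            score_b = promoter_score(meth.beta_b, meth.cpg_map_b.probe_ids)
            score_a_full = promoter_score(meth.beta, meth.cpg_map.probe_ids)
            comet = cross_promoter_correlation(score_a_full, score_b)
            auroc = tumor_vs_normal_auroc(1.0 - score_a, meth.beta.groups[score_a.index])
            pd.DataFrame(
                [
                    {"statistic": "meth_expr_r", "value": coupling.r, "p": coupling.p, "n": coupling.n},
                    {"statistic": "cross_promoter_r", "value": comet.r, "p": comet.p, "n": comet.n},
                    {"statistic": "auroc_tumor_vs_normal", "value": auroc.auroc, "p": auroc.p,
                     "n": auroc.n_pos + auroc.n_neg},
                ]
            ).to_csv(out / "integration.tsv", sep="\t", index=False)
            _finish("integrate", {"meth_expr_r": coupling.r, "cross_promoter_r": comet.r,
                                  "auroc": auroc.auroc})
        except Exception as exc:  # noqa: BLE001
            raise StageError("integrate", exc) from exc

    if "survival" in stages:
        try:
            table = bundle.survival.copy()
            tumor_cols = [s for s in score_a.index if s in table.index]
            score_t = score_a[tumor_cols]
            status_label = classify_methylation(score_t, threshold=config.beta_threshold)
            table = table.loc[tumor_cols]
            table["meth_score"] = score_t
            stat, p_lr = logrank_test(
                table["dfs_time"], table["dfs_event"], status_label.to_numpy()
            )
            km = kaplan_meier(table["dfs_time"], table["dfs_event"], status_label.to_numpy())
            for g, curve in km.items():
                curve.to_csv(out / f"km_dfs_{g}.tsv", sep="\t", index=False)
            fit = cox_fit(table, "status", endpoint="dfs")
            fit.summary.to_csv(out / "cox_dfs.tsv", sep="\t")
            selection, refit = elastic_net_cox_select(
                meth.beta.values[tumor_cols], table, endpoint="dfs",
                mixing=config.elastic_net_mixing,
                cv_folds=min(config.cv_folds, max(2, int(table["dfs_event"].sum()))),
                seed=config.seed,
            )
            validation = bootstrap_validate(
                table, "status", endpoint="dfs", B=config.bootstrap_replicates, seed=config.seed
            )
            score_b_t = promoter_score(meth.beta_b, meth.cpg_map_b.probe_ids)[tumor_cols]
            table["score_a"] = promoter_score(meth.beta, meth.cpg_map.probe_ids)[tumor_cols]
            table["score_b"] = score_b_t
            both = cox_fit(table, ["score_a", "score_b"], endpoint="dfs")
            one = cox_fit(table, ["score_a"], endpoint="dfs")
            lrt_stat, lrt_df, lrt_p = nested_lrt(both, one)
            _finish("survival", {
                "logrank": {"statistic": stat, "p": p_lr},
                "cox_status": {"hr": fit.hazard_ratio("status"),
                               "ci": [float(fit.summary.loc["status", "hr_ci_low"]),
                                      float(fit.summary.loc["status", "hr_ci_high"])],
                               "n": fit.n, "events": fit.n_events},
                "elastic_net": {"selected": selection.selected,
                                "chosen_alpha": selection.chosen_alpha,
                                "refit_terms": list(refit.summary.index) if refit else []},
                "bootstrap": validation,
                "two_marker_lrt": {"statistic": lrt_stat, "df": lrt_df, "p": lrt_p},
            })
        except Exception as exc:  # noqa: BLE001
            raise StageError("survival", exc) from exc

    summary["runtime_s"] = round(time.time() - t0, 2)
    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=str))
    return summary
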