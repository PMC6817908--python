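# Methods

## The problem being modelled

In non-small-cell lung cancer and similar settings, promoter CpG islands
of overexpressed genes are often unmethylated in both tumor and normal
tissue, while the flanking shores (~2 kb on either side) are methylated
in normal lung and lose methylation specifically in tumors.  Shore
hypomethylation of this kind can release expression, travel together
across co-regulated promoters, and stratify patient survival.  The
package implements the full analysis chain for this pattern — finding the
gene by consensus co-expression, localizing the hypomethylated shore run,
quantifying methylation–expression coupling, and modelling prognosis —
together with a generator that plants each effect with known parameters.

## Consensus co-expression cascade

Per cohort, Pearson (or Spearman) correlation of every gene against the
seed gene; two-sided p from the t-transform with n−2 df;
Benjamini–Hochberg within cohort across all testable genes.  Zero-variance
genes are flagged and excluded from the adjustment.  The per-histology
consensus requires q ≤ α (default 0.05) **and** positive r in every
cohort of the histology; sets are intersected across histologies; the
differential-expression filter applies a two-sided Mann–Whitney test per
candidate on a reference cohort carrying both groups, with BH restricted
to the candidate set so that the adjustment mirrors the cascade order.
The correlation screen runs on tumor samples only, matching the
tumor-series databases such screens are normally run on.

Choices the source analysis left open, fixed here and logged in every
run: the significance rule is FDR-adjusted q ≤ 0.05 (thousands of genes
are screened, so raw p would not control errors); sign consistency
defaults to "positive in all cohorts"; ID harmonization is exact string
match with unmatched genes dropped and counted; multiple array probes per
gene collapse to the maximum-variance probe.

## Cumulative-difference curve and region calls

With probes in map order (positions strictly increasing; labels forming
contiguous north_shore → island → south_shore blocks), per-probe group
means are computed on the percent scale with pairwise deletion of missing
values; probes under 50% coverage in a group are excluded and logged.
The curve accumulates Δᵢ = mean%_normal − mean%_tumor, so tumor
hypomethylation gives positive, rising segments — the sign convention is
fixed this way because an unmethylated island then shows as a flat
segment between two rises.  The "steep slope" is operationalized as run
criteria rather than a derivative threshold: a call is a maximal run of
consecutive probes with Δᵢ ≥ `min_delta_pp` (default 5 pp) and per-CpG
Mann–Whitney BH q ≤ 0.05, of length ≥ `min_run` (default 5, the size of
region such analyses aim to confirm by pyrosequencing).  A single failing
probe splits a run; calls never overlap.

The per-CpG test is Mann–Whitney + BH throughout.  A nonparametric test
avoids modelling β distributions, and it is the test named for
methylation group comparisons in this tradition; moderated linear models
(LIMMA-style) are deliberately not used.

β ≥ 0.5 classifies a sample as methylated; the boundary goes to the
methylated class so that both classes are attainable and the convention
is closed.  Hierarchical clustering of samples uses Euclidean distance on
complete-probe β vectors with average linkage; leaf order is scipy's
deterministic ordering, ties broken by input sample order.

## Integration

Promoter score = unweighted mean β over a caller-specified probe
interval (median is available); correlations are Pearson by default with
Spearman for monotone robustness; pairs are matched by sample id and
incomplete pairs dropped with the n reported.  AUROC is computed by
explicit pair counting with half-credit ties, which equals U/(n₁n₂);
its p-value is the two-sided Mann–Whitney p on the same data.  No
DeLong-style confidence interval is attached — only the test
correspondence is reported.

## Survival models

Endpoints are DFS (surgery → recurrence) and OS (diagnosis → death/last
follow-up), months, 1 = event.  Cox models use lifelines' partial
likelihood with Efron tie handling (the accepted default when tie
handling is unstated) and keep the log partial likelihood for nested
testing.  `nested_lrt` checks covariate nesting and sample identity, and
returns 2·ΔlogPL on the parameter-difference df; identical fits give
exactly zero.

Elastic-net Cox selection (scikit-survival's coxnet path, mixing
default 0.5) chooses the penalty by 10-fold cross-validated partial
likelihood in the Verweij–van Houwelingen form
cvℓ_k = ℓ(all; β_train(k)) − ℓ(train(k); β_train(k)).  Two numerical
points matter.  First, penalties not fitted in every training fold are
excluded from the comparison: fold-level likelihoods sit at different
levels, so averaging over different fold subsets fabricates spurious
peaks at the dense end of the path.  Second, the one-standard-error rule
uses the SE of **paired fold-wise differences** from the best penalty;
the classical unpaired fold SD is dominated by fold-composition noise
and, for Cox partial likelihoods, is so large that it always selects the
null model.  Selected CpGs are refit unpenalized with confounders.

Internal validation is Harrell's optimism-corrected bootstrap: corrected
c = apparent c − mean_b(c_train(b) − c_orig(b)); failed replicates
(degenerate resamples) are skipped and counted.

## The synthetic generator

All randomness derives from one global integer seed; every component
hashes a string tag into a child generator, so adding a component never
perturbs existing streams, and identical configs are byte-identical.

*Expression.* Genes × samples, log2-like scale (baseline 8, unit
variance).  The seed gene and the `module_size` planted genes load on one
shared standard-normal factor with loading √r, giving any pair of them —
in particular seed↔module gene — population correlation exactly
`target_module_r` (default 0.5).  Signature genes gain `de_effect`
(default 1.5 SD) in tumor samples.  Defaults: 3 cohorts per histology,
100 tumor + 50 normal samples, 2000 genes.

*Methylation.* β values are logit-normal — effects and latent factors
are additive on the logit scale and β stays strictly inside (0,1); only
the marginal location and spread matter downstream, so a Beta model would
buy nothing.  Island probes sit at β ≈ 0.08 in both groups; shores at
0.65 in normals; the planted run (default probes 5–9 of the 20-probe
north shore) drops by `delta_meth` (default 20 pp) in tumors only.
Logit-scale SDs: 0.35 per-probe noise, 0.35 per-sample latent; the latent
is shared between the two simulated promoters with weight
√`comethylation_rho` (default 0.8), which after averaging over probes
yields promoter-score correlations a few percent below ρ (attenuation by
residual probe noise).  The mean planted difference on the β scale is
≈ 19 pp rather than 20 because the logit-normal mean shrinks toward 0.5.

*Coupling.* Seed-gene expression of tumor samples is built directly from
the standardized planted-region score: e = 8 + ρ·z + √(1−ρ²)·ε with
ρ = `coupling_rho` (default −0.5) — matching an observed inverse
correlation without claiming mechanism.

*Survival.* Exponential proportional hazards with linear predictor
log HR·status + 0.02·(age−mean) + 0.2·sex + 0.4·smoking (defaults;
log HR = log 2 per methylation-status unit).  Baseline medians 36 (DFS)
and 48 (OS) months.  Censoring is independent Uniform(0, c) with c solved
by bisection from the exact expression P(C<T) = (1−e^{−λc})/(λc) averaged
over the cohort, so the realized censoring fraction matches
`censoring_rate` (default 0.4, ≈ 60% events); rate 0 disables censoring.
Smoking is a binary ever/never indicator (one log-HR per confounder).
DFS and OS are drawn independently given the linear predictor.

What the generator does **not** emulate: 450k probe chemistry and its
type-I/type-II biases, batch effects, copy-number confounding,
non-proportional hazards, informative censoring, or correlated
DFS/OS event processes.  Passing tests therefore demonstrate statistical
correctness of the machinery under a clean generative model, not
robustness to those real-data pathologies.

## Problem sizes of the reference experiments

Signature recovery: 50 seeds at the full study condition (6 cohorts ×
2000 genes).  Null specificity: 20 seeds at 1000 genes.  Region
localization: 100 seeds at 40/40 samples on the 60-probe map.  Per-CpG
calibration: 2000 independent null probes.  AUROC: 20 replicates at
500/500 plus an exact pair-count/U equality check.  Coupling: 10
replicates at n = 200.  Cox recovery: 30 seeds at n = 300; log-rank null:
200 replicates; nested-LRT null: 500 simulations at n = 150.  The AUROC
and coupling tolerances (±0.02, ±0.12) are bands on the estimate at the
stated n; the experiments average a small fixed number of replicates at
that n so the comparison reflects the estimator rather than one draw.

## Known limitations

* The consensus cascade's per-gene recall is the product of six
  per-cohort powers; at n = 100 tumors and r = 0.5 the per-cohort BH
  power is ≈ 0.98, giving ≈ 0.89 expected recall of the planted module —
  the cascade is intentionally conservative (a gene must pass
  everywhere), and recall rises steeply with cohort size or module
  correlation.
* The Cox hazard-ratio band [1.6, 2.5] at n = 300 with ~180 events spans
  ±1.5 asymptotic SE of the log coefficient, so ~13% of seeds fall
  outside it even with a correct estimator.
* Elastic-net selection under pure noise occasionally returns a dense
  model when the CV curve is flat; the median null selection size is 0.
* The "continuous survival curve" rendering holds confounders at their
  sample means; conditioning choices are reported, not inferred.
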