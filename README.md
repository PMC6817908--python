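# shorescan

Tools for a recurring discovery pattern in tumor epigenomics: a gene is
found through **consensus co-expression screening** (it correlates with a
seed gene of interest in every cohort examined), its promoter turns out to
carry **CpG-shore hypomethylation** restricted to tumors, the
hypomethylation couples inversely to expression, and the methylation
status carries **prognostic information** in survival models.  `shorescan`
implements each link of that chain as a tested library, and ships a
planted-truth synthetic multi-omics generator so the whole pipeline can be
exercised and validated without any external cohort.

Intended users: computational biologists analysing Infinium-450k-style
promoter methylation together with expression and survival data from
tumor/normal cohorts, and anyone who needs a reproducible, property-tested
reference implementation of the statistics below.

## What it computes

**Consensus co-expression cascade.** For each cohort, every gene *g* is
correlated with the seed gene, with two-sided p from the t-transform
t = r·√((n−2)/(1−r²)) and Benjamini–Hochberg adjustment per cohort.
A gene enters the per-histology consensus iff q ≤ α with consistently
positive r in *every* cohort of that histology; the per-histology sets are
intersected, and survivors are filtered by a two-sided Mann–Whitney
tumor-vs-normal test (BH over the candidate set only).  Each stage's
output is a subset of the previous one.

**Cumulative-difference curve and region calling.** Over an ordered
promoter map (north shore → island → south shore), per-probe group means
of β×100 give Δᵢ = mean%_normal(i) − mean%_tumor(i), and the curve
Cᵢ = Σ_{j≤i} Δⱼ.  Rising segments mark consistent tumor hypomethylation;
an unmethylated island contributes a flat segment.  A region call is a
maximal run of ≥ `min_run` (default 5) consecutive probes with
Δᵢ ≥ 5 pp and per-CpG Mann–Whitney q ≤ 0.05.

**Integration.** Promoter scores (mean β over a probe interval),
Pearson/Spearman methylation–expression correlation, cross-promoter
co-methylation, and tumor-vs-normal AUROC by pair counting with
half-credit ties (equal to U/(n₁n₂); p from the Mann–Whitney
correspondence).

**Prognosis.** β ≥ 0.5 ⇒ methylated classification; Kaplan–Meier and
log-rank; Cox proportional hazards (Efron ties) adjusted for age, sex and
smoking; elastic-net penalized Cox CpG selection with the penalty chosen
by 10-fold cross-validated partial likelihood under a one-standard-error
rule; Harrell's optimism-corrected bootstrap c-index; and the nested
likelihood-ratio test 2·Δlog PL ~ χ² for whether a second marker adds
information.

**Synthetic truth.** One global seed drives linked generators: a shared
latent factor plants the co-expression module at an exact population r; a
logit-normal β model plants an island/shore profile with a
tumor-restricted hypomethylated shore run; a shared per-sample factor
co-methylates two promoters; exponential proportional-hazards survival
(DFS and OS) follows methylation status plus confounders with calibrated
uniform censoring.

## Worked example

```
python analysis/01_simulate.py --seed 0
python analysis/03_methylation_regions.py --seed 0
python analysis/05_survival_models.py --seed 0
```

prints, with seed 0:

```
curve over 60 probes; total cumulative difference 99.2 pp
planted run: probes 5..9
called run: probes 5..9 (cg20000006..cg20000010), mean delta 19.6 pp, regions north_shore

log-rank by beta>=0.5 status: chi2 = 13.28, p = 0.000268; median DFS (months): {'unmethylated': 14.3, 'methylated': 27.9}
Cox DFS, status adjusted for age/sex/smoking: HR = 2.00 [1.37, 2.91], p = 0.00035 (planted HR = 2.0; 170 events / 300)
nested LRT (promoter B on top of promoter A): chi2(1) = 1.06, p = 0.30
```

The region caller localizes the planted 5-CpG hypomethylated run exactly;
the Cox model recovers the planted hazard ratio of 2 for hypomethylated
tumors (here HR 2.00, by construction of the generator); and the nested
LRT correctly finds that a second, co-methylated promoter adds no
independent prognostic information.  `analysis/02_signature_screen.py`
and `analysis/04_integration.py` run the co-expression cascade
(29/30 planted genes recovered at seed 0) and the cross-layer
correlations (r = −0.60 coupling, r = 0.82 co-methylation, AUROC 0.94).

## Layout

```
src/shorescan/      library: synthdata, coexpr, methyl, integrate,
                    survival, pipeline, experiments, cli
analysis/           numbered narrative drivers writing results/
tests/              pytest suite (unit + property + acceptance bands)
scripts/            acceptance.py
docs/methods.md     models, parameters, design choices, limitations
```

A `shorescan` console script exposes `simulate / signature / methylation /
integrate / survival / all` subcommands over a YAML run configuration.
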