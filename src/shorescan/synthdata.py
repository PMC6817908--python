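"""Planted-truth synthetic multi-omics generator.

Emulates the statistical structure of a two-histology lung-tumor study so
that every downstream stage can be tested against a recorded ground truth:

* several expression cohorts per histology in which a seed gene and a
  planted module share one latent factor (population correlation equal to
  the configured target), and the signature genes carry a tumor-vs-normal
  mean shift;
* an ordered promoter CpG map (north shore, island, south shore) whose
  beta values are logit-normal, with the island unmethylated in both
  groups, shores methylated in normal lung, and a planted run of
  consecutive shore CpGs hypomethylated in tumors only;
* a second promoter co-methylated with the first through a shared
  per-sample latent factor;
* a seed-gene expression vector inversely coupled to the promoter
  methylation score;
* exponential proportional-hazards survival (DFS and OS) driven by
  methylation status plus age/sex/smoking confounders, with independent
  uniform censoring calibrated to the requested censoring rate.

All randomness derives from one global integer seed via tagged child
generators, so identical configs produce byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from ._util import child_rng, read_tsv_matrix, sha256_file, write_tsv_matrix
from .coexpr import Cohort, CohortCollection
from .config import SimulationConfig
from .methyl import BetaMatrix, CpGMap, load_cpg_map, write_cpg_map

SEED_GENE = "SEED"
HISTOLOGIES = ("adeno", "squamous")


@dataclass
class SyntheticTruth:
    """What was planted, for verifying recovery downstream."""

    planted_gene_ids: list[str]
    planted_region_bounds: tuple[int, int]  # inclusive probe index interval
    true_coupling: float
    true_log_hr: float
    rng_seed: int


def _truth(config: SimulationConfig) -> SyntheticTruth:
    start, length = config.planted_region
    return SyntheticTruth(
        planted_gene_ids=[f"MOD{i:04d}" for i in range(1, config.module_size + 1)],
        planted_region_bounds=(start, start + length - 1),
        true_coupling=config.coupling_rho,
        true_log_hr=config.hazard_log_hr,
        rng_seed=config.rng_seed,
    )


def generate_expression_cohorts(config: SimulationConfig) -> tuple[CohortCollection, SyntheticTruth]:
    """Generate one expression matrix per cohort with a planted module.

    Module genes (and the seed) load on a shared standard-normal factor
    with loading sqrt(target_module_r), so any two of them — in particular
    the seed and each module gene — have population correlation equal to
    ``target_module_r``.  Signature genes additionally gain ``de_effect``
    (log2 units, = per-gene SDs) in tumor samples.  All other genes are
    independent noise.
    """
    config.validate()
    truth = _truth(config)
    gene_ids = (
        [SEED_GENE]
        + truth.planted_gene_ids
        + [f"G{i:05d}" for i in range(1, config.n_genes - config.module_size)]
    )
    n_module = config.module_size + 1  # planted genes + seed
    loading = np.sqrt(config.target_module_r)
    cohorts = []
    for hist in HISTOLOGIES:
        for k in range(config.n_cohorts_per_histology):
            name = f"{hist}_{k + 1}"
            rng = child_rng(config.rng_seed, "expr", name)
            n_t, n_n = config.n_samples_tumor, config.n_samples_normal
            n = n_t + n_n
            factor = rng.standard_normal(n)
            X = rng.standard_normal((len(gene_ids), n))
            X[:n_module] = loading * factor + np.sqrt(1 - config.target_module_r) * X[:n_module]
            X[:n_module, :n_t] += config.de_effect  # tumor shift for signature genes
            X += 8.0  # log2-intensity-like baseline
            samples = [f"{name}_T{i:03d}" for i in range(1, n_t + 1)] + [
                f"{name}_N{i:03d}" for i in range(1, n_n + 1)
            ]
            groups = pd.Series(["tumor"] * n_t + ["normal"] * n_n, index=samples)
            expr = pd.DataFrame(X, index=gene_ids, columns=samples)
            cohorts.append(Cohort(name=name, histology=hist, expression=expr, groups=groups))
    return CohortCollection(cohorts), truth


def _promoter_map(config: SimulationConfig, prefix: int, start_pos: int) -> CpGMap:
    n_sh, n_is = config.n_cpgs_shore, config.n_cpgs_island
    total = 2 * n_sh + n_is
    ids = [f"cg{prefix:d}{i:07d}" for i in range(1, total + 1)]
    regions = ["north_shore"] * n_sh + ["island"] * n_is + ["south_shore"] * n_sh
    frame = pd.DataFrame(
        {
            "chrom": "chrS",
            "pos": start_pos + 80 * np.arange(total),
            "region": regions,
        },
        index=pd.Index(ids, name="probe_id"),
    )
    return CpGMap(frame)


@dataclass
class MethylationSim:
    """Two co-methylated promoters plus the coupled seed-gene expression."""

    cpg_map: CpGMap
    beta: BetaMatrix
    cpg_map_b: CpGMap
    beta_b: BetaMatrix
    coupled_expression: pd.Series  # seed-gene log2 expression, tumor samples
    truth: SyntheticTruth


def _beta_for_promoter(
    config: SimulationConfig,
    cpg_map: CpGMap,
    latent: np.ndarray,
    groups: pd.Series,
    rng: np.random.Generator,
) -> BetaMatrix:
    regions = cpg_map.frame["region"].to_numpy()
    mu_normal = np.where(regions == "island", logit(config.island_beta), logit(config.shore_beta_normal))
    mu_tumor = mu_normal.copy()
    start, end = config.planted_region[0], config.planted_region[0] + config.planted_region[1] - 1
    tumor_level = config.shore_beta_normal - config.delta_meth / 100.0
    if tumor_level <= 0 or tumor_level >= 1:
        raise ValueError("delta_meth drives tumor beta out of (0,1)")
    north = np.where(regions == "north_shore")[0]
    planted = north[start : end + 1]
    mu_tumor[planted] = logit(tumor_level)
    is_tumor = (groups.to_numpy() == "tumor")
    mu = np.where(is_tumor[None, :], mu_tumor[:, None], mu_normal[:, None])
    noise = rng.standard_normal((len(regions), len(groups))) * config.probe_logit_sd
    vals = expit(mu + latent[None, :] + noise)
    df = pd.DataFrame(vals, index=cpg_map.frame.index, columns=groups.index)
    return BetaMatrix(df, groups)


def generate_methylation(config: SimulationConfig) -> MethylationSim:
    """Generate the promoter pair, planted shore region and coupled expression.

    Beta values are logit-normal (strictly inside (0,1)); a per-sample
    latent factor, shared between the two promoters with weight
    sqrt(comethylation_rho), induces the cross-promoter correlation.  The
    seed-gene expression of tumor samples is built from the standardized
    planted-region methylation score so that its population correlation
    with that score equals ``coupling_rho``.
    """
    config.validate()
    truth = _truth(config)
    rng = child_rng(config.rng_seed, "meth")
    n_t, n_n = config.n_samples_tumor, config.n_samples_normal
    samples = [f"T{i:03d}" for i in range(1, n_t + 1)] + [f"N{i:03d}" for i in range(1, n_n + 1)]
    groups = pd.Series(["tumor"] * n_t + ["normal"] * n_n, index=samples)
    map_a = _promoter_map(config, prefix=2, start_pos=1_000_000)
    map_b = _promoter_map(config, prefix=7, start_pos=2_000_000)
    rho = config.comethylation_rho
    shared = rng.standard_normal(len(samples))
    own_a = rng.standard_normal(len(samples))
    own_b = rng.standard_normal(len(samples))
    lat_a = config.sample_latent_sd * (np.sqrt(rho) * shared + np.sqrt(1 - rho) * own_a)
    lat_b = config.sample_latent_sd * (np.sqrt(rho) * shared + np.sqrt(1 - rho) * own_b)
    beta_a = _beta_for_promoter(config, map_a, lat_a, groups, rng)
    beta_b = _beta_for_promoter(config, map_b, lat_b, groups, rng)
    # inverse methylation -> expression coupling on the tumor samples
    start, end = truth.planted_region_bounds
    region_probes = map_a.probe_ids[start : end + 1]
    tumor_cols = [s for s in samples if groups[s] == "tumor"]
    score = beta_a.values.loc[region_probes, tumor_cols].mean(axis=0)
    z = (score - score.mean()) / score.std(ddof=0)
    rho_c = config.coupling_rho
    eps = rng.standard_normal(len(tumor_cols))
    expr = 8.0 + rho_c * z.to_numpy() + np.sqrt(1 - rho_c**2) * eps
    coupled = pd.Series(expr, index=tumor_cols, name=SEED_GENE)
    return MethylationSim(
        cpg_map=map_a, beta=beta_a, cpg_map_b=map_b, beta_b=beta_b,
        coupled_expression=coupled, truth=truth,
    )


def make_covariates(n: int, config: SimulationConfig, status: np.ndarray | None = None) -> pd.DataFrame:
    """Patient covariates: methylation status plus age/sex/smoking.

    ``status`` (1 = hypomethylated/at-risk) defaults to a fair Bernoulli
    draw; age ~ N(65, 8) years; sex and ever-smoking are Bernoulli(0.4)
    and Bernoulli(0.7), typical of surgical lung-cancer series.
    """
    rng = child_rng(config.rng_seed, "covariates", n)
    if status is None:
        status = rng.integers(0, 2, n)
    return pd.DataFrame(
        {
            "status": np.asarray(status, dtype=float),
            "age": rng.normal(65.0, 8.0, n),
            "sex": rng.integers(0, 2, n).astype(float),
            "smoking": (rng.random(n) < 0.7).astype(float),
        },
        index=[f"P{i:04d}" for i in range(1, n + 1)],
    )


def _censoring_horizon(lam: np.ndarray, target: float) -> float:
    """Horizon c of Uniform(0,c) censoring giving mean censoring ``target``.

    For T ~ Exp(lam) and C ~ Uniform(0,c), P(censored) = (1-exp(-lam*c))/(lam*c),
    monotone decreasing in c; solved by bisection on the cohort mean.
    """

    def rate(c: float) -> float:
        x = lam * c
        return float(np.mean((1 - np.exp(-x)) / x))

    lo, hi = 1e-6, 1e8
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if rate(mid) > target:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def generate_survival(per_sample_covariates: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Exponential proportional-hazards DFS and OS with uniform censoring.

    The linear predictor is hazard_log_hr * status plus the configured
    confounder log-HRs applied to centered age (per year), sex and
    smoking.  Baseline medians: 36 months (DFS), 48 months (OS).  Times
    are months.
    """
    config.validate()
    required = {"status", "age", "sex", "smoking"}
    if not required.issubset(per_sample_covariates.columns):
        raise ValueError(f"covariates must include {sorted(required)}")
    cov = per_sample_covariates
    eff = config.confounder_effects
    lp = (
        config.hazard_log_hr * cov["status"].to_numpy()
        + eff.get("age", 0.0) * (cov["age"].to_numpy() - cov["age"].mean())
        + eff.get("sex", 0.0) * cov["sex"].to_numpy()
        + eff.get("smoking", 0.0) * cov["smoking"].to_numpy()
    )
    rng = child_rng(config.rng_seed, "survival", len(cov))
    out = cov.copy()
    for endpoint, median_months in (("dfs", 36.0), ("os", 48.0)):
        lam = np.log(2) / median_months * np.exp(lp)
        T = rng.exponential(1.0 / lam)
        if config.censoring_rate == 0:
            time, event = T, np.ones(len(T), dtype=int)
        else:
            horizon = _censoring_horizon(lam, config.censoring_rate)
            C = rng.uniform(0, horizon, len(T))
            time = np.minimum(T, C)
            event = (T <= C).astype(int)
        out[f"{endpoint}_time"] = time
        out[f"{endpoint}_event"] = event
    return out


@dataclass
class FixtureBundle:
    """Everything one simulated study produces, plus its ground truth."""

    collection: CohortCollection
    methylation: MethylationSim
    survival: pd.DataFrame
    truth: SyntheticTruth
    config: SimulationConfig


def simulate_bundle(config: SimulationConfig) -> FixtureBundle:
    """Run all three generators under one seed and link them."""
    collection, truth = generate_expression_cohorts(config)
    meth = generate_methylation(config)
    # methylation status of the planted region drives survival
    start, end = truth.planted_region_bounds
    region = meth.cpg_map.probe_ids[start : end + 1]
    tumor_cols = meth.beta.samples_in("tumor")
    score = meth.beta.values.loc[region, tumor_cols].mean(axis=0)
    status = (score < 0.5).astype(int).to_numpy()  # hypomethylated -> at risk
    cov = make_covariates(len(tumor_cols), config, status=status)
    cov.index = tumor_cols
    table = generate_survival(cov, config)
    return FixtureBundle(collection=collection, methylation=meth, survival=table, truth=truth, config=config)


def write_fixture_bundle(bundle: FixtureBundle, directory, overwrite: bool = False) -> dict[str, str]:
    """Write the bundle as plain TSV/JSON files with a checksum manifest."""
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not overwrite:
        raise FileExistsError(f"{directory} is not empty (pass overwrite=True)")
    directory.mkdir(parents=True, exist_ok=True)
    files: list[str] = []

    ann_rows = []
    for cohort in bundle.collection.cohorts:
        fname = f"expr_{cohort.name}.tsv"
        write_tsv_matrix(cohort.expression, directory / fname)
        files.append(fname)
        for s in cohort.expression.columns:
            ann_rows.append(
                {"sample": s, "cohort": cohort.name, "histology": cohort.histology, "group": cohort.groups[s]}
            )
    pd.DataFrame(ann_rows).to_csv(directory / "annotation.tsv", sep="\t", index=False)
    files.append("annotation.tsv")
    write_cpg_map(bundle.methylation.cpg_map, directory / "cpg_map_a.tsv")
    write_cpg_map(bundle.methylation.cpg_map_b, directory / "cpg_map_b.tsv")
    write_tsv_matrix(bundle.methylation.beta.values, directory / "beta_a.tsv")
    write_tsv_matrix(bundle.methylation.beta_b.values, directory / "beta_b.tsv")
    bundle.methylation.beta.groups.rename("group").to_csv(directory / "meth_groups.tsv", sep="\t")
    bundle.methylation.coupled_expression.rename("expression").to_csv(
        directory / "coupled_expression.tsv", sep="\t"
    )
    bundle.survival.to_csv(directory / "survival.tsv", sep="\t", na_rep=".")
    files += [
        "cpg_map_a.tsv", "cpg_map_b.tsv", "beta_a.tsv", "beta_b.tsv",
        "meth_groups.tsv", "coupled_expression.tsv", "survival.tsv",
    ]
    truth = bundle.truth
    (directory / "truth.json").write_text(
        json.dumps(
            {
                "planted_gene_ids": truth.planted_gene_ids,
                "planted_region_bounds": list(truth.planted_region_bounds),
                "true_coupling": truth.true_coupling,
                "true_log_hr": truth.true_log_hr,
                "rng_seed": truth.rng_seed,
            },
            indent=1,
        )
    )
    files.append("truth.json")
    checksums = {f: sha256_file(directory / f) for f in sorted(files)}
    with open(directory / "MANIFEST.txt", "w") as fh:
        for f, digest in checksums.items():
            fh.write(f"{f}={digest}\n")
    return checksums


def load_fixture_bundle(directory) -> FixtureBundle:
    """Round-trip a written bundle, verifying every manifest checksum."""
    directory = Path(directory)
    manifest = {}
    for line in (directory / "MANIFEST.txt").read_text().splitlines():
        if line.strip():
            name, digest = line.split("=", 1)
            manifest[name] = digest
    for name, digest in manifest.items():
        actual = sha256_file(directory / name)
        if actual != digest:
            raise ValueError(f"checksum mismatch for {name}: bundle corrupted or tampered")
    ann = pd.read_csv(directory / "annotation.tsv", sep="\t")
    cohorts = []
    for name, sub in ann.groupby("cohort", sort=False):
        expr = read_tsv_matrix(directory / f"expr_{name}.tsv")
        groups = pd.Series(sub["group"].to_numpy(), index=sub["sample"].to_numpy())
        cohorts.append(
            Cohort(name=name, histology=sub["histology"].iloc[0], expression=expr, groups=groups)
        )
    meth_groups = pd.read_csv(directory / "meth_groups.tsv", sep="\t", index_col=0)["group"]
    map_a = load_cpg_map(directory / "cpg_map_a.tsv")
    map_b = load_cpg_map(directory / "cpg_map_b.tsv")
    beta_a = BetaMatrix(read_tsv_matrix(directory / "beta_a.tsv"), meth_groups)
    beta_b = BetaMatrix(read_tsv_matrix(directory / "beta_b.tsv"), meth_groups)
    coupled = pd.read_csv(directory / "coupled_expression.tsv", sep="\t", index_col=0)["expression"]
    survival = pd.read_csv(directory / "survival.tsv", sep="\t", index_col=0, na_values=["."])
    raw = json.loads((directory / "truth.json").read_text())
    truth = SyntheticTruth(
        planted_gene_ids=raw["planted_gene_ids"],
        planted_region_bounds=tuple(raw["planted_region_bounds"]),
        true_coupling=raw["true_coupling"],
        true_log_hr=raw["true_log_hr"],
        rng_seed=raw["rng_seed"],
    )
    meth = MethylationSim(
        cpg_map=map_a, beta=beta_a, cpg_map_b=map_b, beta_b=beta_b,
        coupled_expression=coupled, truth=truth,
    )
    config = SimulationConfig(rng_seed=truth.rng_seed)
    return FixtureBundle(
        collection=CohortCollection(cohorts), methylation=meth, survival=survival,
        truth=truth, config=config,
    )
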