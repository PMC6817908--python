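"""Configuration objects for the synthetic study and the end-to-end pipeline."""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml


@dataclass
class SimulationConfig:
    """Parameters of the planted-truth multi-omics simulation.

    The generator emulates the statistical structure of a two-histology
    lung-cancer study: several expression cohorts per histology with a
    seed-gene co-expression module, an ordered promoter CpG map
    (north shore / island / south shore) with tumor-restricted shore
    hypomethylation, inverse methylation->expression coupling,
    cross-promoter co-methylation, and proportional-hazards survival.

    Units: ``de_effect`` is a log2-expression shift in units of the per-gene
    SD; ``delta_meth`` is in percentage points of methylation;
    ``hazard_log_hr`` and ``confounder_effects`` are log hazard ratios;
    times are months.
    """

    n_cohorts_per_histology: int = 3
    n_samples_tumor: int = 100
    n_samples_normal: int = 50
    n_genes: int = 2000
    module_size: int = 30
    target_module_r: float = 0.5
    de_effect: float = 1.5
    n_cpgs_island: int = 20
    n_cpgs_shore: int = 20          # per shore (north and south)
    planted_region: tuple[int, int] = (5, 5)   # (start index within north shore, run length)
    delta_meth: float = 20.0        # percentage points, tumor hypomethylation
    coupling_rho: float = -0.5
    comethylation_rho: float = 0.8
    hazard_log_hr: float = math.log(2.0)
    confounder_effects: dict[str, float] = field(
        default_factory=lambda: {"age": 0.02, "sex": 0.2, "smoking": 0.4}
    )
    censoring_rate: float = 0.4
    rng_seed: int = 0

    # baseline methylation levels and logit-scale noise; chosen so that beta
    # stays strictly inside (0,1) and shore/island contrast mirrors a typical
    # promoter profile (unmethylated island, methylated shores in normal lung)
    island_beta: float = 0.08
    shore_beta_normal: float = 0.65
    probe_logit_sd: float = 0.35
    sample_latent_sd: float = 0.35

    def validate(self) -> None:
        counts = dict(
            n_cohorts_per_histology=self.n_cohorts_per_histology,
            n_samples_tumor=self.n_samples_tumor,
            n_samples_normal=self.n_samples_normal,
            n_genes=self.n_genes,
            module_size=self.module_size,
            n_cpgs_island=self.n_cpgs_island,
            n_cpgs_shore=self.n_cpgs_shore,
        )
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise ValueError(f"{name} must be an integer >= 1, got {value!r}")
        if self.module_size >= self.n_genes:
            raise ValueError("module larger than genome")
        if not 0 <= self.target_module_r < 1:
            raise ValueError("target_module_r must lie in [0,1)")
        if not -1 < self.coupling_rho <= 0:
            raise ValueError("coupling_rho must lie in (-1, 0]")
        if not 0 <= self.comethylation_rho < 1:
            raise ValueError("comethylation_rho must lie in [0, 1)")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must lie in [0, 1)")
        start, length = self.planted_region
        if start < 0 or length < 1 or start + length > self.n_cpgs_shore:
            raise ValueError("planted_region must lie entirely within the north shore")
        if not 0 < self.island_beta < 1 or not 0 < self.shore_beta_normal < 1:
            raise ValueError("baseline beta levels must lie in (0,1)")
        if self.shore_beta_normal - self.delta_meth / 100.0 <= 0:
            raise ValueError(
                "delta_meth drives tumor beta out of (0,1): "
                f"shore baseline {self.shore_beta_normal} minus {self.delta_meth}pp"
            )

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    Exactly one data source per layer: either a synthetic block
    (``simulation``) or input paths.  Thresholds default to the values used
    throughout the package and are all recorded in the run log.
    """

    simulation: Optional[SimulationConfig] = None
    expression_dir: Optional[Path] = None
    methylation_dir: Optional[Path] = None
    seed_gene: str = "SEED"
    correlation_method: str = "pearson"
    consensus_alpha: float = 0.05
    require_sign: str = "positive"
    de_alpha: float = 0.05
    min_run: int = 5
    min_delta_pp: float = 5.0
    q_max: float = 0.05
    beta_threshold: float = 0.5
    dichotomize_rule: str = "median"
    elastic_net_mixing: float = 0.5
    cv_folds: int = 10
    bootstrap_replicates: int = 200
    output_dir: Path = Path("results/pipeline")
    seed: int = 0
    verbosity: int = 1

    def validate(self) -> None:
        synthetic = self.simulation is not None
        paths = self.expression_dir is not None or self.methylation_dir is not None
        if synthetic and paths:
            raise ValueError("configure either a synthesis block or input paths, not both")
        if not synthetic and not paths:
            raise ValueError("no data source configured")
        for name in ("consensus_alpha", "de_alpha", "q_max"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0,1], got {v}")
        if not 0 <= self.beta_threshold <= 1:
            raise ValueError("beta_threshold must lie in [0,1]")
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")
        if not 0 <= self.elastic_net_mixing <= 1:
            raise ValueError("elastic_net_mixing must lie in [0,1]")
        if self.require_sign not in ("positive", "negative", "any"):
            raise ValueError("require_sign must be positive|negative|any")
        if self.simulation is not None:
            self.simulation.validate()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**{k: v for k, v in raw.items() if k != "simulation"})
        if sim is not None:
            if "planted_region" in sim:
                sim["planted_region"] = tuple(sim["planted_region"])
            cfg.simulation = SimulationConfig(**sim)
        for name in ("expression_dir", "methylation_dir", "output_dir"):
            v = getattr(cfg, name)
            if v is not None:
                setattr(cfg, name, Path(v))
        cfg.validate()
        return cfg

    def thresholds(self) -> dict:
        """Every threshold that can fire during a run, for the audit log."""
        return {
            "seed_gene": self.seed_gene,
            "correlation_method": self.correlation_method,
            "consensus_alpha": self.consensus_alpha,
            "require_sign": self.require_sign,
            "de_alpha": self.de_alpha,
            "min_run": self.min_run,
            "min_delta_pp": self.min_delta_pp,
            "q_max": self.q_max,
            "beta_threshold": self.beta_threshold,
            "dichotomize_rule": self.dichotomize_rule,
            "elastic_net_mixing": self.elastic_net_mixing,
            "cv_folds": self.cv_folds,
            "bootstrap_replicates": self.bootstrap_replicates,
            "seed": self.seed,
        }
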