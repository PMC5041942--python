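"""Configuration objects for the simulator and the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Tuple

import yaml

from mircross.errors import ConfigError


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic data generator.

    Defaults emulate a three-grade glioma cohort (63 / 33 / 64 samples in
    grades II / III / IV) with differential signal, negative miRNA-target
    coupling, pathway enrichment, inter-pathway PPI density and a two-group
    hazard difference all planted.  Expression is generated directly on log
    scale; upstream normalization is assumed done.
    """

    n_samples_per_grade: Tuple[int, int, int] = (63, 33, 64)
    n_mirnas: int = 150
    n_genes: int = 600
    #: planted differential features per grade contrast (III vs II, IV vs II)
    n_diff_mirnas: int = 30
    n_diff_genes: int = 180
    #: planted miRNA->target couples per differential miRNA
    n_targets_per_mirna: int = 3
    #: planted miRNAs sharing one pathway home (controls how concentrated
    #: pathway-level enrichment is: m = mirnas_per_pathway * n_targets_per_mirna)
    mirnas_per_pathway: int = 3
    #: mean shift, log2 expression units, in case grade vs grade II
    effect_size: float = 2.0
    #: regression slope of a planted target on its miRNA (must be negative)
    coupling_beta: float = -0.8
    #: residual standard deviation, log2 units
    noise_sd: float = 0.5
    n_pathways: int = 30
    pathway_size: int = 40
    #: pathway sets may share genes (required when size*n exceeds n_genes)
    allow_pathway_overlap: bool = True
    #: pathway pairs given dense inter-pathway PPI edges among planted
    #: differential genes (density 5x baseline)
    n_planted_crosstalk_pairs: int = 5
    baseline_ppi_density: float = 0.05
    #: between-group hazard ratio of the planted risk split
    hazard_ratio: float = 3.0
    #: target fraction of censored samples
    censoring_rate: float = 0.2
    #: median survival of the low-risk group, months
    baseline_median_survival: float = 30.0
    #: log2-unit loading of the risk factor on planted differential miRNAs
    risk_factor_loading: float = 1.0
    #: ratio of decoy (non-planted) to planted target pairs
    decoy_pair_ratio: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        c = self
        if len(c.n_samples_per_grade) != 3 or any(n < 2 for n in c.n_samples_per_grade):
            raise ConfigError("n_samples_per_grade must be three integers >= 2")
        if 2 * c.n_diff_mirnas > c.n_mirnas:
            raise ConfigError("planted differential miRNAs (both contrasts) exceed n_mirnas")
        if 2 * c.n_diff_genes > c.n_genes:
            raise ConfigError("planted differential genes (both contrasts) exceed n_genes")
        if c.n_targets_per_mirna * c.n_diff_mirnas > c.n_diff_genes:
            raise ConfigError("coupled target genes exceed n_diff_genes")
        if c.coupling_beta >= 0:
            raise ConfigError("coupling_beta must be negative")
        if c.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        if not (0 <= c.censoring_rate < 1):
            raise ConfigError("censoring_rate must lie in [0, 1)")
        if c.hazard_ratio <= 0:
            raise ConfigError("hazard_ratio must be positive")
        if not (0 <= c.baseline_ppi_density <= 1):
            raise ConfigError("baseline_ppi_density must be a probability")
        if c.pathway_size > c.n_genes:
            raise ConfigError("pathway_size exceeds n_genes")
        if (c.pathway_size * c.n_pathways > c.n_genes) and not c.allow_pathway_overlap:
            raise ConfigError(
                "pathway_size * n_pathways exceeds n_genes; set allow_pathway_overlap"
            )
        if 2 * c.n_planted_crosstalk_pairs > c.n_pathways:
            raise ConfigError("not enough pathways for disjoint planted crosstalk pairs")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["n_samples_per_grade"] = list(self.n_samples_per_grade)
        return d


def null_config(seed: int = 0) -> SyntheticConfig:
    """Configuration with no planted structure of any kind.

    Every downstream p-value should be approximately uniform on such data.
    """
    return SyntheticConfig(
        effect_size=0.0,
        coupling_beta=-1e-9,
        n_planted_crosstalk_pairs=0,
        hazard_ratio=1.0,
        risk_factor_loading=0.0,
        seed=seed,
    )


@dataclass
class PipelineConfig:
    """Thresholds, sizes and paths shared by every pipeline stage.

    Precedence when running the CLI is command line > config file > these
    defaults.  All thresholds are the study's printed operating points:
    FDR < 5%, inverse-correlation cutoff -0.4 at p < 0.05, enrichment and
    crosstalk thresholds 0.05, PPI combined score >= 900, hub fraction 15%.
    """

    outdir: str = "results/pipeline"
    seed: int = 0
    # stage: differential calling
    alpha: float = 0.05
    t_variant: str = "student"
    # stage: signature pairs
    correlation_cutoff: float = -0.4
    correlation_p_max: float = 0.05
    correlation_samples: str = "per_contrast"  # or "all"
    # stage: miRNA-pathway network
    enrichment_threshold: float = 0.05
    enrichment_tail: str = "ge"
    universe: str = "annotated"  # or "measured"
    hub_fraction: float = 0.15
    # stage: pathway crosstalk
    ppi_min_score: int = 900
    permutations: int = 1000
    crosstalk_threshold: float = 0.05
    log_floor: float = 1e-300
    randomization: str = "joint"  # or "single"
    # stage: modules
    clique_k: int = 3
    min_biclique_mirnas: int = 1
    min_biclique_pathways: int = 1
    # stage: survival
    survival_mode: str = "combined"  # combined | genes | mirnas
    kmeans_restarts: int = 10
    # simulation stage
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    def validate(self) -> None:
        for name in ("alpha", "correlation_p_max", "enrichment_threshold",
                     "crosstalk_threshold"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.permutations < 1:
            raise ConfigError("permutations must be >= 1")
        if self.clique_k < 3:
            raise ConfigError("clique_k must be >= 3")
        if not (0 < self.hub_fraction <= 1):
            raise ConfigError("hub_fraction must lie in (0, 1]")
        if self.t_variant not in ("student", "welch"):
            raise ConfigError("t_variant must be 'student' or 'welch'")
        if self.correlation_samples not in ("per_contrast", "all"):
            raise ConfigError("correlation_samples must be 'per_contrast' or 'all'")
        if self.enrichment_tail not in ("ge", "gt"):
            raise ConfigError("enrichment_tail must be 'ge' or 'gt'")
        if self.survival_mode not in ("combined", "genes", "mirnas"):
            raise ConfigError("survival_mode must be combined, genes or mirnas")
        self.synthetic.validate()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["synthetic"] = self.synthetic.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        syn = d.pop("synthetic", {})
        if isinstance(syn, SyntheticConfig):
            syn_cfg = syn
        else:
            syn = dict(syn)
            if "n_samples_per_grade" in syn:
                syn["n_samples_per_grade"] = tuple(syn["n_samples_per_grade"])
            syn_cfg = SyntheticConfig(**syn)
        known = {f for f in cls.__dataclass_fields__ if f != "synthetic"}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(synthetic=syn_cfg, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"configuration file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
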