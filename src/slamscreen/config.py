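"""Pipeline configuration: a flat YAML file mirrored by CLI flags."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Optional

import yaml


class ConfigError(ValueError):
    """Invalid configuration value or file (CLI exit code 2)."""


@dataclass
class PipelineConfig:
    # paths
    outdir: str = "slamscreen_out"
    bam: Optional[str] = None
    control_bam: Optional[str] = None
    gtf: Optional[str] = None
    whitelist: Optional[str] = None
    sgrna_table: Optional[str] = None
    sgrna_fastq: Optional[str] = None
    snp_mask: Optional[str] = None
    mito_contig: str = "chrM"

    # read filtering / nascent calling
    mapq_min: int = 30
    min_base_quality: int = 45  # strict >; lower on platforms capped at 40
    min_tc_fraction: float = 0.30
    snp_min_coverage: int = 10
    snp_min_alt_fraction: float = 0.5

    # cell QC
    min_umis: int = 300
    min_genes: int = 200
    min_sgrna_umis: int = 10
    max_unannotated_fraction: float = 0.40

    # singlet calling
    singlet_top_fraction: float = 0.60
    singlet_fold: float = 3.0
    sgrna_min_total_umis: int = 10

    # knockdown filtering
    knockdown_min_reduction: float = 0.40
    min_cells_per_target: int = 50

    # kinetics & statistics
    labeling_time: float = 2.0
    n_iter: int = 500
    fdr_threshold: float = 0.05
    top_k_genes: int = 1000
    n_bins: int = 10
    top_fraction: float = 0.03
    deg_min_fc: float = 1.5

    # simulation (used by the `simulate` stage)
    sim_n_genes: int = 300
    sim_n_mito_genes: int = 8
    sim_n_cells: int = 2000
    sim_n_targets: int = 5
    sim_sgrnas_per_gene: int = 3
    sim_n_ntc: int = 5
    sim_knockdown_effect: float = 0.7
    sim_doublet_rate: float = 0.05
    sim_p_conversion: float = 0.05
    sim_p_error: float = 0.001
    sim_n_snps: int = 50
    sim_ambient_sgrna_rate: float = 0.2
    sim_mean_sgrna_umis: float = 30.0
    sim_read_level: bool = False
    sim_dispersion: Optional[float] = None

    seed: int = 0

    def validate(self) -> "PipelineConfig":
        checks = [
            (0 <= self.min_tc_fraction <= 1, "min_tc_fraction in [0,1]"),
            (0 <= self.max_unannotated_fraction <= 1,
             "max_unannotated_fraction in [0,1]"),
            (0 < self.singlet_top_fraction <= 1,
             "singlet_top_fraction in (0,1]"),
            (self.singlet_fold >= 1, "singlet_fold >= 1"),
            (0 <= self.knockdown_min_reduction <= 1,
             "knockdown_min_reduction in [0,1]"),
            (self.labeling_time > 0, "labeling_time > 0"),
            (self.n_iter >= 1, "n_iter >= 1"),
            (0 < self.fdr_threshold < 1, "fdr_threshold in (0,1)"),
            (0 < self.top_fraction <= 1, "top_fraction in (0,1]"),
            (self.mapq_min >= 0, "mapq_min >= 0"),
            (0 <= self.sim_p_conversion <= 1, "sim_p_conversion in [0,1]"),
            (0 <= self.sim_p_error <= 1, "sim_p_error in [0,1]"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(f"configuration violates: {msg}")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        try:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
        except OSError as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        if not isinstance(data, dict):
            raise ConfigError("config file must be a flat mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data).validate()

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def updated(self, **overrides) -> "PipelineConfig":
        data = asdict(self)
        for k, v in overrides.items():
            if v is not None:
                if k not in data:
                    raise ConfigError(f"unknown config key: {k}")
                data[k] = v
        return PipelineConfig(**data).validate()
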