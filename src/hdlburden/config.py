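"""Pipeline configuration.

All tunable thresholds of the analysis live in one declarative object so a run
is fully described by a config file plus a seed.  Defaults are the cutoffs of
the analysis protocol: 10th-percentile isopleth selection; gnomAD MAF 0.01 for
heterozygous / 0.05 for homozygous candidate-branch inclusion; burden-branch
rare thresholds 1e-5 / 1e-4 / 1e-3; removal of variants carried by more than
40% of samples; 80th/50th damaging-percentile class boundaries; alpha 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml


@dataclass
class PipelineConfig:
    selection_quantile: float = 0.10
    het_maf_cutoff: float = 0.01
    hom_maf_cutoff: float = 0.05
    burden_maf_thresholds: tuple[float, ...] = (1e-5, 1e-4, 1e-3)
    platform_share_cutoff: float = 0.40
    damaging_upper_percentile: float = 0.80
    damaging_lower_percentile: float = 0.50
    alpha: float = 0.05
    seed: int = 0
    gene_list_path: Optional[str] = None
    rate_table_path: Optional[str] = None
    gene_sets_path: Optional[str] = None

    def __post_init__(self) -> None:
        fractions = {
            "selection_quantile": self.selection_quantile,
            "het_maf_cutoff": self.het_maf_cutoff,
            "hom_maf_cutoff": self.hom_maf_cutoff,
            "platform_share_cutoff": self.platform_share_cutoff,
            "damaging_upper_percentile": self.damaging_upper_percentile,
            "damaging_lower_percentile": self.damaging_lower_percentile,
            "alpha": self.alpha,
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {value}")
        if not 0.0 < self.damaging_lower_percentile < self.damaging_upper_percentile < 1.0:
            raise ValueError(
                "need 0 < lower percentile < upper percentile < 1, got "
                f"{self.damaging_lower_percentile} / {self.damaging_upper_percentile}"
            )
        thresholds = tuple(self.burden_maf_thresholds)
        if any(not 0.0 <= t <= 1.0 for t in thresholds):
            raise ValueError("burden MAF thresholds must be fractions in [0,1]")
        if list(thresholds) != sorted(thresholds):
            raise ValueError("burden MAF thresholds must be sorted ascending")
        self.burden_maf_thresholds = thresholds

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "burden_maf_thresholds" in data:
            data["burden_maf_thresholds"] = tuple(data["burden_maf_thresholds"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["burden_maf_thresholds"] = list(self.burden_maf_thresholds)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
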