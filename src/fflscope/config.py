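"""Run configuration: every pipeline threshold in one validated object.

Defaults are the study's stated cutoffs: mRNA DEGs at adjusted p < 0.05 and
|log2FC| >= 1, miRNA DEGs at adjusted p < 0.1 and |log2FC| >= 0.58, PPI
interaction score strictly > 0.4, TF-prediction NES strictly > 5.0, miRNA
predictions supported by >= 2 tools, correlation validation at alpha 0.05,
ssGSEA exponent 0.25, and an optimal-cutpoint minimum group proportion 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import yaml


@dataclass
class RunConfig:
    # differential expression
    mrna_p_cut: float = 0.05
    mrna_lfc_cut: float = 1.0
    mirna_p_cut: float = 0.1
    mirna_lfc_cut: float = 0.58
    batch_center: bool = False
    # PPI / hub ranking
    ppi_min_score: float = 0.4
    top_k_hubs: int = 15
    mcode_vwp: float = 0.2
    mcode_haircut: bool = True
    mcode_fluff: bool = False
    mcode_min_size: int = 3
    # regulatory network
    nes_min: float = 5.0
    min_tools: int = 2
    corr_alpha: float = 0.05
    tumor_only_correlation: bool = True
    # scoring
    ssgsea_alpha: float = 0.25
    ssgsea_normalize: bool = True
    # survival
    cutpoint_minprop: float = 0.1
    # reproducibility / paths
    seed: int = 0
    input_dir: str = "."

    def __post_init__(self) -> None:
        checks = {
            "mrna_p_cut": (0.0, 1.0),
            "mirna_p_cut": (0.0, 1.0),
            "corr_alpha": (0.0, 1.0),
            "ppi_min_score": (0.0, 1.0),
            "mcode_vwp": (0.0, 1.0),
            "cutpoint_minprop": (0.0, 0.5),
            "ssgsea_alpha": (0.0, 2.0),
        }
        for name, (lo, hi) in checks.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        for name in ("mrna_lfc_cut", "mirna_lfc_cut", "nes_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.min_tools < 1 or self.top_k_hubs < 1 or self.mcode_min_size < 2:
            raise ValueError("count thresholds out of range")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls(**d)
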