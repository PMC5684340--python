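"""Declarative pipeline configuration with the analysis defaults.

Every numeric default is the published analysis value: 2-of-4 peak support,
+-1000 bp promoter windows, |log2 fc| >= 1 at BH q < 0.05 with a <= 1.05-fold
background band, 1.5/1.1 de-novo enrichment thresholds, 12.5 kb stitching,
SE fold-change cutoffs 2.0/0.5, +-250 kb and +-50 kb gene-assignment windows,
a 100 A.U. expression floor, coverage >= 10 with fold >= 1.5 for DE genes,
and 10,000 permutation simulations. The config round-trips losslessly
through YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

__all__ = ["PipelineConfig", "PAPER_DEFAULTS"]

PAPER_DEFAULTS = {
    "min_support": 2,
    "promoter_flank": 1000,
    "logfc_threshold": 1.0,
    "q_threshold": 0.05,
    "background_band": 1.05,
    "de_novo_hi": 1.5,
    "de_novo_lo": 1.1,
    "stitch_gap": 12_500,
    "se_gained_fc": 2.0,
    "se_lost_fc": 0.5,
    "window_enhancer_gene": 250_000,
    "window_nearest_gene": 50_000,
    "expression_floor": 100.0,
    "de_min_coverage": 10.0,
    "de_min_fc": 1.5,
    "n_sims": 10_000,
}


@dataclass
class PipelineConfig:
    # thresholds (defaults = published analysis values)
    min_support: int = 2
    promoter_flank: int = 1000
    logfc_threshold: float = 1.0
    q_threshold: float = 0.05
    background_band: float = 1.05
    de_novo_hi: float = 1.5
    de_novo_lo: float = 1.1
    de_novo_scale: str = "log2"
    stitch_gap: int = 12_500
    se_gained_fc: float = 2.0
    se_lost_fc: float = 0.5
    se_epsilon: float = 0.1
    window_enhancer_gene: int = 250_000
    window_nearest_gene: int = 50_000
    expression_floor: float = 100.0
    de_min_coverage: float = 10.0
    de_min_fc: float = 1.5
    n_sims: int = 10_000
    seed: int = 0
    # simulation block passed through to SimulationConfig (simulate/all)
    simulation: dict = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
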