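"""Run configuration: thresholds, caps and seeds, serialisable to YAML."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .io import ConfigurationError


@dataclass
class RunConfig:
    """Defaults mirror the framework's shipped thresholds.

    QC keeps cells with at least 1% of the median library size; biological
    signal uses BH-adjusted p < 0.1, |log2FC| > 1, expressed at log2
    expression > 1 and bimodality index > 0.03; data are split 50/50;
    log2-CPM uses pseudocount 1; neighbourhood measures use k = 5 at a 5%
    significance level.
    """

    qc_min_fraction: float = 0.01
    split_fraction: float = 0.5
    pseudocount: float = 1.0
    bh_alpha: float = 0.1
    logfc_threshold: float = 1.0
    expr_threshold: float = 1.0
    bi_cutoff: float = 0.03
    knn_k: int = 5
    nn_alpha: float = 0.05
    correlation_subsample: int = 500
    kde_subsample: int = 5000
    seed: int = 0
    measures: list[str] = field(default_factory=lambda: ["kde"])

    def validate(self) -> None:
        if not 0 <= self.qc_min_fraction < 1:
            raise ConfigurationError("qc_min_fraction must be in [0, 1)")
        if not 0 < self.bh_alpha <= 1:
            raise ConfigurationError("bh_alpha must be in (0, 1]")
        if self.knn_k <= 0 or self.correlation_subsample <= 0:
            raise ConfigurationError("k and subsample caps must be positive")
        if not 0 <= self.nn_alpha <= 1:
            raise ConfigurationError("nn_alpha must be in [0, 1]")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg
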