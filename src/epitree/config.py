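"""Pipeline configuration: every tunable threshold in one place.

Defaults are the standard values for this analysis: HWE p < 1e-4, MAF
0.01, call rate 0.98, sample genotyping rate 0.98, association candidate
threshold p < 0.0005, backward-elimination step of 50 SNPs, LD r^2
threshold 0.4, 3-fold cross-validation, 1,000 permutation networks, and
Laplace pseudocount 1.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, fields

import yaml

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    hwe: float = 1e-4
    maf: float = 0.01
    call_rate: float = 0.98
    sample_rate: float = 0.98
    p_threshold: float = 5e-4
    step: int = 50
    r2: float = 0.4
    k_folds: int = 3
    B: int = 1000
    alpha: float = 1.0
    n_bins: int = 4
    seed: int = 0
    strata: str = "race"
    always_include: list[str] = field(default_factory=lambda: ["race", "sex"])
    use_prior: bool = False
    sig_level: float = 0.05
    background: str = "candidates"  # or "post_qc"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def log_resolved(self) -> None:
        log.info("resolved config: %s", asdict(self))
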