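"""Structured configuration for the end-to-end simulation study."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .simulate import GenerativeConfig


@dataclass
class StudyConfig:
    """Everything needed to run the simulation study end to end.

    ``mode`` selects the bin-variance stage: ``chi2`` regresses simulated
    GWAS chi-square statistics on bin annotations (the end-to-end
    regime); ``oracle`` averages true squared effects over all SNPs per
    bin; ``oracle_causal_threshold`` averages true squared effects over
    causal SNPs only and thresholds per-SNP pmix at the generative
    plateau during inference (the regime in which the estimator is
    unbiased).
    """

    generative: GenerativeConfig = field(default_factory=GenerativeConfig)
    true_w_values: tuple[float, ...] = (0.0, 0.95, 1.0)
    n_replicates: int = 10
    mode: str = "chi2"
    n_common_bins: int = 10
    de_popsize: int = 30
    de_maxiter: int = 200
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.generative, dict):
            self.generative = GenerativeConfig(**self.generative)
        self.true_w_values = tuple(float(w) for w in self.true_w_values)
        if self.mode not in ("chi2", "oracle", "oracle_causal_threshold"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        # generative invariants are validated by GenerativeConfig itself

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "StudyConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(**payload)
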