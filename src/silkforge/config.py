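"""Run configuration: stage seeds, thresholds, and paths, with validation
and lossless JSON round-tripping."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path


@dataclass
class RunConfig:
    # simulation
    family: str = "MaSp4"
    n_repeats: int = 12
    repeat_len_aa: int = 40
    short_coverage: float = 50.0
    short_read_len: int = 150
    short_err_rate: float = 0.0
    long_coverage: float = 15.0
    long_mean_len: int = 5000
    long_err_rate: float = 0.08
    # assembly
    k: int = 31
    min_count: int = 2
    min_seed_score: float = 100.0
    anchor_k: int = 51
    min_depth: int = 5
    min_frac: float = 0.8
    max_extension: int = 20000
    boundary_window: int = 300
    boundary_period_max: int = 150
    # long-read confirmation
    correction_k: int = 17
    correction_min_count: int = 2
    map_seed_k: int = 15
    min_identity: float = 0.7
    # catalogue / phylo / profiling
    crp_threshold: float = 0.05
    bootstrap_B: int = 50
    # seeds per stage
    seeds: dict = field(default_factory=lambda: {
        "gene": 11, "short": 2, "long": 3, "bootstrap": 5})
    # optional external inputs for the profile stage
    counts_a: str | None = None
    counts_b: str | None = None
    lengths: str | None = None
    out_dir: str = "forge_out"

    def validate(self) -> None:
        checks = [
            (self.n_repeats >= 0, "n_repeats must be >= 0"),
            (self.repeat_len_aa > 0, "repeat_len_aa must be > 0"),
            (self.short_coverage > 0, "short_coverage must be > 0"),
            (self.short_read_len > 0, "short_read_len must be > 0"),
            (0 <= self.short_err_rate <= 1, "short_err_rate must be in [0,1]"),
            (0 <= self.long_err_rate <= 1, "long_err_rate must be in [0,1]"),
            (self.long_mean_len >= 500, "long_mean_len must be >= 500"),
            (self.k % 2 == 1 and self.k > 0, "k must be odd and positive"),
            (self.min_count >= 1, "min_count must be >= 1"),
            (self.anchor_k >= 1, "anchor_k must be >= 1"),
            (self.min_depth >= 1, "min_depth must be >= 1"),
            (0.5 < self.min_frac <= 1.0, "min_frac must be in (0.5, 1]"),
            (self.boundary_window >= 2 * self.boundary_period_max,
             "boundary_window must be >= 2 * boundary_period_max"),
            (0 <= self.min_identity <= 1, "min_identity must be in [0,1]"),
            (0 < self.crp_threshold < 1, "crp_threshold must be in (0,1)"),
            (self.bootstrap_B >= 1, "bootstrap_B must be >= 1"),
        ]
        errors = [msg for ok, msg in checks if not ok]
        if errors:
            raise ValueError("invalid configuration: " + "; ".join(errors))

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_json(Path(path).read_text())
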