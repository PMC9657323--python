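"""Run configuration.

A single flat key/value file (YAML subset) drives the CLI; precedence is
CLI flag > config file > defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from pathlib import Path

import yaml


@dataclass(frozen=True)
class AnalysisConfig:
    """Analysis-wide tunables.

    Parameters
    ----------
    season_length_days:
        Days per (warm or cold) season used to scale day-level emissions to
        seasonal cumulative totals.
    permutations:
        Number of label permutations for PERMANOVA / Mantel / forward
        selection p-values.
    rng_seed:
        Top-level seed; each module draws from an independent child stream.
    rarefaction_fraction:
        Rarefaction target depth as a fraction of the minimum sample depth.
    alpha:
        Significance level for multiple-range tests and variable selection.
    qc_r2_min:
        Minimum linear-fit R-squared for a chamber session to pass QC.
    """

    season_length_days: int = 180
    permutations: int = 999
    rng_seed: int = 0
    rarefaction_fraction: float = 0.95
    alpha: float = 0.05
    qc_r2_min: float = 0.9

    def __post_init__(self) -> None:
        if self.permutations < 1:
            raise ValueError("permutations must be >= 1")
        if not 0 < self.rarefaction_fraction <= 1:
            raise ValueError("rarefaction_fraction must be in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.season_length_days < 1:
            raise ValueError("season_length_days must be positive")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        """Load from a key: value file; keyword overrides win over the file."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain key: value pairs")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(
                f"unknown config keys {sorted(unknown)}; valid keys: {sorted(known)}"
            )
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def with_overrides(self, **overrides) -> "AnalysisConfig":
        return replace(self, **{k: v for k, v in overrides.items() if v is not None})
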