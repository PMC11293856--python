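"""Run configuration with provenance-friendly TOML round-tripping.

Every default is either a field-standard preprocessing constant
(occurrence floor, multiplicative-replacement factor, FDR level, the 2.5-97.5
percentile projection envelope, the silhouette scan range, the 10% neutral
band, the 30% persistence floor) or a documented package choice; resolved
configs are archived beside run outputs so any result can be traced back to
its parameters.
"""

from __future__ import annotations

import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    min_occurrence: int = 10
    impute_factor: float = 0.65
    fdr_level: float = 0.01
    n_boot: int = 100
    learner: str = "random_forest"
    n_estimators: int = 500
    cv_folds: int = 5
    performance_floor: float = 0.5  # balanced accuracy floor for retained cADMs
    r2_floor: float = 0.0  # R^2 floor for retained rADMs
    mask_q_lo: float = 2.5
    mask_q_hi: float = 97.5
    k_min: int = 2
    k_max: int = 15
    band_fraction: float = 0.10
    band_mode: str = "max_fraction"
    min_copresence: float = 0.30
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def to_toml(self, path) -> None:
        lines = []
        for key, value in asdict(self).items():
            if key == "paths":
                continue
            if isinstance(value, str):
                lines.append(f'{key} = "{value}"')
            elif isinstance(value, bool):
                lines.append(f"{key} = {str(value).lower()}")
            else:
                lines.append(f"{key} = {value}")
        if self.paths:
            lines.append("")
            lines.append("[paths]")
            for key, value in self.paths.items():
                lines.append(f'{key} = "{value}"')
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        return cls(**data)
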