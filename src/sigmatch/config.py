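"""Pipeline configuration: defaults, YAML overrides, validation."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional, Sequence, Union

import yaml


@dataclass
class PipelineConfig:
    """Tunable knobs of the full pipeline.

    ``threshold_grid`` — DEG thresholds swept by the cross-validation.
    ``z_cap`` — consensus magnitude used when >= 2 sample z-scores agree
    exactly.  ``sd_tolerance`` — below this, a standard deviation counts as
    zero.  ``target_down`` — drop disruption samples whose target did not
    decrease.  ``source_filter`` / ``species`` — restrict samples to one
    read-count source or species (None = mix everything, the default).
    ``bonferroni_m`` — hypothesis count for p-value adjustment (72: the
    number of signature-based predictor configurations evaluated).
    ``predictor_priority`` — deterministic tie order for the ensemble.
    """

    threshold_grid: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(10))
    z_cap: float = 10.0
    sd_tolerance: float = 1e-8
    target_down: bool = False
    source_filter: Optional[str] = None
    species: Optional[str] = None
    bonferroni_m: int = 72
    seed: int = 0
    predictor_priority: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        grid = tuple(float(t) for t in self.threshold_grid)
        if list(grid) != sorted(grid):
            raise ValueError("threshold grid must be sorted")
        if grid and not (0.0 <= grid[0] and grid[-1] < 1.0):
            raise ValueError("threshold grid must lie within [0, 1)")
        object.__setattr__(self, "threshold_grid", grid)
        if self.bonferroni_m < 1:
            raise ValueError("bonferroni_m must be >= 1")


def load_config(path: Union[str, Path, None] = None, **overrides) -> PipelineConfig:
    """Build a config from defaults, an optional YAML file, and overrides."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a YAML mapping")
        known = {f.name for f in fields(PipelineConfig)}
        unknown = set(loaded) - known
        if unknown:
            raise ValueError(f"{path}: unknown config key(s): {sorted(unknown)}")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig(**data)
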