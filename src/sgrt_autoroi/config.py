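"""YAML run configuration with validated, protocol-derived defaults.

An empty file (or missing section) yields the full defaults; unknown keys
are rejected by name.  One global seed fans out to per-stage seeds through
a stable hash so stages are reproducible yet statistically independent.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Optional, Tuple

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .errors import InvalidInputError, InvalidParameterError
from .roi import ShiftConfig


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class BodySection(_Section):
    scale_min: float = 0.8
    scale_max: float = 1.2
    target_height_mm: float = 1617.0


class ImagingSection(_Section):
    n: int = 3000
    ratio: float = 0.85
    image_size: int = 200
    render_spacing_mm: float = 3.0


class TrainingSection(_Section):
    epochs: int = 2000
    learning_rate: float = 1.0e-3
    batch_size: int = 32
    hidden_layer_sizes: Tuple[int, ...] = (128, 64)
    alpha: float = 1.0e-4
    feature_size: int = 32


class ShiftsSection(_Section):
    upper_shift_mm: float = 10.0
    lower_shift_mm: float = 30.0
    lr_fraction: float = 0.75
    retraction_mm: float = 80.0
    breast_eval_sup_mm: float = 27.0
    breast_eval_inf_mm: float = 12.0
    ptv_sup_mm: float = -24.0
    ptv_inf_mm: float = 17.0

    def to_shift_config(self) -> ShiftConfig:
        cfg = ShiftConfig(**self.model_dump())
        cfg.validate()
        return cfg


class EvaluationSection(_Section):
    grid_spacing_mm: float = 1.0
    tune_min_mm: float = 0.0
    tune_max_mm: float = 45.0
    tune_step_mm: float = 5.0
    silhouette_spacing_mm: float = 2.0

    def candidates(self) -> Tuple[float, ...]:
        n = int(round((self.tune_max_mm - self.tune_min_mm) / self.tune_step_mm)) + 1
        return tuple(self.tune_min_mm + i * self.tune_step_mm for i in range(n))


class RunConfig(_Section):
    body: BodySection = BodySection()
    imaging: ImagingSection = ImagingSection()
    training: TrainingSection = TrainingSection()
    shifts: ShiftsSection = ShiftsSection()
    evaluation: EvaluationSection = EvaluationSection()
    seed: int = 0
    outdir: Optional[str] = None


def load_config(path=None) -> RunConfig:
    """Load and validate a YAML config; ``None`` or an empty file = defaults."""
    data = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise InvalidInputError(f"config file not found: {path}")
        data = yaml.safe_load(p.read_text()) or {}
    try:
        return RunConfig(**data)
    except ValidationError as exc:
        keys = sorted({".".join(str(loc) for loc in err["loc"]) for err in exc.errors()})
        raise InvalidParameterError(
            f"invalid configuration keys: {', '.join(keys)}") from exc


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(mode="json"), sort_keys=False))


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31."""
    digest = hashlib.blake2b(f"{global_seed}:{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2 ** 31)
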