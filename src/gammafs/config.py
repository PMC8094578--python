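"""Run configuration and deterministic per-stage seed derivation."""

from __future__ import annotations

import hashlib
import tomllib
from dataclasses import dataclass, fields
from pathlib import Path

from .exceptions import ValidationError

__all__ = ["RunConfig", "derive_seed"]


def derive_seed(root_seed, stage: str) -> int:
    """Deterministic stage seed derived from one root seed.

    Hash-based so adding a stage never shifts the seeds of the others; the
    result is always below 2**31.
    """
    h = hashlib.sha256(f"{root_seed}/{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


@dataclass
class RunConfig:
    """Knobs of the end-to-end pipeline; defaults are the study conditions
    (150 ranking replicates, 5-fold CV x 10 repeats, 1000 validation
    replicates)."""

    seed: int = 0
    B_ranking: int = 150
    cv_folds: int = 5
    cv_repeats: int = 10
    B_validation: int = 1000
    scorer: str = "gamma"
    max_subset_size: int | None = None
    derivative_units: str = "seconds"   # scale of the derivative moments

    def __post_init__(self):
        for name in ("B_ranking", "cv_folds", "cv_repeats", "B_validation"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.max_subset_size is not None and self.max_subset_size < 1:
            raise ValidationError("max_subset_size must be >= 1")

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        data = tomllib.loads(Path(path).read_text())
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.seed, stage)
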