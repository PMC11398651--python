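"""Run configuration: a flat ``key: value`` text file with validation.

Every numeric constant any stage uses lives here so a run can be reproduced
from its echoed config alone. All randomness derives from ``seed`` with
per-stage child seeds.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np


class ConfigValidationError(ValueError):
    pass


@dataclass
class RunConfig:
    output_dir: str = "run_output"
    volumes_dir: str | None = None     # None -> simulate a phantom cohort
    masks_dir: str | None = None
    manifest_path: str | None = None

    n_patients: int = 6
    grid_shape: tuple = (4, 64, 64)
    n_nce: int = 2
    n_lap: int = 7
    n_pvp: int = 7
    grade_fractions: tuple = (7 / 39, 32 / 39)
    observer_target_dsc: float = 0.79
    noise_sd: float = 4.0
    drift_per_sequence: float = 0.0

    ccc_cutoff: float = 0.90
    spearman_threshold: float = 0.90
    alpha: float = 0.05
    bin_width_hu: float = 25.0
    select_nce: int = 2
    select_lap: int = 7
    select_pvp: int = 7
    train_n: int = 29
    test_n: int = 10
    max_features: int = 3

    seed: int = 17
    column_mapping: dict = field(default_factory=dict)

    def validate(self) -> None:
        def check(cond, msg):
            if not cond:
                raise ConfigValidationError(msg)
        check(0 < self.ccc_cutoff <= 1.0, f"ccc_cutoff must be in (0, 1], got {self.ccc_cutoff}")
        check(0 < self.spearman_threshold <= 1.0,
              f"spearman_threshold must be in (0, 1], got {self.spearman_threshold}")
        check(0 < self.alpha < 1, f"alpha must be in (0, 1), got {self.alpha}")
        check(self.bin_width_hu > 0, f"bin_width_hu must be > 0, got {self.bin_width_hu}")
        check(0 < self.observer_target_dsc <= 1.0,
              f"observer_target_dsc must be in (0, 1], got {self.observer_target_dsc}")
        check(self.n_patients >= 2, "n_patients must be >= 2")
        check(self.train_n > 0 and self.test_n > 0, "split sizes must be positive")
        check(self.select_nce >= 2 and self.select_lap >= 7 and self.select_pvp >= 7,
              "selection counts must be >= 2/7/7")
        for p in (self.volumes_dir, self.masks_dir, self.manifest_path):
            if p is not None:
                check(Path(p).exists(), f"path does not exist: {p}")

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage child seed derived from the root seed."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31 - 1)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["grade_fractions"] = list(self.grade_fractions)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]

    def echo(self) -> str:
        lines = [f"{k}: {v}" for k, v in sorted(self.to_dict().items())]
        return "\n".join(lines)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Parse a flat ``key: value`` config file (``#`` comments allowed)."""
        kwargs = {}
        fields = {f: t for f, t in cls.__dataclass_fields__.items()}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if ":" not in line:
                raise ConfigValidationError(f"{path}:{lineno}: expected 'key: value'")
            key, raw = (s.strip() for s in line.split(":", 1))
            if key not in fields:
                raise ConfigValidationError(f"{path}:{lineno}: unknown key {key!r}")
            kwargs[key] = _coerce(key, raw)
        return cls(**kwargs)


def _coerce(key: str, raw: str):
    if raw.lower() in ("none", "null", ""):
        return None
    if key in ("grid_shape", "grade_fractions"):
        parts = [p for p in raw.replace(",", " ").split() if p]
        vals = [float(p) for p in parts]
        return tuple(int(v) if key == "grid_shape" else v for v in vals)
    if key == "column_mapping":
        return json.loads(raw)
    for cast in (int, float):
        try:
            v = cast(raw)
            if cast is int and "." in raw:
                continue
            return v
        except ValueError:
            continue
    return raw
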