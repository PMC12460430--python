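"""Run configuration: every tunable in one serializable place.

A :class:`RunConfig` collects the defaults of all pipeline stages so a run
can be reproduced from the YAML file written next to its outputs.  Explicit
seeds are required for every stochastic stage; there is no wall-clock
seeding.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import yaml

from .mapping import DEFAULT_COST_RANKING, MappingConfig
from .measures import MeasureConfig
from .synthetic import CohortConfig, MotorParams

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    """All pipeline tunables; see the per-module docs for semantics."""

    seed: Optional[int] = None

    # input handling
    time_unit: str = "s"
    flip_y: bool = False

    # outlier filtering
    early_frac: float = 0.035
    sd_mult: float = 2.0

    # measures
    sampen_m: int = 2
    sampen_r_frac: float = 0.2
    pause_threshold: float = 0.0

    # mapping
    corr_threshold: float = 0.9
    vip_threshold: float = 0.8
    max_r2_loss: float = 0.01
    max_rmsep_rise: float = 0.002
    cost_ranking: Tuple[str, ...] = tuple(DEFAULT_COST_RANKING)

    # resampling
    B: int = 1000
    sizes: Optional[List[int]] = None          # default: 1..max common count
    selfcorr_sizes: Optional[List[int]] = None  # default: 10..max common count
    fit_starts: int = 5

    # synthetic cohort
    cohort: CohortConfig = field(default_factory=CohortConfig)

    def measure_config(self) -> MeasureConfig:
        return MeasureConfig(sampen_m=self.sampen_m,
                             sampen_r_frac=self.sampen_r_frac,
                             pause_threshold=self.pause_threshold)

    def mapping_config(self) -> MappingConfig:
        return MappingConfig(
            corr_threshold=self.corr_threshold,
            vip_threshold=self.vip_threshold,
            max_r2_loss=self.max_r2_loss,
            max_rmsep_rise=self.max_rmsep_rise,
            cost_ranking=tuple(self.cost_ranking),
        )

    def require_seed(self) -> int:
        if self.seed is None:
            raise ValueError(
                "an explicit seed is required for stochastic stages "
                "(set `seed` in the config or pass --seed)"
            )
        return int(self.seed)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort"]["motor"] = asdict(self.cohort.motor)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    raw.pop("config_hash", None)  # derived field written by save_config
    cohort_raw = raw.pop("cohort", None)
    cfg = RunConfig(**raw)
    if cohort_raw is not None:
        motor_raw = cohort_raw.pop("motor", None)
        motor = MotorParams(**{k: tuple(v) if isinstance(v, list) else v
                               for k, v in (motor_raw or {}).items()})
        cohort_raw = {k: tuple(v) if isinstance(v, list) else v
                      for k, v in cohort_raw.items()}
        cfg.cohort = CohortConfig(**cohort_raw, motor=motor)
    if cfg.cost_ranking is not None:
        cfg.cost_ranking = tuple(cfg.cost_ranking)
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    d = cfg.to_dict()
    d["config_hash"] = cfg.config_hash()
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
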