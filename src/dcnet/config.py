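"""Run configuration: paths, analysis parameters and flags.

All analysis defaults are the reference values of the emulated study design:
discard 10 volumes, FD threshold 0.2 mm, minimum 3 minutes of surviving
scan, 2 mm / 2 degree motion limits, 0.01-0.08 Hz passband, sparsity sweep
0.05-0.40 in steps of 0.01 with reporting threshold 0.30, and alpha 0.05.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class SimulateConfig:
    """Synthetic-cohort parameters surfaced in the run configuration."""

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"HC": 40, "SD": 34, "MDD": 40}
    )
    g: int = 246
    T: int = 200
    ar_coefficient: float = 0.3
    effects: list[dict] = field(default_factory=list)
    spike_rate: float = 0.02
    spike_amplitude_mm: float = 0.3
    drift_scale_mm: float = 0.01


@dataclass
class RunConfig:
    data_dir: str = "data"
    output_dir: str = "results"
    tr_seconds: float = 2.5
    n_discard: int = 10
    fd_threshold: float = 0.2
    min_minutes: float = 3.0
    trans_limit_mm: float = 2.0
    rot_limit_deg: float = 2.0
    low_hz: float = 0.01
    high_hz: float = 0.08
    sparsity_min: float = 0.05
    sparsity_max: float = 0.40
    sparsity_step: float = 0.01
    reporting_sparsity: float = 0.30
    alpha: float = 0.05
    covariates: tuple[str, ...] = ("age", "sex", "education", "mean_fd")
    seed: int = 0
    edge_ranking: str = "signed"  # documented flag; "signed" is the only mode built
    cross_validate: bool = False  # composite index is evaluated in-sample by default
    diagnostics: bool = True
    diagnostic_nulls: int = 20
    simulate: SimulateConfig = field(default_factory=SimulateConfig)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        sim = raw.pop("simulate", {})
        cfg = cls(**raw)
        if sim:
            cfg.simulate = SimulateConfig(**sim)
        if isinstance(cfg.covariates, list):
            cfg.covariates = tuple(cfg.covariates)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["covariates"] = list(self.covariates)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]
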