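"""Pipeline configuration: every tunable in one serializable object.

Defaults encode the analysis conventions: 2.5 m/s maximum speed, 24 h
regularization, 1.0/1.8 deg geolocator errors, 10-day gap rule, 5-day
minimum segment, 7-day shore-release trim, 100 CRW replicates, 2 m/s active-
speed cutoff, presence:background ratios 1:1..1:5, the learning-rate and
tree-complexity grids, bag fraction 0.6, 10 CV folds, and the 0.1 floor /
0.75 quantile persistence threshold. A master seed fans out deterministically
to per-stage child seeds so stages can be rerun in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

STAGES = ("simulate", "preprocess", "pseudoabs", "covariates", "fit", "predict", "report")


@dataclass
class PipelineConfig:
    # track processing
    v_max_mps: float = 2.5
    dt_hours: float = 24.0
    geolocator_error_deg: tuple[float, float] = (1.0, 1.8)
    gap_days: float = 10.0
    min_segment_len: int = 5
    trim_days: int = 7
    mpm_window_days: int = 7
    mpm_gamma_thresh: float = 0.75
    mpm_heading_sector: tuple[float, float] = (225.0, 315.0)
    mpm_min_run_days: int = 10
    # pseudo-absences
    n_rep: int = 100
    v_active_max_mps: float = 2.0
    # covariates
    sd_window_days: int = 30
    rugosity_window: int = 3
    # model
    ratio: int = 1
    ratio_grid: tuple[int, ...] = (1, 2, 3, 4, 5)
    learning_rate: float = 0.1
    tree_complexity: int = 5
    lr_grid: tuple[float, ...] = (0.0001, 0.0005, 0.001, 0.005, 0.01, 0.05, 0.1, 0.3, 0.5)
    tc_grid: tuple[int, ...] = (3, 4, 5)
    bag_fraction: float = 0.6
    cv_folds: int = 10
    step_size: int = 50
    max_trees: int = 250
    run_ratio_experiment: bool = False
    run_grid_search: bool = False
    eval_regimes: tuple[str, ...] = ("full", "split75", "kfold10")
    # prediction
    persistence_floor: float = 0.1
    persistence_quantile: float = 0.75
    predict_every_n_days: int = 1
    # synthetic ocean (used by the simulate stage)
    domain_lon: tuple[float, float] = (-40.0, -10.0)
    domain_lat: tuple[float, float] = (20.0, 50.0)
    grid_step: float = 0.25
    start_date: str = "2000-01-01"
    n_days: int = 731
    n_eddies: int = 48
    n_tracks: int = 40
    # seeding
    master_seed: int = 0

    def child_seed(self, stage: str) -> int:
        """Deterministic per-stage child seed derived from the master seed."""
        if stage not in STAGES:
            raise KeyError(f"unknown stage {stage!r}")
        ss = np.random.SeedSequence(self.master_seed).spawn(len(STAGES))
        return int(ss[STAGES.index(stage)].generate_state(1)[0] % (2 ** 31))

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        fields = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(d) - set(fields)
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        kw = {}
        for k, v in d.items():
            if isinstance(v, list):
                v = tuple(v)
            kw[k] = v
        return cls(**kw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def digest(self) -> str:
        """Stable hash of the full configuration, for provenance records."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
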