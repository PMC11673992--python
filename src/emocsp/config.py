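"""Pipeline configuration: a validated YAML-backed schema.

Unknown keys are rejected so typos fail loudly; every default mirrors the
reference protocol where one is stated (250 Hz, 19 channels, 3 s windows
at 70% overlap, FIR order 800, Adam over 10 epochs, 70/15/15 split).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, model_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulationSection(_Strict):
    n_channels: int = 19
    fs: float = 250.0
    n_subjects: int = 16
    n_retained: int = 7
    separation: float = 4.0
    pink_scale: float = 0.5
    white_scale: float = 0.2
    track_seconds: float = 60.0
    pause_seconds: float = 15.0


class PreprocessSection(_Strict):
    notch_hz: float = 50.0
    notch_q: float = 30.0
    band_low: float = 0.5
    band_high: float = 45.0
    fir_order: int = 800
    head_trim_s: float = 10.0
    tail_trim_s: float = 10.0
    win_s: float = 3.0
    overlap_frac: float = 0.70
    ica_artifact_rejection: bool = False


class MCCSPSection(_Strict):
    m: int = 3
    mode: str = "composite"
    rank_tol: float = 1e-10
    trace_norm: bool = False


class NetworkSection(_Strict):
    activation: str = "relu"
    epochs: int = 10
    head_epochs: int = 30
    learning_rate: float = 1e-3
    batch_size: int = 32
    head_weight_decay: float = 1e-2
    n_branches: int = 3
    scaling: str = "global"


class SplitSection(_Strict):
    train: float = 0.70
    val: float = 0.15
    test: float = 0.15
    granularity: str = "block"

    @model_validator(mode="after")
    def _sums(self):
        if abs(self.train + self.val + self.test - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        return self


class BaselineSection(_Strict):
    alpha: float = 0.05
    wavelet: str = "db4"
    dwt_level: int = 4
    knn_k: int = 5
    mlp_hidden: int = 35


class PipelineConfig(_Strict):
    seed: int = 0
    workdir: str = "emocsp_run"
    snr_grid: list[float] = [-4.0, 0.0, 1.0, 10.0, 20.0]
    simulation: SimulationSection = SimulationSection()
    preprocess: PreprocessSection = PreprocessSection()
    mccsp: MCCSPSection = MCCSPSection()
    network: NetworkSection = NetworkSection()
    split: SplitSection = SplitSection()
    baseline: BaselineSection = BaselineSection()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
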