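"""Run configuration: one serializable object drives the whole analysis.

Defaults mirror the recording-study analysis settings: 1–30 Hz band-pass at
100 Hz, −50..+400 ms lags, ridge grid 10^−4..10^8, 25% accuracy ROI, 20%
surprise quantiles, 1,000 cluster permutations, 10-fold information-model
resampling.  Fixture sizes (melody/subject counts, note counts, SNR) default
to a scaled synthetic study that runs on a laptop.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .errors import ConfigError

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    # global
    seed: int = 0
    out_dir: str = "results/run"
    figures: bool = True

    # stimuli: either a directory of MIDI files or a synthetic fixture
    stimuli_dir: str | None = None
    n_real: int = 10
    n_shuffled: int = 4
    n_notes: int = 60
    temperature: float = 0.3
    sixteenth_duration: float = 0.06
    pitch_order: int = 1
    rhythm_order: int = 1

    # information dynamics
    folds: int = 10
    max_order: int = 10
    bias: float = 2.0
    ltm_online: bool = True
    pretrain_dir: str | None = None

    # features
    fs: float = 100.0
    include_flux: bool = True
    include_envelope: bool = False
    include_ioi_next: bool = False
    audio_sr: float = 16000.0
    n_bands: int = 32

    # synthetic EEG
    n_subjects: int = 20
    n_channels: int = 64
    snr: float = 1.0
    active_features: tuple[str, ...] = ("onset", "ioi", "St", "Et")
    shuffled_info_gain: float = 0.0
    latency_jitter_ms: float = 10.0
    gain_sd: float = 0.2

    # preprocessing
    low_hz: float = 1.0
    high_hz: float = 30.0
    bad_z: float = 2.75
    interp_radius_mm: float = 18.0

    # TRF / variance partitioning
    lag_min_ms: float = -50.0
    lag_max_ms: float = 400.0
    lambda_min_exp: int = -4
    lambda_max_exp: int = 8
    roi_fraction: float = 0.25
    reduced_models: tuple[str, ...] = ("highlevel", "timing", "pitch", "ioi", "ipi")
    n_randomizations: int = 1

    # ERP
    quantile: float = 0.20
    n_perm: int = 1000
    cluster_alpha: float = 0.025
    min_neighbors: int = 3
    adjacency_radius_mm: float = 30.0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ConfigError("folds must be >= 2")
        if not 0 < self.roi_fraction <= 1:
            raise ConfigError("roi_fraction must be in (0, 1]")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("active_features", "reduced_models"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("active_features", "reduced_models"):
            if key in d:
                d[key] = tuple(d[key])
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        """Stable hash of the configuration, for provenance logs."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def replace(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)
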