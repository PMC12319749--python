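"""Pipeline configuration: every analysis threshold with its standard
default, JSON round-trip serialization, and validation."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from .synthgen import MediationPaths, REST_PATHS, TASK_PATHS


@dataclass
class PipelineConfig:
    seed: int = 0
    # cohort
    n_subjects: int = 180
    age_range: tuple[float, float] = (20.0, 79.0)
    # generator
    grid_dims: tuple[int, int, int] = (18, 18, 18)
    n_networks: int = 7
    rest_volumes: int = 350
    task_volumes: int = 330
    tr_s: float = 2.0
    noise_sd: float = 0.3
    mediation_rest: MediationPaths = REST_PATHS
    mediation_task: MediationPaths = TASK_PATHS
    load_gains: tuple[float, float, float] = (1.0, 1.3, 1.6)
    hemodynamic_delay_s: float = 4.0
    tac_noise_scale: float = 0.15
    # preprocessing
    fd_scrub_mm: float = 0.2
    fd_exclude_mm: float = 0.30
    band_hz: tuple[float, float] = (0.009, 0.09)
    fwhm_mm: float = 6.0
    outlier_z: float = 3.29
    accuracy_floor: float = 0.5
    # parcellation
    top_k: int = 25
    tie_rule: str = "summed-z"
    # connectivity
    roi_table: str | None = None  # None -> toy ROIs on the synthetic grid
    lag_s: float = 4.0
    min_volumes: int = 30
    # SRTM
    srtm_weights: str = "duration"
    # stats
    n_boot: int = 5000

    def validate(self) -> None:
        low, high = self.band_hz
        nyquist = 1.0 / (2.0 * self.tr_s)
        if not (0 < low < high < nyquist):
            raise ValueError(
                f"band {self.band_hz} Hz invalid: must satisfy "
                f"0 < low < high < Nyquist ({nyquist:.4g} Hz at TR {self.tr_s} s)"
            )
        if self.n_subjects < 4:
            raise ValueError("n_subjects must be >= 4")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.fwhm_mm < 0:
            raise ValueError("fwhm_mm must be non-negative")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mediation_rest"] = dataclasses.asdict(self.mediation_rest)
        d["mediation_task"] = dataclasses.asdict(self.mediation_task)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("mediation_rest", "mediation_task"):
            if key in d and isinstance(d[key], dict):
                d[key] = MediationPaths(**d[key])
        for key in ("age_range", "grid_dims", "band_hz", "load_gains"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, path_or_text: str | Path) -> "PipelineConfig":
        p = Path(path_or_text) if not str(path_or_text).lstrip().startswith("{") else None
        text = p.read_text() if p is not None else str(path_or_text)
        return cls.from_dict(json.loads(text))

    def hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]
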