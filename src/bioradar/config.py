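"""Structured run configuration: YAML in, validated dataclasses out.

A single config file drives the whole pipeline.  Sections mirror the
processing stages::

    scene:      {targets: [{range_m: 3.0, resp_freq_hz: 0.3}, ...], seed: 1, ...}
    preprocess: {n_range_bins: 200, clutter_window: 100, ...}
    autocorr:   {estimator: biased}
    wavelet:    {wavelet_name: db4, n_levels: 6, ...}
    detection:  {blind_range_m: 1.0, pit_k: 3.0, ...}
    out_dir:    results/run1
    log_level:  INFO

Unknown keys are rejected (typos should fail loudly, not silently fall back
to defaults).  Cross-field consistency (cutoff below Nyquist, wavelet depth
feasible for the record length, ...) is checked up front in
:meth:`RunConfig.validate`, before any computation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .correlation import AutocorrParams
from .detection import DetectionParams
from .entropy import WaveletParams
from .exceptions import ConfigError
from .preprocess import PreprocessParams
from .scene import SceneConfig, TargetSpec


@dataclass
class RunConfig:
    scene: SceneConfig = field(default_factory=SceneConfig)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    autocorr: AutocorrParams = field(default_factory=AutocorrParams)
    wavelet: WaveletParams = field(default_factory=WaveletParams)
    detection: DetectionParams = field(default_factory=DetectionParams)
    out_dir: str = "bioradar_out"
    log_level: str = "INFO"

    def validate(self) -> None:
        self.scene.validate()
        n_slow = self.scene.n_slow
        self.preprocess.validate(self.scene.n_fast, n_slow, self.scene.slow_fs_hz)
        self.autocorr.validate(n_slow)
        n_lags = (self.autocorr.max_lag or n_slow - 1) + 1
        self.wavelet.validate(n_lags)
        self.detection.validate()
        if self.detection.power_band_hz[1] > self.scene.slow_fs_hz / 2.0:
            raise ConfigError("power band exceeds the slow-time Nyquist rate")

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return _plain(d)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw or {})
        kwargs = {}
        section_types = {
            "preprocess": PreprocessParams,
            "autocorr": AutocorrParams,
            "wavelet": WaveletParams,
            "detection": DetectionParams,
        }
        if "scene" in raw:
            kwargs["scene"] = _scene_from_dict(raw.pop("scene"))
        for name, typ in section_types.items():
            if name in raw:
                kwargs[name] = _dataclass_from_dict(typ, raw.pop(name), name)
        for name in ("out_dir", "log_level"):
            if name in raw:
                kwargs[name] = raw.pop(name)
        if raw:
            raise ConfigError(f"unknown config section(s): {sorted(raw)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config root must be a mapping, got {type(raw)}")
        return cls.from_dict(raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _plain(obj):
    """Recursively convert numpy/tuple values to YAML-friendly types."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _dataclass_from_dict(typ, raw: dict, section: str):
    if not isinstance(raw, dict):
        raise ConfigError(f"config section {section!r} must be a mapping")
    names = {f.name for f in dataclasses.fields(typ)}
    unknown = set(raw) - names
    if unknown:
        raise ConfigError(f"unknown key(s) in {section!r}: {sorted(unknown)}")
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()
    }
    return typ(**coerced)


def _scene_from_dict(raw: dict) -> SceneConfig:
    if not isinstance(raw, dict):
        raise ConfigError("config section 'scene' must be a mapping")
    raw = dict(raw)
    targets = [
        _dataclass_from_dict(TargetSpec, t, "scene.targets")
        for t in raw.pop("targets", [])
    ]
    cfg = _dataclass_from_dict(SceneConfig, raw, "scene")
    cfg.targets = targets
    return cfg
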