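"""Configuration objects for the texture-analysis pipeline.

All tunables live here so a run is fully described by one
:class:`PipelineConfig`, which round-trips through YAML.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

BANDS = ("LF", "MF", "HF", "TB")
#: conversion ids: 1 zigzag, 2 zigzag of rotated patch, 3 spiral, 4 spiral of rotated patch
CONVERSIONS = (1, 2, 3, 4)


@dataclass(frozen=True)
class WaveletConfig:
    """Continuous wavelet analysis settings.

    The scale grid is log-spaced between the scales whose center
    frequencies are ``freq_max`` and ``freq_min`` cycles/sample.  Scales
    are assigned to frequency bands by their center frequency: HF above
    ``hf_edge``, MF above ``mf_edge``, LF above ``lf_edge``, and the
    remainder is the very-low-frequency (VLF) trend, which the total
    band (TB) excludes.
    """

    mother: str = "db4"
    n_scales: int = 32
    freq_min: float = 0.005
    freq_max: float = 0.5
    hf_edge: float = 0.125
    mf_edge: float = 0.03125
    lf_edge: float = 0.0078

    def __post_init__(self) -> None:
        if not (0 < self.freq_min < self.freq_max <= 0.5):
            raise ValueError("need 0 < freq_min < freq_max <= 0.5")
        if not (self.lf_edge < self.mf_edge < self.hf_edge < self.freq_max):
            raise ValueError("band edges must satisfy lf < mf < hf < freq_max")
        if self.n_scales < 4:
            raise ValueError("need at least 4 scales to populate 4 bands")


@dataclass(frozen=True)
class ARConfig:
    """Autoregressive model settings.

    ``orders`` maps each band to its model order; the defaults follow
    the band-dependent orders used for 20x20-pixel patches (LF=100,
    MF=50, HF=30, TB=80).  ``spectrum_gain`` selects the numerator of
    the parametric spectrum: ``"unit"`` for 1/|A(f)|^2, ``"sigma2"``
    for sigma^2/|A(f)|^2.
    """

    orders: Mapping[str, int] = field(
        default_factory=lambda: {"LF": 100, "MF": 50, "HF": 30, "TB": 80}
    )
    n_freq: int = 512
    spectrum_gain: str = "unit"
    diagonal_loading: float = 1e-9

    def __post_init__(self) -> None:
        missing = set(BANDS) - set(self.orders)
        if missing:
            raise ValueError(f"orders missing bands: {sorted(missing)}")
        if any(p < 1 for p in self.orders.values()):
            raise ValueError("model orders must be positive")
        if self.n_freq < 64:
            raise ValueError("n_freq must be at least 64")
        if self.spectrum_gain not in ("unit", "sigma2"):
            raise ValueError("spectrum_gain must be 'unit' or 'sigma2'")


@dataclass(frozen=True)
class SegmentConfig:
    patch_size: int = 20
    n_init: int = 10
    assignment: str = "oracle"  # oracle | centroid_reference

    def __post_init__(self) -> None:
        if self.patch_size < 2:
            raise ValueError("patch_size must be >= 2")
        if self.assignment not in ("oracle", "centroid_reference"):
            raise ValueError("assignment must be 'oracle' or 'centroid_reference'")


@dataclass(frozen=True)
class PipelineConfig:
    bands: WaveletConfig = field(default_factory=WaveletConfig)
    ar: ARConfig = field(default_factory=ARConfig)
    segment: SegmentConfig = field(default_factory=SegmentConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Stable short hash of the full configuration, for run provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        return cls(
            bands=WaveletConfig(**d.get("bands", {})),
            ar=ARConfig(**d.get("ar", {})),
            segment=SegmentConfig(**d.get("segment", {})),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


DEFAULT_CONFIG = PipelineConfig()
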