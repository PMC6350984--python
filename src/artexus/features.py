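"""Spectral energy-ratio texture features.

From the 16 AR spectra of a patch (4 conversions x 4 bands) 30 energy
ratios ER_1..ER_30 are computed:

* ER_1..ER_4 — main-peak-to-total ratios within a single spectrum:
  the energy between the onset and offset of the spectrum's main peak
  divided by the spectrum's total energy.  Always in (0, 1].
* ER_5..ER_30 — total-energy ratios between two band spectra, e.g.
  LF-over-HF energy across conversions; sensitive to how texture
  irregularity distributes across frequency bands.

Energies are plain sums of the discretised spectral density over the
frequency grid; "total" means the full [0, Nyquist] band.  The main
peak's onset/offset are the local minima flanking the global maximum
(grid boundaries or half-power crossings when no interior minimum
exists).

The full candidate space is the 256 ordered pairs of the 16 spectra;
the 30-ratio registry used here is the published selection from that
space.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .armodel import ARSpectrum
from .config import BANDS, CONVERSIONS

__all__ = [
    "ERSpec",
    "ER_REGISTRY",
    "FeatureVector",
    "FEATURE_NAMES",
    "candidate_ratio_space",
    "spectral_energy",
    "main_peak_bounds",
    "compute_features",
]


@dataclass(frozen=True)
class ERSpec:
    id: int
    kind: str  # "peak_over_total" | "band_over_band"
    num: tuple[int, str]  # (conversion_id, band)
    den: tuple[int, str]


def _registry() -> tuple[ERSpec, ...]:
    peak = [(1, "HF"), (1, "MF"), (1, "LF"), (1, "TB")]
    ratio = [
        ((1, "HF"), (1, "TB")), ((2, "HF"), (2, "TB")),
        ((1, "MF"), (1, "TB")), ((2, "MF"), (2, "TB")),
        ((2, "LF"), (2, "TB")), ((3, "LF"), (3, "TB")), ((4, "LF"), (4, "TB")),
        ((1, "LF"), (2, "HF")), ((1, "LF"), (3, "HF")), ((1, "LF"), (4, "HF")),
        ((2, "LF"), (1, "HF")), ((2, "LF"), (2, "HF")), ((2, "LF"), (3, "HF")),
        ((2, "LF"), (4, "HF")), ((3, "LF"), (2, "HF")), ((3, "LF"), (3, "HF")),
        ((3, "LF"), (4, "HF")), ((4, "LF"), (2, "HF")), ((4, "LF"), (3, "HF")),
        ((4, "LF"), (4, "HF")), ((1, "MF"), (2, "HF")), ((1, "MF"), (3, "HF")),
        ((1, "MF"), (4, "HF")), ((2, "MF"), (2, "HF")), ((2, "MF"), (3, "HF")),
        ((2, "MF"), (4, "HF")),
    ]
    specs = [ERSpec(i + 1, "peak_over_total", nd, nd) for i, nd in enumerate(peak)]
    specs += [ERSpec(i + 5, "band_over_band", num, den) for i, (num, den) in enumerate(ratio)]
    return tuple(specs)


#: The 30-feature registry: ER id -> (NUM spectrum, DEN spectrum).
ER_REGISTRY: tuple[ERSpec, ...] = _registry()
FEATURE_NAMES: tuple[str, ...] = tuple(f"ER_{s.id}" for s in ER_REGISTRY)


def candidate_ratio_space() -> list[tuple[tuple[int, str], tuple[int, str]]]:
    """All 256 ordered (NUM, DEN) pairs of the 16 per-patch spectra."""
    keys = [(i, b) for i in CONVERSIONS for b in BANDS]
    return [(n, d) for n in keys for d in keys]


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray  # ER_1..ER_30
    patch_row: int = 0
    patch_col: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.shape != (len(ER_REGISTRY),):
            raise ValueError(f"expected {len(ER_REGISTRY)} feature values")


def spectral_energy(spectrum: ARSpectrum, f_lo: float = 0.0, f_hi: float = 0.5) -> float:
    """Sum of the spectral density over grid points with f_lo <= f <= f_hi."""
    if f_lo > f_hi:
        raise ValueError("f_lo must not exceed f_hi")
    mask = (spectrum.freqs >= f_lo) & (spectrum.freqs <= f_hi)
    return float(spectrum.density[mask].sum())


def main_peak_bounds(spectrum: ARSpectrum) -> tuple[float, float]:
    """Frequency onset/offset of the spectrum's main (tallest) peak.

    The bounds are the nearest local minima flanking the global maximum;
    a side with no interior minimum (monotone flank) falls back to its
    half-power crossing, then to the grid boundary.
    """
    d = spectrum.density
    f = spectrum.freqs
    n = d.size
    ipk = int(np.argmax(d))
    half = d[ipk] / 2.0

    def _left() -> int:
        for i in range(ipk - 1, 0, -1):
            if d[i] <= d[i - 1] and d[i] <= d[i + 1]:
                return i
        return -1

    def _right() -> int:
        for i in range(ipk + 1, n - 1):
            if d[i] <= d[i - 1] and d[i] <= d[i + 1]:
                return i
        return -1

    i1, i2 = _left(), _right()
    if i1 < 0:
        below = np.flatnonzero(d[:ipk] < half)
        i1 = int(below[-1]) if below.size else 0
        if ipk == 0 or not below.size:
            warnings.warn("no interior minimum left of the peak; boundary/half-power fallback",
                          RuntimeWarning, stacklevel=2)
    if i2 < 0:
        above = np.flatnonzero(d[ipk + 1:] < half)
        i2 = ipk + 1 + int(above[0]) if above.size else n - 1
        if ipk == n - 1 or not above.size:
            warnings.warn("no interior minimum right of the peak; boundary/half-power fallback",
                          RuntimeWarning, stacklevel=2)
    return float(f[i1]), float(f[i2])


def _index_spectra(spectra: Iterable[ARSpectrum]) -> Mapping[tuple[int, str], ARSpectrum]:
    table: dict[tuple[int, str], ARSpectrum] = {}
    for s in spectra:
        key = (s.conversion_id, s.band)
        if key in table:
            raise ValueError(f"duplicate spectrum for conversion/band {key}")
        table[key] = s
    expected = {(i, b) for i in CONVERSIONS for b in BANDS}
    missing = expected - set(table)
    if missing:
        raise ValueError(f"missing spectra for conversion/band pairs: {sorted(missing)}")
    return table


def compute_features(spectra: Sequence[ARSpectrum],
                     patch_row: int = 0, patch_col: int = 0) -> FeatureVector:
    """The 30 energy ratios of one patch from its 16 AR spectra."""
    table = _index_spectra(spectra)
    values = np.empty(len(ER_REGISTRY))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # peak fallbacks are routine
        for j, spec in enumerate(ER_REGISTRY):
            s_num, s_den = table[spec.num], table[spec.den]
            den = spectral_energy(s_den)
            assert den > 0, "AR spectral density is clipped strictly positive"
            if spec.kind == "peak_over_total":
                f1, f2 = main_peak_bounds(s_num)
                values[j] = spectral_energy(s_num, f1, f2) / den
            else:
                values[j] = spectral_energy(s_num) / den
    return FeatureVector(values, patch_row, patch_col)
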