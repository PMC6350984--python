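"""Wavelet frequency-band decomposition of texture signals.

Each 1-D texture signal is analysed with a continuous wavelet transform
(Daubechies mother wavelet, log-spaced scale grid) and re-synthesised
over scale subsets into four band signals:

* ``LF`` / ``MF`` / ``HF`` — low / middle / high frequency narrowband
  reconstructions,
* ``TB`` — the total band, i.e. all scales except the very-low-frequency
  (VLF) trend scales, which removes slow intensity inhomogeneity.

The forward transform correlates the signal with the sampled, L2-scale-
normalised wavelet.  Band synthesis applies the adjoint (convolution
with the same kernel), which makes each per-scale analysis+synthesis
pass exactly zero-phase; per-scale weights are fitted once by least
squares so that the summed all-scale response is flat across the
analysed frequency range.  Daubechies wavelets have strongly nonlinear
phase, so this frame-corrected adjoint synthesis reconstructs far more
faithfully than the classic delta-function (single-integral) inverse,
which suffers phase interference between neighbouring scales.

Boundary handling is symmetric reflection padding, trimmed back to the
signal length after synthesis.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pywt
from scipy.signal import fftconvolve

from .config import WaveletConfig
from .imgsig import TextureSignal

__all__ = ["BandSignal", "WaveletBank", "cwt_decompose", "reconstruct_band", "decompose_bands"]

_BAND_NAMES = ("LF", "MF", "HF", "TB")


@dataclass(frozen=True)
class BandSignal:
    samples: np.ndarray
    band: str
    conversion_id: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.band not in _BAND_NAMES:
            raise ValueError(f"band must be one of {_BAND_NAMES}")

    def __len__(self) -> int:
        return self.samples.size


class WaveletBank:
    """Precomputed kernels, scale grid, band masks and synthesis weights.

    Building the bank is moderately expensive (kernel sampling and a
    least-squares fit of the synthesis weights), so instances are cached
    per configuration via :func:`get_bank`.
    """

    def __init__(self, cfg: WaveletConfig):
        self.cfg = cfg
        wav = pywt.Wavelet(cfg.mother)
        _, psi, grid = wav.wavefun(level=10)
        fc = pywt.central_frequency(cfg.mother)
        self.center_freqs = np.geomspace(cfg.freq_max, cfg.freq_min, cfg.n_scales)
        self.scales = fc / self.center_freqs  # increasing
        support = grid[-1]
        self.kernels = []
        for a in self.scales:
            t = np.arange(int(np.ceil(support * a)) + 1) / a
            k = np.interp(t, grid, psi) / np.sqrt(a)
            k -= k.mean()  # discrete admissibility: sampled wavelet sums to zero
            self.kernels.append(k)
        self.pad = len(self.kernels[-1]) + 2
        self.weights = self._fit_weights()
        cf = self.center_freqs
        self.band_masks = {
            "HF": cf > cfg.hf_edge,
            "MF": (cf > cfg.mf_edge) & (cf <= cfg.hf_edge),
            "LF": (cf > cfg.lf_edge) & (cf <= cfg.mf_edge),
        }
        vlf = cf <= cfg.lf_edge
        self.band_masks["VLF"] = vlf
        self.band_masks["TB"] = ~vlf
        for name in ("LF", "MF", "HF"):
            if not self.band_masks[name].any():
                raise ValueError(f"scale grid leaves band {name} empty; adjust edges")

    def _fit_weights(self) -> np.ndarray:
        # zero-phase per-scale response = DFT of the kernel autocorrelation;
        # solve least squares for a flat summed response over the analysed range
        nfft = 4096
        freqs = np.fft.rfftfreq(nfft)
        resp = np.empty((len(self.kernels), freqs.size))
        for j, k in enumerate(self.kernels):
            ac = fftconvolve(k, k[::-1])
            c = len(k) - 1
            h = np.zeros(nfft)
            h[: len(ac) - c] = ac[c:]
            h[nfft - c:] = ac[:c]
            resp[j] = np.real(np.fft.rfft(h))
        mask = freqs >= 0.8 * self.cfg.freq_min
        w, *_ = np.linalg.lstsq(resp[:, mask].T, np.ones(mask.sum()), rcond=None)
        return w

    # -- forward ---------------------------------------------------------
    def min_length(self) -> int:
        return 2

    def decompose(self, x: np.ndarray) -> list[np.ndarray]:
        """Correlate with every kernel; returns padded full-mode coefficient rows."""
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = x[None, :]
        xp = np.pad(x, ((0, 0), (self.pad, self.pad)), mode="symmetric")
        return [fftconvolve(xp, k[None, ::-1], mode="full", axes=1) for k in self.kernels]

    def coefficients(self, x: np.ndarray) -> np.ndarray:
        """Trimmed (n_scales, n_samples) coefficient matrix, sample-centred.

        Row ``j`` holds the correlation of the signal with the scale-``j``
        wavelet whose support starts at the sample (the synthesis path
        compensates for this one-sided support).
        """
        n = np.asarray(x).shape[-1]
        rows = [c[..., self.pad: self.pad + n] for c in self.decompose(x)]
        return np.stack([r[0] if r.ndim == 2 else r for r in rows])

    # -- synthesis -------------------------------------------------------
    def synthesize(self, coeff_rows: list[np.ndarray], scale_idx: np.ndarray, n: int) -> np.ndarray:
        """Adjoint synthesis over a scale subset, trimmed to length ``n``."""
        first = coeff_rows[0]
        shape = first.shape[:-1] + (n,)
        acc = np.zeros(shape)
        for i in scale_idx:
            k = self.kernels[i]
            y = fftconvolve(coeff_rows[i], k[None, :] if coeff_rows[i].ndim == 2 else k,
                            mode="full", axes=-1)
            d = self.pad + len(k) - 1
            acc += self.weights[i] * y[..., d: d + n]
        return acc

    def band_signals(self, x: np.ndarray) -> dict[str, np.ndarray]:
        """LF/MF/HF/TB reconstructions of one signal or a batch of signals."""
        x = np.asarray(x, dtype=float)
        n = x.shape[-1]
        rows = self.decompose(x)
        out = {}
        for name in _BAND_NAMES:
            idx = np.flatnonzero(self.band_masks[name])
            y = self.synthesize(rows, idx, n)
            out[name] = y[0] if x.ndim == 1 else y
        return out


@lru_cache(maxsize=4)
def get_bank(cfg: WaveletConfig) -> WaveletBank:
    return WaveletBank(cfg)


def _check_length(x: np.ndarray, bank: WaveletBank) -> None:
    if x.shape[-1] < 2:
        raise ValueError("signal too short for wavelet analysis: need at least 2 samples")


def cwt_decompose(signal: TextureSignal | np.ndarray, cfg: WaveletConfig) -> np.ndarray:
    """Continuous wavelet coefficients, shape (n_scales, n_samples)."""
    x = signal.samples if isinstance(signal, TextureSignal) else np.asarray(signal, float)
    bank = get_bank(cfg)
    _check_length(x, bank)
    return bank.coefficients(x)


def reconstruct_band(
    signal: TextureSignal | np.ndarray,
    scale_subset: np.ndarray,
    cfg: WaveletConfig,
    band: str = "TB",
    conversion_id: int = 1,
) -> BandSignal:
    """Re-synthesise a signal from a subset of scale indices."""
    scale_subset = np.asarray(scale_subset, dtype=int)
    if scale_subset.size == 0:
        raise ValueError("scale subset is empty")
    bank = get_bank(cfg)
    if scale_subset.min() < 0 or scale_subset.max() >= len(bank.scales):
        raise ValueError("scale subset indices out of range")
    x = signal.samples if isinstance(signal, TextureSignal) else np.asarray(signal, float)
    rows = bank.decompose(x)
    y = bank.synthesize(rows, scale_subset, x.shape[-1])[0]
    cid = signal.conversion_id if isinstance(signal, TextureSignal) else conversion_id
    return BandSignal(y, band, cid)


def decompose_bands(signal: TextureSignal, cfg: WaveletConfig) -> list[BandSignal]:
    """The four band signals {LF, MF, HF, TB} of one texture signal."""
    bank = get_bank(cfg)
    _check_length(signal.samples, bank)
    per_band = bank.band_signals(signal.samples)
    return [BandSignal(per_band[b], b, signal.conversion_id) for b in _BAND_NAMES]
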