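"""Synthetic two-texture phantoms with known ground truth.

Real clinical ultrasound shows an organ whose speckle texture differs
from the surrounding tissue in its spatial frequency content, corrupted
by multiplicative speckle noise and a slowly varying intensity trend
(beam/gain inhomogeneity).  The generator emulates exactly these three
ingredients so every pipeline stage can be exercised with a known
pixel-accurate ground truth:

* band-limited textures — white Gaussian fields filtered to a
  configurable isotropic spatial-frequency annulus;
* multiplicative Rayleigh speckle of configurable strength (the
  standard first-order speckle proxy);
* an additive smooth low-order polynomial intensity trend, which the
  very-low-frequency wavelet scales are designed to absorb.

It does not simulate ultrasound physics (no scatterer maps,
point-spread convolution, attenuation or shadowing), so passing tests
demonstrate sensitivity to spatial-frequency texture contrast under
speckle, not clinical performance.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["TextureParams", "Phantom", "gen_texture", "gen_phantom"]


@dataclass(frozen=True)
class TextureParams:
    """Spatial-frequency band and noise level of one texture class.

    ``band`` is the (low, high) isotropic frequency annulus in
    cycles/pixel (Nyquist 0.5); ``base_intensity`` the mean gray level
    in [0, 1]; ``amplitude`` the gray-level standard deviation of the
    texture fluctuation; ``speckle_strength`` the coefficient of the
    multiplicative Rayleigh noise (0.3 is a realistic default).
    """

    band: tuple[float, float] = (0.05, 0.45)
    base_intensity: float = 0.5
    amplitude: float = 0.15
    speckle_strength: float = 0.3

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not (0 <= lo < hi <= 0.5 * np.sqrt(2)):
            raise ValueError("band must satisfy 0 <= lo < hi <= Nyquist*sqrt(2)")
        if not (0 <= self.base_intensity <= 1):
            raise ValueError("base_intensity must be in [0, 1]")
        if self.speckle_strength < 0:
            raise ValueError("speckle_strength must be >= 0")


@dataclass(frozen=True)
class Phantom:
    image: np.ndarray
    gt_mask: np.ndarray
    params_inside: TextureParams
    params_outside: TextureParams
    trend_amplitude: float
    seed: int

    def provenance(self) -> dict:
        return {
            "params_inside": asdict(self.params_inside),
            "params_outside": asdict(self.params_outside),
            "trend_amplitude": self.trend_amplitude,
            "seed": self.seed,
            "shape": list(self.image.shape),
        }

    def save(self, image_path: str | Path, gt_path: str | Path | None = None) -> None:
        from . import io as _io

        _io.write_image(image_path, self.image)
        if gt_path is not None:
            _io.write_mask(gt_path, self.gt_mask)
        side = Path(image_path).with_suffix(".json")
        side.write_text(json.dumps(self.provenance(), indent=2))


def _bandpass_field(shape: tuple[int, int], band: tuple[float, float],
                    rng: np.random.Generator) -> np.ndarray:
    """White Gaussian field filtered to an isotropic frequency annulus, unit variance."""
    h, w = shape
    noise = rng.standard_normal(shape)
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    rad = np.hypot(fy, fx)
    lo, hi = band
    # raised-cosine edges, 10% of the band width, to avoid ringing
    soft = 0.1 * (hi - lo)
    mask = np.clip((rad - (lo - soft)) / (soft + 1e-12), 0, 1) \
        * np.clip(((hi + soft) - rad) / (soft + 1e-12), 0, 1)
    field = np.real(np.fft.ifft2(np.fft.fft2(noise) * mask))
    sd = field.std()
    if sd == 0:
        raise ValueError(f"frequency band {band} is empty for shape {shape}")
    return field / sd


def gen_texture(params: TextureParams, shape: tuple[int, int],
                seed: int | np.random.Generator = 0) -> np.ndarray:
    """One textured raster in [0, 1]; deterministic for a given seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    field = _bandpass_field(shape, params.band, rng)
    img = params.base_intensity + params.amplitude * field
    if params.speckle_strength > 0:
        ray = rng.rayleigh(scale=1.0, size=shape)
        ray = ray / np.sqrt(np.pi / 2)  # unit mean
        img = img * (1.0 + params.speckle_strength * (ray - 1.0))
    return np.clip(img, 0.0, 1.0)


def _ellipse_mask(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    h, w = shape
    cy = rng.uniform(0.38, 0.62) * h
    cx = rng.uniform(0.38, 0.62) * w
    ry = rng.uniform(0.18, 0.30) * h
    rx = rng.uniform(0.18, 0.30) * w
    theta = rng.uniform(0, np.pi)
    yy, xx = np.mgrid[:h, :w]
    y0, x0 = yy - cy, xx - cx
    u = np.cos(theta) * x0 + np.sin(theta) * y0
    v = -np.sin(theta) * x0 + np.cos(theta) * y0
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def _poly_trend(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Smooth random quadratic surface scaled to [0, 1]."""
    h, w = shape
    y = np.linspace(-1, 1, h)[:, None]
    x = np.linspace(-1, 1, w)[None, :]
    c = rng.uniform(-1, 1, size=6)
    t = c[0] + c[1] * x + c[2] * y + c[3] * x * y + c[4] * x ** 2 + c[5] * y ** 2
    t = t - t.min()
    rng_span = t.max()
    return t / rng_span if rng_span > 0 else np.zeros(shape)


def gen_phantom(shape: tuple[int, int] = (400, 400),
                inside: TextureParams = TextureParams(band=(0.03, 0.12)),
                outside: TextureParams = TextureParams(band=(0.18, 0.45)),
                trend_amplitude: float = 0.0,
                seed: int = 0,
                patch_size: int = 20,
                max_retries: int = 10) -> Phantom:
    """Two-texture phantom: elliptical organ-like region on a background.

    Inside and outside are filled from independent band-limited
    textures; a smooth additive intensity trend of the given amplitude
    covers the whole image.  The ellipse is randomised (seeded) and
    regenerated if it covers fewer than four whole patches.
    """
    rng = np.random.default_rng(seed)
    min_area = 4 * patch_size * patch_size
    for attempt in range(max_retries):
        mask = _ellipse_mask(shape, rng)
        if mask.sum() >= min_area:
            break
        warnings.warn("degenerate phantom mask; retrying", RuntimeWarning, stacklevel=2)
    else:
        raise RuntimeError("could not draw a non-degenerate phantom mask")
    tex_in = gen_texture(inside, shape, rng)
    tex_out = gen_texture(outside, shape, rng)
    img = np.where(mask, tex_in, tex_out)
    if trend_amplitude != 0:
        img = img + trend_amplitude * _poly_trend(shape, rng)
    img = np.clip(img, 0.0, 1.0)
    return Phantom(img, mask.astype(np.uint8), inside, outside, float(trend_amplitude), seed)
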