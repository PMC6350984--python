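"""Patch-wise unsupervised segmentation and its evaluation.

The image is tiled into non-overlapping square patches (20x20 pixels by
default), each patch runs through the texture pipeline (signal
conversion -> wavelet bands -> AR spectra -> 30 energy ratios), and the
patch feature vectors are clustered into two groups with k-means.
Energy ratios are strictly positive ratio-scale quantities spanning
orders of magnitude with heavy-tailed speckle-driven outliers, so
features are log-transformed and robust-scaled per column (median /
interquartile range) before clustering; with plain z-scoring single
extreme-ratio patches dominate the Euclidean geometry and k-means
degenerates.

K-means does not know which cluster is the target tissue.  Two
assignment modes exist:

* ``oracle`` — choose the cluster-to-class mapping with the larger Dice
  overlap against a ground-truth mask (the standard way to score an
  unsupervised segmentation);
* ``centroid_reference`` — label the cluster whose centroid (in
  z-scored feature space) is nearer to a stored reference centroid,
  for use without ground truth.

Evaluation is pixel-level over the tiled region only: Dice
2TP/(2TP+FP+FN), sensitivity TP/(TP+FN), specificity TN/(TN+FP).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .armodel import fit_band_spectra
from .bands import BandSignal, get_bank
from .config import DEFAULT_CONFIG, PipelineConfig
from .features import FEATURE_NAMES, compute_features
from .imgsig import convert_all

__all__ = [
    "PatchGrid",
    "SegmentationResult",
    "EvalMetrics",
    "tile",
    "patch_features",
    "featurize_image",
    "cluster_patches",
    "evaluate",
]


@dataclass(frozen=True)
class PatchGrid:
    patch_size: int
    n_rows: int
    n_cols: int
    image_shape: tuple[int, int]

    @property
    def n_patches(self) -> int:
        return self.n_rows * self.n_cols

    def patch_slices(self, row: int, col: int) -> tuple[slice, slice]:
        s = self.patch_size
        return slice(row * s, (row + 1) * s), slice(col * s, (col + 1) * s)

    def covered_shape(self) -> tuple[int, int]:
        return self.n_rows * self.patch_size, self.n_cols * self.patch_size


@dataclass(frozen=True)
class SegmentationResult:
    patch_labels: np.ndarray  # (n_rows, n_cols) in {0, 1}
    pixel_mask: np.ndarray  # (H, W) uint8 in {0, 1}; constant per patch, 0 outside the grid
    grid: PatchGrid
    assignment: str


@dataclass(frozen=True)
class EvalMetrics:
    dice: float
    sensitivity: float
    specificity: float
    tp: int
    fp: int
    tn: int
    fn: int

    def to_dict(self) -> dict:
        return {
            "dice": self.dice, "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
        }


def tile(image: np.ndarray, patch_size: int = 20) -> PatchGrid:
    """Non-overlapping patch grid anchored at (0, 0); border strips that do
    not fill a whole patch are excluded."""
    h, w = np.asarray(image).shape[:2]
    if h < patch_size or w < patch_size:
        raise ValueError(f"image {h}x{w} smaller than one {patch_size}x{patch_size} patch")
    return PatchGrid(patch_size, h // patch_size, w // patch_size, (h, w))


def patch_features(patch: np.ndarray, cfg: PipelineConfig = DEFAULT_CONFIG,
                   patch_row: int = 0, patch_col: int = 0):
    """Full texture pipeline for one gray-level patch (values in [0, 1])."""
    patch = np.asarray(patch, dtype=float)
    if np.ptp(patch) == 0:
        raise ValueError("constant patch has no texture to characterise")
    signals = convert_all(patch)
    bank = get_bank(cfg.bands)
    band_signals = []
    for sig in signals:
        per_band = bank.band_signals(sig.samples)
        band_signals.extend(
            BandSignal(per_band[b], b, sig.conversion_id) for b in ("LF", "MF", "HF", "TB")
        )
    spectra = fit_band_spectra(band_signals, cfg.ar)
    return compute_features(spectra, patch_row, patch_col)


def featurize_image(image: np.ndarray, cfg: PipelineConfig = DEFAULT_CONFIG
                    ) -> tuple[np.ndarray, PatchGrid]:
    """Feature matrix (n_patches x 30) of an image, rows ordered by (row, col)."""
    image = np.asarray(image, dtype=float)
    grid = tile(image, cfg.segment.patch_size)
    feats = np.empty((grid.n_patches, len(FEATURE_NAMES)))
    k = 0
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            sl = grid.patch_slices(r, c)
            try:
                feats[k] = patch_features(image[sl], cfg, r, c).values
            except Exception as exc:  # re-raise with patch coordinates
                raise RuntimeError(f"feature extraction failed at patch ({r}, {c})") from exc
            k += 1
    return feats, grid


def _scale_features(features: np.ndarray, log: bool = True) -> np.ndarray:
    """Log-transform and robust-scale (median/IQR) the feature columns.

    The IQR is immune to the heavy-tailed outliers that speckle induces
    in a few extreme-ratio patches; zero-spread columns are dropped.
    """
    if log:
        features = np.log(features)
    med = np.median(features, axis=0)
    q75, q25 = np.percentile(features, [75, 25], axis=0)
    spread = q75 - q25
    keep = spread > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-spread feature column(s)",
                      RuntimeWarning, stacklevel=3)
    if not keep.any():
        raise ValueError("all feature columns are constant; nothing to cluster")
    return (features[:, keep] - med[keep]) / spread[keep]


def paint_mask(grid: PatchGrid, patch_labels: np.ndarray) -> np.ndarray:
    mask = np.zeros(grid.image_shape, dtype=np.uint8)
    s = grid.patch_size
    core = np.kron(patch_labels.astype(np.uint8), np.ones((s, s), dtype=np.uint8))
    mask[: grid.n_rows * s, : grid.n_cols * s] = core
    return mask


def cluster_patches(features: np.ndarray, grid: PatchGrid, seed: int = 0,
                    cfg: PipelineConfig = DEFAULT_CONFIG,
                    reference_centroid: np.ndarray | None = None) -> SegmentationResult:
    """Two-cluster k-means over z-scored patch features.

    Returned labels are raw cluster indices unless ``centroid_reference``
    assignment is configured and a reference centroid is given, in which
    case label 1 is the cluster nearest the reference.
    """
    features = np.asarray(features, dtype=float)
    if features.shape[0] < 2:
        raise ValueError("need at least 2 patches to cluster")
    z = _scale_features(features)
    km = KMeans(n_clusters=2, n_init=cfg.segment.n_init, random_state=seed)
    labels = km.fit_predict(z)
    assignment = "raw"
    if cfg.segment.assignment == "centroid_reference" and reference_centroid is not None:
        d = np.linalg.norm(km.cluster_centers_ - np.asarray(reference_centroid), axis=1)
        target = int(np.argmin(d))
        labels = (labels == target).astype(int)
        assignment = "centroid_reference"
    patch_labels = labels.reshape(grid.n_rows, grid.n_cols)
    return SegmentationResult(patch_labels, paint_mask(grid, patch_labels), grid, assignment)


def _confusion(pred: np.ndarray, gt: np.ndarray) -> tuple[int, int, int, int]:
    p = pred.astype(bool)
    g = gt.astype(bool)
    tp = int(np.sum(p & g))
    fp = int(np.sum(p & ~g))
    fn = int(np.sum(~p & g))
    tn = int(np.sum(~p & ~g))
    return tp, fp, tn, fn


def _metrics(tp: int, fp: int, tn: int, fn: int) -> EvalMetrics:
    dice = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 1.0
    se = tp / (tp + fn) if (tp + fn) else 1.0
    sp = tn / (tn + fp) if (tn + fp) else 1.0
    return EvalMetrics(dice, se, sp, tp, fp, tn, fn)


def evaluate(result: SegmentationResult | np.ndarray, gt_mask: np.ndarray,
             grid: PatchGrid | None = None, oracle: bool = True) -> EvalMetrics:
    """Pixel-level Dice/SE/SP of a segmentation against ground truth.

    With ``oracle=True`` (and a :class:`SegmentationResult` whose labels
    are raw cluster indices) the cluster-to-class mapping maximising
    Dice is chosen before scoring.  Only pixels inside the tiled region
    are counted.
    """
    if isinstance(result, SegmentationResult):
        pred = result.pixel_mask
        grid = result.grid
        already_assigned = result.assignment == "centroid_reference"
    else:
        pred = np.asarray(result)
        already_assigned = True
    gt = np.asarray(gt_mask)
    if pred.shape != gt.shape:
        raise ValueError(f"mask shape {pred.shape} != ground truth shape {gt.shape}")
    if grid is not None:
        hc, wc = grid.covered_shape()
        pred = pred[:hc, :wc]
        gt = gt[:hc, :wc]
    tp, fp, tn, fn = _confusion(pred, gt)
    if oracle and not already_assigned:
        m0 = _metrics(tp, fp, tn, fn)
        m1 = _metrics(fn, tn, fp, tp)  # swapped cluster identity
        return m0 if m0.dice >= m1.dice else m1
    return _metrics(tp, fp, tn, fn)
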