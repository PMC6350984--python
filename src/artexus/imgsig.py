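"""Matrix-to-signal conversion of gray-level patches.

A 2-D patch is turned into four 1-D texture signals by traversing the
matrix, and its 90-degree-rotated version, in zigzag (boustrophedon)
and clockwise-spiral order.  Every traversal is a bijection between
pixels and signal samples, so each signal is a permutation of the patch
values and the patch can be reconstructed from any one of them.

Conventions (frozen for reproducibility): the zigzag starts at element
(0, 0) moving right and alternates row direction; the spiral starts at
(0, 0) and winds clockwise inward; the rotation is a counter-clockwise
quarter turn.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TextureSignal",
    "validate_patch",
    "zigzag_scan",
    "spiral_scan",
    "zigzag_indices",
    "spiral_indices",
    "rotate90",
    "convert_all",
]


@dataclass(frozen=True)
class TextureSignal:
    """1-D signal obtained from one matrix-to-signal conversion.

    ``conversion_id`` is 1 for zigzag, 2 for zigzag of the rotated
    patch, 3 for spiral, 4 for spiral of the rotated patch.
    """

    samples: np.ndarray
    conversion_id: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.samples.ndim != 1:
            raise ValueError("samples must be 1-D")
        if self.conversion_id not in (1, 2, 3, 4):
            raise ValueError("conversion_id must be in 1..4")

    def __len__(self) -> int:
        return self.samples.size


def validate_patch(patch: np.ndarray) -> np.ndarray:
    patch = np.asarray(patch, dtype=float)
    if patch.ndim != 2 or patch.size == 0:
        raise ValueError("patch must be a non-empty 2-D array")
    if not np.all(np.isfinite(patch)):
        raise ValueError("patch contains non-finite values")
    return patch


def zigzag_indices(h: int, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column index arrays of the boustrophedon row traversal."""
    rows = np.repeat(np.arange(h), w)
    cols = np.tile(np.arange(w), h).reshape(h, w)
    cols[1::2] = cols[1::2, ::-1]
    return rows, cols.ravel()


def spiral_indices(h: int, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column index arrays of the clockwise inward spiral from (0, 0)."""
    rows: list[int] = []
    cols: list[int] = []
    top, bottom, left, right = 0, h - 1, 0, w - 1
    while top <= bottom and left <= right:
        for c in range(left, right + 1):
            rows.append(top), cols.append(c)
        for r in range(top + 1, bottom + 1):
            rows.append(r), cols.append(right)
        if bottom > top:
            for c in range(right - 1, left - 1, -1):
                rows.append(bottom), cols.append(c)
        if right > left:
            for r in range(bottom - 1, top, -1):
                rows.append(r), cols.append(left)
        top, bottom, left, right = top + 1, bottom - 1, left + 1, right - 1
    return np.array(rows, dtype=int), np.array(cols, dtype=int)


def zigzag_scan(patch: np.ndarray, conversion_id: int = 1) -> TextureSignal:
    """Boustrophedon row traversal: row 0 left-to-right, row 1 reversed, ..."""
    patch = validate_patch(patch)
    r, c = zigzag_indices(*patch.shape)
    return TextureSignal(patch[r, c], conversion_id)


def spiral_scan(patch: np.ndarray, conversion_id: int = 3) -> TextureSignal:
    """Clockwise inward spiral traversal starting at the top-left corner."""
    patch = validate_patch(patch)
    r, c = spiral_indices(*patch.shape)
    return TextureSignal(patch[r, c], conversion_id)


def rotate90(patch: np.ndarray) -> np.ndarray:
    """Counter-clockwise quarter turn; (r, c) -> (W-1-c, r), four applications are the identity."""
    return np.rot90(validate_patch(patch))


def convert_all(patch: np.ndarray) -> list[TextureSignal]:
    """The four texture signals of a patch: zigzag, rotated zigzag, spiral, rotated spiral."""
    patch = validate_patch(patch)
    rot = rotate90(patch)
    return [
        zigzag_scan(patch, 1),
        zigzag_scan(rot, 2),
        spiral_scan(patch, 3),
        spiral_scan(rot, 4),
    ]
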