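"""Gramian angular field encoders: GASF, GADF, and the fused IGAF variant.

A [-1, 1] normalized series x̃ is mapped to polar angles φ = arccos(x̃); the
summation field is cos(φ_i + φ_j), the difference field sin(φ_i − φ_j), and
the fused image takes the difference field on the upper triangle (diagonal
included) and the summation field on the strict lower triangle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
from PIL import Image
from skimage.transform import resize as _skimage_resize

from .prep import NormalizedSeries

Variant = Literal["GASF", "GADF", "IGAF"]


class RangeError(ValueError):
    """Raised when series values fall outside the arccos domain."""


@dataclass(frozen=True)
class GafImage:
    """An N×N angular-field image with its variant tag."""

    matrix: np.ndarray
    variant: Variant

    @property
    def side(self) -> int:
        return self.matrix.shape[0]


def _as_values(series: NormalizedSeries | np.ndarray) -> np.ndarray:
    if isinstance(series, NormalizedSeries):
        if series.range_mode != "[-1,1]":
            raise ValueError("GAF encoding requires [-1,1] normalization")
        return series.values
    return np.asarray(series, dtype=np.float64)


def to_polar(series: NormalizedSeries | np.ndarray) -> np.ndarray:
    """Map x̃ ∈ [-1, 1] to angles φ = arccos(x̃) ∈ [0, π].

    Values are clipped to [-1, 1] only within 1e-12 rounding slack; anything
    farther out raises :class:`RangeError`.
    """
    x = _as_values(series)
    if x.size and (x.min() < -1.0 - 1e-12 or x.max() > 1.0 + 1e-12):
        raise RangeError("series values outside [-1-1e-12, 1+1e-12]")
    return np.arccos(np.clip(x, -1.0, 1.0))


def gasf(series: NormalizedSeries | np.ndarray) -> GafImage:
    """Summation field cos(φ_i + φ_j); symmetric, values in [-1, 1]."""
    phi = to_polar(series)
    if phi.size < 2:
        raise ValueError("series must have length >= 2")
    return GafImage(matrix=np.cos(phi[:, None] + phi[None, :]), variant="GASF")


def gadf(series: NormalizedSeries | np.ndarray) -> GafImage:
    """Difference field sin(φ_i − φ_j); antisymmetric with a zero diagonal."""
    phi = to_polar(series)
    if phi.size < 2:
        raise ValueError("series must have length >= 2")
    mat = np.sin(phi[:, None] - phi[None, :])
    np.fill_diagonal(mat, 0.0)
    return GafImage(matrix=mat, variant="GADF")


def igaf(series: NormalizedSeries | np.ndarray) -> GafImage:
    """Fused field: GADF where i ≤ j, GASF where i > j.

    The diagonal belongs to the difference branch and is therefore zero.
    """
    d = gadf(series).matrix
    s = gasf(series).matrix
    i, j = np.indices(d.shape)
    return GafImage(matrix=np.where(i <= j, d, s), variant="IGAF")


def resize_square(image: np.ndarray, target_side: int, method: str = "bilinear") -> np.ndarray:
    """Bilinear resize of a square image; values clamped to the input range."""
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2 or img.shape[0] != img.shape[1]:
        raise ValueError("input must be a square 2-D image")
    if target_side < 1:
        raise ValueError("target_side must be >= 1")
    if method != "bilinear":
        raise ValueError(f"unsupported method {method!r}")
    if target_side == img.shape[0]:
        return img.copy()
    out = _skimage_resize(
        img,
        (target_side, target_side),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return np.clip(out, img.min(), img.max())


def export_png(image: GafImage | np.ndarray, path: str | Path,
               value_range: tuple[float, float] = (-1.0, 1.0)) -> None:
    """Write an 8-bit grayscale PNG via an affine map of ``value_range`` to [0, 255]."""
    mat = image.matrix if isinstance(image, GafImage) else np.asarray(image)
    lo, hi = value_range
    scaled = np.clip((mat - lo) / (hi - lo), 0.0, 1.0)
    Image.fromarray(np.round(scaled * 255).astype(np.uint8), mode="L").save(path)


def export_matrix(image: GafImage | np.ndarray, path: str | Path,
                  metadata: dict | None = None) -> None:
    """Write the float matrix losslessly (.npy) with a JSON metadata sidecar."""
    mat = image.matrix if isinstance(image, GafImage) else np.asarray(image)
    path = Path(path)
    np.save(path, mat)
    meta = dict(metadata or {})
    if isinstance(image, GafImage):
        meta.setdefault("variant", image.variant)
    meta.setdefault("side", int(mat.shape[0]))
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=2)
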