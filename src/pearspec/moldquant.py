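"""Moldy-core quantification and grading from cross-section photographs.

Procedure: trace the cross-section contour with Canny edge detection and fill
it, iteratively threshold the blue channel inside the contour (browning
darkens blue), label below-threshold pixels with 8-connectivity, drop speckle
components, and report S = mold area / cross-section area × 100 together with
the three-level grade.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Literal

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import feature

Grade = Literal["healthy", "slight", "severe"]

#: grade boundary between slight and severe, in percent
SEVERE_THRESHOLD = 10.0
#: default tolerance on the S = 0 boundary (pixel noise allowance), percent
DEFAULT_HEALTHY_EPS = 0.1
#: default minimum component area (pixels) kept as mold
DEFAULT_MIN_AREA = 20

_STRUCT8 = np.ones((3, 3), dtype=bool)


class SegmentationError(RuntimeError):
    """Raised when no closed cross-section contour can be found."""


class DegenerateInputError(ValueError):
    """Raised when a plane is constant and thresholding is undefined."""


@dataclass(frozen=True)
class MoldQuantResult:
    """Quantification outcome: areas, percentage S, and grade."""

    S1: int  # mold area, pixels
    S2: int  # cross-section area, pixels
    S: float  # S1 / S2 * 100
    grade: Grade
    component_count: int

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def load_image(path: str | Path) -> np.ndarray:
    """Load a PNG/JPEG as an HxWx3 uint8 array."""
    return np.asarray(Image.open(path).convert("RGB"))


def split_channels(image: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split an RGB image into its R, G, B planes (lossless)."""
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an HxWx3 RGB image")
    return img[..., 0], img[..., 1], img[..., 2]


def cross_section_mask(image: np.ndarray) -> tuple[np.ndarray, int]:
    """Segment the cross-section: Canny edges → largest filled contour.

    Hysteresis thresholds are derived from the image median (0.66/1.33 of the
    median on the 8-bit scale). Edges are morphologically closed, holes
    filled, and the largest connected region kept.
    """
    img = np.asarray(image)
    if img.ndim == 3:
        gray = img.astype(np.float64).mean(axis=2)
    else:
        gray = img.astype(np.float64)
    med = np.median(gray)
    low, high = 0.66 * med, 1.33 * med
    edges = feature.canny(gray, sigma=2.0, low_threshold=low, high_threshold=high)
    closed = ndimage.binary_closing(edges, structure=_STRUCT8, iterations=2)
    filled = ndimage.binary_fill_holes(closed)
    labels, n = ndimage.label(filled, structure=_STRUCT8)
    if n == 0:
        raise SegmentationError("no closed cross-section contour found")
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    best = int(np.argmax(areas)) + 1
    mask = labels == best
    area = int(mask.sum())
    # a filled contour must enclose real area, not just an edge ribbon
    if area < 0.005 * mask.size:
        raise SegmentationError("largest contour region is implausibly small")
    return mask, area


def iterative_threshold(plane: np.ndarray, mask: np.ndarray | None = None,
                        tol: float = 0.5) -> float:
    """Ridler–Calvard fixed point: T ← (mean(values≤T) + mean(values>T)) / 2."""
    vals = np.asarray(plane, dtype=np.float64)
    if mask is not None:
        vals = vals[mask]
    vals = vals.ravel()
    if vals.size == 0 or vals.max() <= vals.min():
        raise DegenerateInputError("constant plane: threshold undefined")
    t = vals.mean()
    for _ in range(500):
        lower = vals[vals <= t]
        upper = vals[vals > t]
        if lower.size == 0 or upper.size == 0:
            break
        t_new = 0.5 * (lower.mean() + upper.mean())
        if abs(t_new - t) < tol:
            return float(t_new)
        t = t_new
    return float(t)


def label_components_8(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """8-connectivity component labeling; returns (label image, per-component areas)."""
    labels, n = ndimage.label(np.asarray(mask, dtype=bool), structure=_STRUCT8)
    if n == 0:
        return labels, np.zeros(0, dtype=np.int64)
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return labels, areas.astype(np.int64)


def grade(S: float, healthy_eps: float = DEFAULT_HEALTHY_EPS) -> Grade:
    """Map the percentage S onto {healthy, slight, severe}.

    S ≤ healthy_eps → healthy; healthy_eps < S ≤ 10 → slight; S > 10 →
    severe. The 10% boundary is inclusive on the slight side.
    """
    if not (0.0 <= S <= 100.0):
        raise ValueError("S must lie in [0, 100]")
    if S <= healthy_eps:
        return "healthy"
    if S <= SEVERE_THRESHOLD:
        return "slight"
    return "severe"


def quantify(
    image: np.ndarray,
    min_area: int = DEFAULT_MIN_AREA,
    healthy_eps: float = DEFAULT_HEALTHY_EPS,
    edge_margin: int = 3,
) -> MoldQuantResult:
    """Full quantification of one RGB cross-section image.

    The blue plane is thresholded only inside the (slightly eroded)
    cross-section mask so contour-transition pixels cannot masquerade as
    mold; components smaller than ``min_area`` are discarded as speckle. A
    blue plane whose within-mask spread is at the noise floor is treated as
    mold-free rather than split in half by the iterative threshold.
    """
    _, _, blue = split_channels(image)
    mask, s2 = cross_section_mask(image)
    inner = ndimage.binary_erosion(mask, structure=_STRUCT8, iterations=edge_margin)
    vals = blue[inner].astype(np.float64)
    s1 = 0
    n_components = 0
    # bimodality guard: threshold only if the spread exceeds sensor noise
    if vals.size and (vals.max() - vals.min()) > 25.0:
        t = iterative_threshold(blue, mask=inner)
        mold_mask = inner & (blue.astype(np.float64) < t)
        labels, areas = label_components_8(mold_mask)
        keep = areas >= min_area
        n_components = int(keep.sum())
        s1 = int(areas[keep].sum())
    S = 100.0 * s1 / s2
    return MoldQuantResult(S1=s1, S2=s2, S=S, grade=grade(S, healthy_eps),
                           component_count=n_components)
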