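"""Laplacian-pyramid Markov transition field encoder.

Pipeline: piecewise aggregate approximation → equal-frequency quantile
discretization → first-order transition matrix W → field expansion
M[i,j] = W[s_i, s_j] → 3-level Laplacian pyramid → weighted layer fusion →
min-max mapping into [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve1d
from skimage.transform import resize as _skimage_resize

DEFAULT_Q = 12
DEFAULT_WINDOW = 5
DEFAULT_LEVELS = 3

# Burt–Adelson 5-tap binomial kernel
_KERNEL5 = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


@dataclass(frozen=True)
class StateSequence:
    """Integer states in [0, q-1] from equal-frequency quantile binning."""

    states: np.ndarray
    q: int
    bin_edges: np.ndarray


@dataclass(frozen=True)
class TransitionModel:
    """q×q first-order transition probability matrix W."""

    W: np.ndarray

    @property
    def q(self) -> int:
        return self.W.shape[0]


@dataclass(frozen=True)
class MtfField:
    """Expanded transition field M with M[i,j] = W[s_i, s_j]."""

    M: np.ndarray


@dataclass(frozen=True)
class PyramidStack:
    """Gaussian levels G0..Gk and Laplacian band-pass levels L0..L(k-1)."""

    gaussian: tuple[np.ndarray, ...]
    laplacian: tuple[np.ndarray, ...]


def paa(series: np.ndarray, window_size: int = DEFAULT_WINDOW) -> np.ndarray:
    """Non-overlapping window means; a trailing partial window is dropped."""
    x = np.asarray(series, dtype=np.float64)
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    if x.ndim != 1 or x.size < window_size:
        raise ValueError("series must be 1-D with length >= window_size")
    n_out = x.size // window_size
    return x[: n_out * window_size].reshape(n_out, window_size).mean(axis=1)


def quantile_discretize(series: np.ndarray, q: int = DEFAULT_Q) -> StateSequence:
    """Assign each point a state in [0, q-1] by rank-based equal-frequency binning.

    With n points, the point of (stable) rank r gets state ``r * q // n``, so
    bin occupancies differ by at most one when values are distinct; ties are
    broken by original order.
    """
    x = np.asarray(series, dtype=np.float64)
    if q < 2:
        raise ValueError("q must be >= 2")
    if x.size < q:
        raise ValueError("series length must be >= q")
    order = np.argsort(x, kind="stable")
    ranks = np.empty(x.size, dtype=np.intp)
    ranks[order] = np.arange(x.size)
    states = (ranks * q) // x.size
    # value thresholds between consecutive occupied bins (diagnostic only)
    sorted_vals = x[order]
    boundaries = [(k * x.size + q - 1) // q for k in range(1, q)]
    edges = np.array([sorted_vals[min(b, x.size - 1)] for b in boundaries])
    return StateSequence(states=states.astype(np.int64), q=q, bin_edges=edges)


def transition_matrix(states: np.ndarray | StateSequence, q: int | None = None) -> TransitionModel:
    """First-order transition probabilities between adjacent states.

    W[i, j] = (#adjacent pairs i→j) / (#pairs leaving i); rows with no
    outgoing observation are left all-zero.
    """
    if isinstance(states, StateSequence):
        q = states.q if q is None else q
        s = states.states
    else:
        s = np.asarray(states, dtype=np.int64)
        if q is None:
            raise ValueError("q is required when passing a raw state vector")
    if s.size < 2:
        raise ValueError("need at least 2 states")
    if s.min() < 0 or s.max() >= q:
        raise ValueError("state out of range [0, q)")
    counts = np.zeros((q, q), dtype=np.float64)
    np.add.at(counts, (s[:-1], s[1:]), 1.0)
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        W = np.where(row_sums > 0, counts / np.where(row_sums > 0, row_sums, 1.0), 0.0)
    return TransitionModel(W=W)


def mtf_expand(states: np.ndarray | StateSequence, model: TransitionModel) -> MtfField:
    """Expand W into the field M[i, j] = W[s_i, s_j]."""
    s = states.states if isinstance(states, StateSequence) else np.asarray(states, dtype=np.int64)
    if s.min() < 0 or s.max() >= model.q:
        raise ValueError("state out of range for transition model")
    return MtfField(M=model.W[s[:, None], s[None, :]])


def _blur(image: np.ndarray) -> np.ndarray:
    out = convolve1d(image, _KERNEL5, axis=0, mode="reflect")
    return convolve1d(out, _KERNEL5, axis=1, mode="reflect")


def _downsample(image: np.ndarray) -> np.ndarray:
    return _blur(image)[::2, ::2]


def _upsample(image: np.ndarray, target_side: int) -> np.ndarray:
    return _skimage_resize(
        image,
        (target_side, target_side),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )


def build_pyramids(image: np.ndarray, levels: int = DEFAULT_LEVELS) -> PyramidStack:
    """Gaussian + Laplacian pyramid with L_k = G_k − upsample(G_{k+1}).

    Reconstruction G_k = L_k + upsample(G_{k+1}) holds exactly by
    construction because the same bilinear upsampler defines both sides.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2 or img.shape[0] != img.shape[1]:
        raise ValueError("image must be square")
    if img.shape[0] < 2**levels:
        raise ValueError(f"image side must be >= {2**levels} for {levels} levels")
    gaussian = [img]
    for _ in range(levels):
        gaussian.append(_downsample(gaussian[-1]))
    laplacian = [
        gaussian[k] - _upsample(gaussian[k + 1], gaussian[k].shape[0])
        for k in range(levels)
    ]
    return PyramidStack(gaussian=tuple(gaussian), laplacian=tuple(laplacian))


def fuse_pyramid(stack: PyramidStack, weights: np.ndarray | None = None) -> np.ndarray:
    """Upsample all layers to the base side, combine as Σ w_k·layer_k, rescale to [0, 1].

    Layers are L0..L(k-1) followed by the coarsest Gaussian level. Weights
    must be non-negative and sum to 1 (default: equal). A constant fused map
    degenerates to all zeros.
    """
    layers = list(stack.laplacian) + [stack.gaussian[-1]]
    n = len(layers)
    w = np.full(n, 1.0 / n) if weights is None else np.asarray(weights, dtype=np.float64)
    if w.size != n:
        raise ValueError(f"expected {n} weights, got {w.size}")
    if np.any(w < 0):
        raise ValueError("weights must be >= 0")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1 within 1e-9")
    side = stack.gaussian[0].shape[0]
    fused = np.zeros((side, side), dtype=np.float64)
    for wk, layer in zip(w, layers):
        fused += wk * (_upsample(layer, side) if layer.shape[0] != side else layer)
    lo, hi = fused.min(), fused.max()
    if hi <= lo:
        return np.zeros_like(fused)
    return (fused - lo) / (hi - lo)


def lpmtf(
    series: np.ndarray,
    q: int = DEFAULT_Q,
    window_size: int = DEFAULT_WINDOW,
    weights: np.ndarray | None = None,
    levels: int = DEFAULT_LEVELS,
) -> np.ndarray:
    """Full encoder: series of length N → square [0, 1] image of side N // window_size."""
    x = np.asarray(series, dtype=np.float64)
    if x.size < q * window_size:
        raise ValueError("series length must be >= q * window_size")
    reduced = paa(x, window_size)
    seq = quantile_discretize(reduced, q)
    model = transition_matrix(seq)
    field = mtf_expand(seq, model)
    stack = build_pyramids(field.M, levels=levels)
    return fuse_pyramid(stack, weights)
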