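"""Minimal vision primitives: patch tokenization, scaled dot-product attention,
the depthwise-separable convolution cost ratio, and a tiny trainable
patch-attention classifier for end-to-end smoke tests on encoded images.

The full-scale transformer is out of scope; what lives here is the token
arithmetic, the attention math, and a desk-scale model (patch embedding →
one self-attention block → mean pool → linear head) trained by gradient
descent in plain numpy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass(frozen=True)
class PatchGrid:
    """Non-overlapping square patch layout over a square image."""

    image_side: int
    patch_size: int
    tokens_per_side: int
    token_count: int


@dataclass(frozen=True)
class DscCostInputs:
    """Parameters of the depthwise-separable vs standard convolution cost model."""

    D_K: int  # kernel side
    M_in: int  # input channels
    N_out: int  # output channels
    D_F: int  # feature-map side

    def __post_init__(self) -> None:
        if min(self.D_K, self.M_in, self.N_out, self.D_F) < 1:
            raise ValueError("all cost-model parameters must be positive integers")


def patch_tokens(image_side: int, patch_size: int = 16) -> PatchGrid:
    """Token layout for 16×16-style patching; remainder pixels are cropped."""
    if image_side < patch_size:
        raise ValueError("image_side must be >= patch_size")
    if patch_size < 1:
        raise ValueError("patch_size must be >= 1")
    per_side = image_side // patch_size
    return PatchGrid(image_side=image_side, patch_size=patch_size,
                     tokens_per_side=per_side, token_count=per_side * per_side)


def _softmax(x: np.ndarray) -> np.ndarray:
    e = np.exp(x - x.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def attention(Q: np.ndarray, K: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Scaled dot-product attention softmax(QKᵀ/√d_k)V."""
    Q, K, V = (np.asarray(m, dtype=np.float64) for m in (Q, K, V))
    if Q.shape[-1] != K.shape[-1]:
        raise ValueError("Q and K must share the key dimension d_k")
    if K.shape[-2] != V.shape[-2]:
        raise ValueError("K and V must share the token count")
    d_k = Q.shape[-1]
    weights = _softmax(Q @ np.swapaxes(K, -1, -2) / np.sqrt(d_k))
    return weights @ V


def multi_head(Q: np.ndarray, K: np.ndarray, V: np.ndarray, h: int,
               w_o: np.ndarray | None = None) -> np.ndarray:
    """Multi-head attention: per-head attention on column slices, concat, project.

    The model dimension must divide evenly into ``h`` heads; ``w_o`` defaults
    to the identity projection.
    """
    Q, K, V = (np.asarray(m, dtype=np.float64) for m in (Q, K, V))
    d_model = Q.shape[-1]
    if d_model % h != 0 or V.shape[-1] % h != 0:
        raise ValueError("model dimension must be divisible by the head count")
    d_h = d_model // h
    d_v = V.shape[-1] // h
    heads = [
        attention(Q[..., i * d_h:(i + 1) * d_h],
                  K[..., i * d_h:(i + 1) * d_h],
                  V[..., i * d_v:(i + 1) * d_v])
        for i in range(h)
    ]
    out = np.concatenate(heads, axis=-1)
    if w_o is not None:
        out = out @ np.asarray(w_o, dtype=np.float64)
    return out


def dsc_cost_standard(inputs: DscCostInputs) -> int:
    """Multiply–add cost of a standard convolution layer."""
    return inputs.D_K**2 * inputs.M_in * inputs.N_out * inputs.D_F**2


def dsc_cost_separable(inputs: DscCostInputs) -> int:
    """Multiply–add cost of the depthwise + pointwise decomposition."""
    return (inputs.D_K**2 * inputs.M_in * inputs.D_F**2
            + inputs.M_in * inputs.N_out * inputs.D_F**2)


def dsc_cost_ratio(inputs: DscCostInputs) -> float:
    """Closed-form cost reduction ratio 1/N_out + 1/D_K²."""
    return 1.0 / inputs.N_out + 1.0 / inputs.D_K**2


# ---------------------------------------------------------------------------
# Tiny trainable patch-attention classifier
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ToyConfig:
    patch_size: int = 12
    embed_dim: int = 16
    epochs: int = 150
    lr: float = 0.01
    use_attention: bool = True


@dataclass
class ToyModel:
    config: ToyConfig
    n_classes: int
    params: dict[str, np.ndarray] = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.params)
        cfg = {
            "patch_size": self.config.patch_size,
            "embed_dim": self.config.embed_dim,
            "epochs": self.config.epochs,
            "lr": self.config.lr,
            "use_attention": self.config.use_attention,
            "n_classes": self.n_classes,
        }
        path.with_suffix(".json").write_text(json.dumps(cfg, indent=2))


def _patchify(images: np.ndarray, patch_size: int) -> np.ndarray:
    """(n, side, side) → (n, tokens, patch_size²), cropping the remainder."""
    n, side, _ = images.shape
    t = side // patch_size
    if t < 1:
        raise ValueError("image side smaller than patch size")
    crop = images[:, : t * patch_size, : t * patch_size]
    patches = crop.reshape(n, t, patch_size, t, patch_size)
    return patches.transpose(0, 1, 3, 2, 4).reshape(n, t * t, patch_size**2)


def _forward(params: dict, P: np.ndarray, use_attention: bool) -> tuple[np.ndarray, dict]:
    E = P @ params["We"] + params["be"]
    if use_attention:
        Q = E @ params["Wq"]
        K = E @ params["Wk"]
        V = E @ params["Wv"]
        d = Q.shape[-1]
        S = np.einsum("ntd,nsd->nts", Q, K) / np.sqrt(d)
        A = _softmax(S)
        Z = np.einsum("nts,nsd->ntd", A, V)
        cache = {"E": E, "Q": Q, "K": K, "V": V, "A": A}
    else:
        Z = E @ params["Wv"]  # per-patch feed-forward only: no token mixing
        cache = {"E": E}
    pooled = Z.mean(axis=1)
    logits = pooled @ params["Wc"] + params["bc"]
    cache.update({"P": P, "Z": Z, "pooled": pooled})
    return logits, cache


def _backward(params: dict, cache: dict, dlogits: np.ndarray,
              use_attention: bool) -> dict[str, np.ndarray]:
    P, Z, pooled = cache["P"], cache["Z"], cache["pooled"]
    grads = {
        "Wc": pooled.T @ dlogits,
        "bc": dlogits.sum(axis=0),
    }
    dpooled = dlogits @ params["Wc"].T
    dZ = np.repeat(dpooled[:, None, :], Z.shape[1], axis=1) / Z.shape[1]
    if use_attention:
        E, Q, K, V, A = cache["E"], cache["Q"], cache["K"], cache["V"], cache["A"]
        d = Q.shape[-1]
        dV = np.einsum("nts,ntd->nsd", A, dZ)
        dA = np.einsum("ntd,nsd->nts", dZ, V)
        # softmax Jacobian applied row-wise
        dS = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
        dQ = np.einsum("nts,nsd->ntd", dS, K) / np.sqrt(d)
        dK = np.einsum("nts,ntd->nsd", dS, Q) / np.sqrt(d)
        grads["Wq"] = np.einsum("ntd,nte->de", E, dQ)
        grads["Wk"] = np.einsum("ntd,nte->de", E, dK)
        grads["Wv"] = np.einsum("ntd,nte->de", E, dV)
        dE = dQ @ params["Wq"].T + dK @ params["Wk"].T + dV @ params["Wv"].T
    else:
        E = cache["E"]
        grads["Wv"] = np.einsum("ntd,nte->de", E, dZ)
        dE = dZ @ params["Wv"].T
    grads["We"] = np.einsum("ntp,ntd->pd", P, dE)
    grads["be"] = dE.sum(axis=(0, 1))
    return grads


def toy_attention_classifier(
    images: np.ndarray,
    labels: np.ndarray,
    config: ToyConfig | None = None,
    seed: int = 0,
) -> tuple[ToyModel, dict[str, float]]:
    """Train the tiny patch classifier by full-batch gradient descent.

    With ``use_attention`` off the token-mixing step is replaced by a
    per-patch feed-forward map, everything else unchanged. Deterministic for
    a fixed seed.
    """
    config = config or ToyConfig()
    images = np.asarray(images, dtype=np.float64)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    y = np.searchsorted(classes, labels)
    P = _patchify(images, config.patch_size)
    norm_mu, norm_sd = float(P.mean()), float(P.std() + 1e-9)
    P = (P - norm_mu) / norm_sd
    n, _, p2 = P.shape
    d = config.embed_dim
    rng = np.random.default_rng(seed)
    params = {
        "We": rng.normal(0, 1.0 / np.sqrt(p2), (p2, d)),
        "be": np.zeros(d),
        "Wq": rng.normal(0, 1.0 / np.sqrt(d), (d, d)),
        "Wk": rng.normal(0, 1.0 / np.sqrt(d), (d, d)),
        "Wv": rng.normal(0, 1.0 / np.sqrt(d), (d, d)),
        "Wc": rng.normal(0, 1.0 / np.sqrt(d), (d, classes.size)),
        "bc": np.zeros(classes.size),
    }
    # Adam state
    m = {k: np.zeros_like(v) for k, v in params.items()}
    v_state = {k: np.zeros_like(v) for k, v in params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    onehot = np.eye(classes.size)[y]
    loss = float("nan")
    for step in range(1, config.epochs + 1):
        logits, cache = _forward(params, P, config.use_attention)
        probs = _softmax(logits)
        loss = -np.log(probs[np.arange(n), y] + 1e-12).mean()
        dlogits = (probs - onehot) / n
        grads = _backward(params, cache, dlogits, config.use_attention)
        for k in params:
            if k not in grads:
                continue
            m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
            v_state[k] = beta2 * v_state[k] + (1 - beta2) * grads[k] ** 2
            m_hat = m[k] / (1 - beta1**step)
            v_hat = v_state[k] / (1 - beta2**step)
            params[k] -= config.lr * m_hat / (np.sqrt(v_hat) + eps)
    model = ToyModel(config=config, n_classes=classes.size, params=params)
    model.params["_norm"] = np.array([norm_mu, norm_sd])
    train_pred = classes[predict_toy(model, images, _classes=classes)]
    metrics = {
        "train_loss": float(loss),
        "train_accuracy": float(np.mean(train_pred == labels)),
    }
    model.params["_classes"] = classes
    return model, metrics


def predict_toy(model: ToyModel, images: np.ndarray,
                _classes: np.ndarray | None = None) -> np.ndarray:
    """Predict class indices (or labels when the model stores classes)."""
    images = np.asarray(images, dtype=np.float64)
    P = _patchify(images, model.config.patch_size)
    norm = model.params.get("_norm")
    if norm is not None:
        P = (P - norm[0]) / norm[1]
    else:
        P = (P - P.mean()) / (P.std() + 1e-9)
    logits, _ = _forward(model.params, P, model.config.use_attention)
    idx = np.argmax(logits, axis=1)
    if _classes is not None:
        return idx
    classes = model.params.get("_classes")
    return classes[idx] if classes is not None else idx
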