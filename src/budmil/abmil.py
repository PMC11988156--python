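"""Gated attention-based multiple instance learning (ABMIL).

The aggregator scores each instance embedding h_k with a gated two-branch
attention network,

    a_k = softmax_k( w^T ( tanh(V h_k) * sigm(U h_k) ) ),

pools the bag into z = sum_k a_k h_k, and classifies the bag with a linear
head p = sigm(c^T z + b) under bag-level binary cross-entropy.  The tanh
branch captures signed feature responses while the sigmoid branch acts as a
learned gate; their element-wise product feeds a single scoring vector w.

Everything here is plain numpy: the forward pass, an analytically derived
backward pass (verified against finite differences in the test-suite), and
the loss.  The optimizer lives in :mod:`budmil.experiment`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

BCE_EPS = 1e-7
CHECKPOINT_SCHEMA = "budmil-checkpoint-v1"


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    # stable for large |x|
    return np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500))),
                    np.exp(np.clip(x, -500, 500)) / (1.0 + np.exp(np.clip(x, -500, 500))))


@dataclass
class AttentionParams:
    """Learnable parameters: gated attention (V, U, w) + linear head (c, b).

    V and U are L x D with L the attention hidden width; w is an L-vector;
    the head maps the D-dim bag embedding to a logit.  No bias terms inside
    the attention branches by default.
    """

    V: np.ndarray
    U: np.ndarray
    w: np.ndarray
    c: np.ndarray
    b: float

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, dtype=np.float64)
        self.U = np.asarray(self.U, dtype=np.float64)
        self.w = np.asarray(self.w, dtype=np.float64)
        self.c = np.asarray(self.c, dtype=np.float64)
        if self.V.shape != self.U.shape:
            raise ValueError(f"V and U must share shape, got {self.V.shape} vs {self.U.shape}")
        L, D = self.V.shape
        if L < 1:
            raise ValueError("attention hidden width L must be >= 1")
        if self.w.shape != (L,):
            raise ValueError(f"w must have shape ({L},), got {self.w.shape}")
        if self.c.shape != (D,):
            raise ValueError(f"c must have shape ({D},), got {self.c.shape}")
        for name in ("V", "U", "w", "c"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite entries in parameter {name}")

    @property
    def L(self) -> int:
        return self.V.shape[0]

    @property
    def D(self) -> int:
        return self.V.shape[1]

    @classmethod
    def init(cls, D: int, L: int = 128, seed: int | None = None) -> "AttentionParams":
        """Seeded initialization: attention branches uniform in
        +-1/sqrt(fan-in), classifier head at zero.

        Zero-initializing the linear head makes the bag score start exactly
        neutral (p = 1/2 for every bag), so the ranking the model produces is
        built entirely from learned signal rather than having to first unlearn
        a random projection — important under small step budgets.  An
        explicit seed is required.
        """
        if seed is None:
            raise ValueError("an explicit seed is required for parameter initialization")
        rng = np.random.default_rng(seed)
        s_in = 1.0 / np.sqrt(D)
        s_att = 1.0 / np.sqrt(L)
        return cls(
            V=rng.uniform(-s_in, s_in, size=(L, D)),
            U=rng.uniform(-s_in, s_in, size=(L, D)),
            w=rng.uniform(-s_att, s_att, size=L),
            c=np.zeros(D),
            b=0.0,
        )

    def copy(self) -> "AttentionParams":
        return AttentionParams(self.V.copy(), self.U.copy(), self.w.copy(), self.c.copy(), self.b)

    def to_dict(self) -> dict:
        return {
            "V": self.V.tolist(),
            "U": self.U.tolist(),
            "w": self.w.tolist(),
            "c": self.c.tolist(),
            "b": float(self.b),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AttentionParams":
        return cls(
            V=np.array(d["V"]), U=np.array(d["U"]), w=np.array(d["w"]),
            c=np.array(d["c"]), b=float(d["b"]),
        )


@dataclass
class BagPrediction:
    """Output of one bag forward pass: attention, pooled embedding, probability."""

    bag_id: str
    a: np.ndarray
    z: np.ndarray
    p: float
    label: int | None = None


def _check_H(H: np.ndarray, params: AttentionParams) -> np.ndarray:
    H = np.asarray(H, dtype=np.float64)
    if H.ndim != 2:
        raise ValueError(f"H must be K x D, got shape {H.shape}")
    if H.shape[0] < 1:
        raise ValueError("bag must contain at least one instance")
    if H.shape[1] != params.D:
        raise ValueError(f"embedding dim {H.shape[1]} != parameter dim {params.D}")
    if not np.all(np.isfinite(H)):
        raise ValueError("non-finite instance embeddings")
    return H


def attention_logits(H: np.ndarray, params: AttentionParams) -> np.ndarray:
    """Pre-softmax attention scores w^T(tanh(V h_k) * sigm(U h_k)), shape (K,)."""
    H = _check_H(H, params)
    gated = np.tanh(H @ params.V.T) * _sigmoid(H @ params.U.T)  # K x L
    return gated @ params.w


def gated_attention(H: np.ndarray, params: AttentionParams) -> np.ndarray:
    """Attention weights a_k over the K instances; positive and summing to 1.

    The softmax subtracts the max logit for numerical stability.
    """
    s = attention_logits(H, params)
    e = np.exp(s - s.max())
    return e / e.sum()


def bag_embedding(H: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Attention-weighted pooling z = sum_k a_k h_k."""
    H = np.asarray(H, dtype=np.float64)
    a = np.asarray(a, dtype=np.float64)
    if H.shape[0] != a.shape[0]:
        raise ValueError(f"{H.shape[0]} instances but {a.shape[0]} attention weights")
    if abs(a.sum() - 1.0) > 1e-6:
        raise ValueError(f"attention weights must sum to 1, got {a.sum():.8f}")
    return a @ H


def predict_bag(H: np.ndarray, params: AttentionParams, bag_id: str = "",
                label: int | None = None) -> BagPrediction:
    """Full forward pass: attention, pooled embedding and bag probability.

    Returns all three together so heatmaps reuse the exact attention the
    classifier saw.
    """
    H = _check_H(H, params)
    a = gated_attention(H, params)
    z = bag_embedding(H, a)
    p = float(_sigmoid(params.c @ z + params.b))
    return BagPrediction(bag_id=bag_id, a=a, z=z, p=p, label=label)


def bce_loss(p: float, y: int) -> float:
    """Bag-level binary cross-entropy with probability clamped to [eps, 1-eps]."""
    if y not in (0, 1):
        raise ValueError(f"label must be 0 or 1, got {y!r}")
    p = min(max(float(p), BCE_EPS), 1.0 - BCE_EPS)
    return -(y * np.log(p) + (1 - y) * np.log(1.0 - p))


def loss_and_grads(H: np.ndarray, y: int, params: AttentionParams) -> tuple[float, dict]:
    """BCE loss of one bag and its gradients w.r.t. V, U, w, c, b.

    Hand-derived backprop through sigm-linear head, attention pooling and the
    gated softmax attention; instance embeddings are frozen inputs.
    """
    if y not in (0, 1):
        raise ValueError(f"label must be 0 or 1, got {y!r}")
    H = _check_H(H, params)

    # forward, keeping intermediates
    T = H @ params.V.T          # K x L
    G = H @ params.U.T          # K x L
    tanh_T = np.tanh(T)
    sig_G = _sigmoid(G)
    A = tanh_T * sig_G          # K x L gated activations
    s = A @ params.w            # K attention logits
    e = np.exp(s - s.max())
    a = e / e.sum()
    z = a @ H
    logit = params.c @ z + params.b
    p = float(_sigmoid(logit))
    loss = bce_loss(p, y)

    # backward; d loss / d logit = p - y, zero where the BCE clamp saturates
    dlogit = (p - y) if BCE_EPS < p < 1.0 - BCE_EPS else 0.0
    dc = dlogit * z
    db = dlogit
    dz = dlogit * params.c      # (D,)
    da = H @ dz                 # (K,)
    ds = a * (da - a @ da)      # softmax Jacobian-vector product
    dA = np.outer(ds, params.w)  # K x L
    dw = A.T @ ds
    dT = dA * (1.0 - tanh_T**2) * sig_G
    dG = dA * tanh_T * sig_G * (1.0 - sig_G)
    dV = dT.T @ H
    dU = dG.T @ H
    return loss, {"V": dV, "U": dU, "w": dw, "c": dc, "b": db}


# ---------------------------------------------------------------------------
# Checkpoints: versioned JSON containers (params + config + seed + encoder).


def save_checkpoint(path: str | Path, params: AttentionParams, *, seed: int,
                    encoder_name: str, config: dict | None = None,
                    extra: dict | None = None) -> None:
    doc = {
        "schema": CHECKPOINT_SCHEMA,
        "params": params.to_dict(),
        "seed": int(seed),
        "encoder_name": encoder_name,
        "config": config or {},
        "extra": extra or {},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_checkpoint(path: str | Path) -> dict:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema") != CHECKPOINT_SCHEMA:
        raise ValueError(f"unrecognized checkpoint schema {doc.get('schema')!r}")
    doc["params"] = AttentionParams.from_dict(doc["params"])
    return doc


__all__ = [
    "AttentionParams",
    "BagPrediction",
    "BCE_EPS",
    "attention_logits",
    "bag_embedding",
    "bce_loss",
    "gated_attention",
    "load_checkpoint",
    "loss_and_grads",
    "predict_bag",
    "save_checkpoint",
]
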