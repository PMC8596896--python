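"""The shallow-and-wide attention CNN (SWAM) and its gradients.

The network is deliberately minimal: an embedding lookup produces the
``d_e × N`` input matrix X; one convolutional layer of ``d_c`` filters of
width ``k`` (zero-padded so the base representation H keeps length N)
computes

    h_n = g(W_c * x_{n:n+k-1} + b_c)

and then one of two pooling heads reduces H to per-label document vectors:

* **per-label attention** — for each label ℓ a parameter vector u_ℓ scores
  every position, α_ℓ = SoftMax(Hᵀ u_ℓ), and v_ℓ = Σ_n α_ℓ,n h_n.  The
  attention weights double as the model's explanation: the argmax of α_ℓ
  marks the most informative snippet for code ℓ.
* **max pooling** — v_j = max_n h_{n,j}, one shared document vector (the
  textCNN head), with argmax positions retained per filter.

Per-label sigmoid classifiers ŷ_ℓ = σ(β_ℓᵀ v_ℓ + b_ℓ) and a
summed-over-labels binary cross-entropy complete the model.

The premise behind the shape of the network: informative snippets are
local, low-level features scattered at random positions, so depth buys
nothing, but the filter bank must be wide enough to dedicate capacity to
every label-specific ("non-generic") snippet in the task.

All forward and backward passes are plain numpy with analytic gradients;
document-padding positions are excluded from attention and pooling by a
mask (the zero-padding in the convolution contract is a separate, always-on
length-preserving pad).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "ModelConfig",
    "ForwardState",
    "SWAMModel",
    "conv_forward",
    "perlabel_attention",
    "attend_pool",
    "max_pool",
    "classify",
    "bce_loss",
    "forward",
]

_PARAM_NAMES = ("E", "Wc", "bc", "U", "B", "b")


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Attributes
    ----------
    n_labels:
        Size of the code set |L|.
    d_e:
        Embedding size (default 100).
    d_c:
        Number of convolution filters — the *width* of the network.  The
        headline configuration uses 500; the narrow ablation uses 50.
    k:
        Filter window width in tokens (grid optimum 4).
    activation:
        Elementwise nonlinearity g, ``"tanh"`` or ``"relu"``.
    attention:
        ``"per_label"`` (attention head) or ``"max_pool"`` (textCNN head).
    dropout:
        Dropout probability q applied to the embedded input during training.
    threshold:
        Probability cutoff for binary decisions.
    freeze_embeddings:
        If True the embedding matrix is not updated during training.
    """

    n_labels: int
    d_e: int = 100
    d_c: int = 500
    k: int = 4
    activation: str = "tanh"
    attention: str = "per_label"
    dropout: float = 0.2
    threshold: float = 0.5
    freeze_embeddings: bool = False

    def __post_init__(self) -> None:
        if self.k < 1 or self.d_c < 1 or self.d_e < 1 or self.n_labels < 1:
            raise ValueError("k, d_c, d_e and n_labels must all be >= 1")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must be in (0, 1)")
        if self.activation not in ("tanh", "relu"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.attention not in ("per_label", "max_pool"):
            raise ValueError(f"unknown attention variant {self.attention!r}")


@dataclass
class ForwardState:
    """All per-document intermediates, kept for prediction and explanation.

    ``A`` holds the attention matrix α (|L| × N) for the per-label variant;
    for the max-pool variant it holds the per-filter argmax positions
    (length d_c).  ``V`` is d_c × |L| (the max-pool document vector is
    broadcast across labels).
    """

    X: np.ndarray
    H: np.ndarray
    A: np.ndarray
    V: np.ndarray
    yhat: np.ndarray


def _activate(Z: np.ndarray, activation: str) -> np.ndarray:
    return np.tanh(Z) if activation == "tanh" else np.maximum(Z, 0.0)


def _activate_backward(dH: np.ndarray, H: np.ndarray, activation: str) -> np.ndarray:
    if activation == "tanh":
        return dH * (1.0 - H * H)
    return dH * (H > 0.0)


def _pad_lr(k: int) -> tuple[int, int]:
    # "padded on both sides" — asymmetric for even k so len(H) == len(X)
    left = (k - 1) // 2
    return left, (k - 1) - left


def _conv_batch(Xb: np.ndarray, Wc: np.ndarray, bc: np.ndarray) -> np.ndarray:
    """Pre-activation convolution on a (batch, N, d_e) stack → (batch, N, d_c)."""
    k = Wc.shape[0]
    left, right = _pad_lr(k)
    Xp = np.pad(Xb, ((0, 0), (left, right), (0, 0)))
    N = Xb.shape[1]
    Z = np.empty((Xb.shape[0], N, Wc.shape[2]))
    Z[:] = bc
    for t in range(k):
        Z += Xp[:, t : t + N, :] @ Wc[t]
    return Z


def _conv_batch_backward(
    dZ: np.ndarray, Xb: np.ndarray, Wc: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of the pre-activation convolution: (dXb, dWc, dbc)."""
    k = Wc.shape[0]
    left, right = _pad_lr(k)
    N = Xb.shape[1]
    Xp = np.pad(Xb, ((0, 0), (left, right), (0, 0)))
    dXp = np.zeros_like(Xp)
    dWc = np.zeros_like(Wc)
    d_e, d_c = Wc.shape[1], Wc.shape[2]
    dZ_flat = dZ.reshape(-1, d_c)
    for t in range(k):
        X_t = Xp[:, t : t + N, :].reshape(-1, d_e)
        dWc[t] = X_t.T @ dZ_flat
        dXp[:, t : t + N, :] += dZ @ Wc[t].T
    dbc = dZ_flat.sum(axis=0)
    return dXp[:, left : left + N, :], dWc, dbc


def _masked_softmax(S: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Softmax over the last axis with masked positions at exactly zero.

    ``S`` is (..., N); ``mask`` broadcasts to it with True at real tokens.
    Raises if any row is fully masked.
    """
    neg = np.where(mask, S, -np.inf)
    m = neg.max(axis=-1, keepdims=True)
    if not np.isfinite(m).all():
        raise ValueError("attention over a fully padded document")
    e = np.exp(neg - m)
    e = np.where(mask, e, 0.0)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# single-document functional ops (matrix convention: X is d_e × N, H is d_c × N)
# ---------------------------------------------------------------------------


def conv_forward(
    X: np.ndarray,
    Wc: np.ndarray,
    bc: np.ndarray,
    activation: str = "tanh",
) -> np.ndarray:
    """Length-preserving convolution of a single document.

    Parameters
    ----------
    X:
        ``d_e × N`` input matrix (one embedded document).
    Wc:
        ``k × d_e × d_c`` filter bank.
    bc:
        Length-``d_c`` bias.

    Returns
    -------
    ``d_c × N`` base representation H = g(W_c * X + b_c), zero-padded on
    both sides so H keeps the length of X.
    """
    X = np.asarray(X, dtype=np.float64)
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in convolution input")
    Z = _conv_batch(X.T[None], np.asarray(Wc, dtype=np.float64), np.asarray(bc))
    return _activate(Z[0], activation).T


def perlabel_attention(
    H: np.ndarray, u: np.ndarray, mask: np.ndarray | None = None
) -> np.ndarray:
    """Attention distribution α = SoftMax(Hᵀ u) over document positions.

    ``mask`` (length N, True at real tokens) removes document-padding
    positions from the softmax; their weight is exactly zero.
    """
    H = np.asarray(H, dtype=np.float64)
    scores = H.T @ np.asarray(u, dtype=np.float64)
    if mask is None:
        mask = np.ones(scores.shape, dtype=bool)
    return _masked_softmax(scores, np.asarray(mask, dtype=bool))


def attend_pool(H: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Attention-weighted document vector v = Σ_n α_n h_n (length d_c)."""
    H = np.asarray(H, dtype=np.float64)
    alpha = np.asarray(alpha, dtype=np.float64)
    if H.shape[1] != alpha.shape[0]:
        raise ValueError(
            f"H has {H.shape[1]} positions but alpha has {alpha.shape[0]}"
        )
    return H @ alpha


def max_pool(
    H: np.ndarray, mask: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-filter max over unmasked positions.

    Returns ``(v, argmax)`` where ``v[j] = max_n h_{j,n}`` and ``argmax[j]``
    is the position attaining it (earliest on ties), both length d_c.
    """
    H = np.asarray(H, dtype=np.float64)
    if mask is None:
        mask = np.ones(H.shape[1], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("max pooling over a fully padded document")
    Hm = np.where(mask[None, :], H, -np.inf)
    arg = Hm.argmax(axis=1)
    return Hm[np.arange(H.shape[0]), arg], arg


def classify(v: np.ndarray, beta: np.ndarray, b: float) -> float:
    """Label likelihood ŷ = σ(βᵀ v + b)."""
    z = float(np.dot(beta, v) + b)
    return float(1.0 / (1.0 + np.exp(-z)))


def bce_loss(yhat: np.ndarray, y: np.ndarray) -> float:
    """Binary cross-entropy summed over labels, averaged over any batch axis.

    ``yhat`` may be a vector (one document) or a ``batch × |L|`` matrix.
    Probabilities outside the open interval (0, 1) are clamped at a
    machine-epsilon margin with a warning.
    """
    yhat = np.asarray(yhat, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if yhat.shape != y.shape:
        raise ValueError(f"shape mismatch: yhat {yhat.shape} vs y {y.shape}")
    eps = np.finfo(np.float64).eps
    if (yhat <= 0.0).any() or (yhat >= 1.0).any():
        warnings.warn("probabilities clamped away from {0,1} in BCE", RuntimeWarning)
        yhat = np.clip(yhat, eps, 1.0 - eps)
    per_doc = -(y * np.log(yhat) + (1.0 - y) * np.log(1.0 - yhat)).sum(axis=-1)
    return float(per_doc.mean()) if per_doc.ndim else float(per_doc)


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------


class SWAMModel:
    """Parameter container with batched forward/backward passes.

    Parameters live in ``self.params``: ``E`` (|vocab| × d_e embeddings,
    PAD row zero), ``Wc``/``bc`` (convolution), ``U`` (d_c × |L| attention
    vectors, per-label variant only), ``B`` (d_c × |L| prediction weights)
    and ``b`` (|L| offsets).  Initialization is symmetric uniform scaled by
    fan-in, fully determined by ``seed``.
    """

    def __init__(
        self,
        config: ModelConfig,
        embedding: np.ndarray,
        pad_id: int = 0,
        seed: int = 0,
    ) -> None:
        embedding = np.asarray(embedding, dtype=np.float64)
        if embedding.shape[1] != config.d_e:
            raise ValueError(
                f"embedding width {embedding.shape[1]} != config d_e {config.d_e}"
            )
        self.config = config
        self.pad_id = pad_id
        rng = np.random.default_rng(seed)
        a_conv = 1.0 / np.sqrt(config.k * config.d_e)
        a_head = 1.0 / np.sqrt(config.d_c)
        self.params: dict[str, np.ndarray] = {
            "E": embedding.copy(),
            "Wc": rng.uniform(-a_conv, a_conv, size=(config.k, config.d_e, config.d_c)),
            "bc": np.zeros(config.d_c),
            "U": rng.uniform(-a_head, a_head, size=(config.d_c, config.n_labels)),
            "B": rng.uniform(-a_head, a_head, size=(config.d_c, config.n_labels)),
            "b": np.zeros(config.n_labels),
        }
        self.params["E"][pad_id] = 0.0

    # -- batched passes -----------------------------------------------------

    def _embed(self, ids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ids = np.asarray(ids, dtype=np.int64)
        mask = ids != self.pad_id
        return self.params["E"][ids], mask

    def forward_batch(
        self,
        ids: np.ndarray,
        train: bool = False,
        dropout_rng: np.random.Generator | None = None,
    ) -> dict:
        """Run a padded id batch ``(batch, N)`` through the network.

        Returns a cache dict with every intermediate needed by
        :meth:`backward_batch`: the (possibly dropped-out) input ``Xb``,
        base representation ``Hb``, attention ``alpha`` (or pool ``argmax``),
        document vectors ``V``, logits ``z`` and probabilities ``yhat``.
        """
        cfg = self.config
        Xb, mask = self._embed(ids)
        if not mask.any(axis=1).all():
            raise ValueError("batch contains a fully padded document")
        drop_mask = None
        if train and cfg.dropout > 0.0:
            if dropout_rng is None:
                raise ValueError("training-mode forward needs a dropout RNG")
            keep = 1.0 - cfg.dropout
            drop_mask = (dropout_rng.random(Xb.shape) < keep) / keep
            Xb = Xb * drop_mask
        Z = _conv_batch(Xb, self.params["Wc"], self.params["bc"])
        Hb = _activate(Z, cfg.activation)
        cache: dict = {"ids": ids, "mask": mask, "Xb": Xb, "Hb": Hb, "drop": drop_mask}
        if cfg.attention == "per_label":
            S = np.einsum("bnj,jl->bln", Hb, self.params["U"])
            alpha = _masked_softmax(S, mask[:, None, :])
            V = np.einsum("bln,bnj->blj", alpha, Hb)
            z = np.einsum("blj,jl->bl", V, self.params["B"]) + self.params["b"]
            cache.update(alpha=alpha, V=V)
        else:
            Hm = np.where(mask[:, :, None], Hb, -np.inf)
            arg = Hm.argmax(axis=1)  # (batch, d_c)
            v = np.take_along_axis(Hm, arg[:, None, :], axis=1)[:, 0, :]
            z = v @ self.params["B"] + self.params["b"]
            cache.update(argmax=arg, v=v)
        cache["z"] = z
        cache["yhat"] = 1.0 / (1.0 + np.exp(-z))
        return cache

    def loss(self, cache: dict, y: np.ndarray) -> float:
        """Batch-mean, label-summed BCE computed stably from the logits."""
        z = cache["z"]
        y = np.asarray(y, dtype=np.float64)
        # softplus(z) - y*z == -[y log σ(z) + (1-y) log(1-σ(z))]
        per_pair = np.logaddexp(0.0, z) - y * z
        return float(per_pair.sum(axis=1).mean())

    def backward_batch(self, cache: dict, y: np.ndarray) -> dict[str, np.ndarray]:
        """Analytic gradients of :meth:`loss` w.r.t. every parameter tensor."""
        cfg = self.config
        ids, mask = cache["ids"], cache["mask"]
        Xb, Hb = cache["Xb"], cache["Hb"]
        y = np.asarray(y, dtype=np.float64)
        batch = ids.shape[0]
        dz = (cache["yhat"] - y) / batch  # (batch, L)

        grads: dict[str, np.ndarray] = {}
        if cfg.attention == "per_label":
            alpha, V = cache["alpha"], cache["V"]
            grads["b"] = dz.sum(axis=0)
            grads["B"] = np.einsum("blj,bl->jl", V, dz)
            dV = dz[:, :, None] * self.params["B"].T[None, :, :]  # (b,L,dc)
            dH = np.einsum("bln,blj->bnj", alpha, dV)
            dalpha = np.einsum("blj,bnj->bln", dV, Hb)
            inner = (alpha * dalpha).sum(axis=-1, keepdims=True)
            dS = alpha * (dalpha - inner)
            grads["U"] = np.einsum("bnj,bln->jl", Hb, dS)
            dH += np.einsum("bln,jl->bnj", dS, self.params["U"])
        else:
            arg, v = cache["argmax"], cache["v"]
            grads["b"] = dz.sum(axis=0)
            grads["B"] = v.T @ dz
            dv = dz @ self.params["B"].T  # (batch, d_c)
            dH = np.zeros_like(Hb)
            bidx = np.arange(batch)[:, None]
            jidx = np.arange(cfg.d_c)[None, :]
            dH[bidx, arg, jidx] = dv

        dZ = _activate_backward(dH, Hb, cfg.activation)
        dXb, grads["Wc"], grads["bc"] = _conv_batch_backward(dZ, Xb, self.params["Wc"])
        if cache["drop"] is not None:
            dXb = dXb * cache["drop"]
        dE = np.zeros_like(self.params["E"])
        if not cfg.freeze_embeddings:
            np.add.at(dE, ids, dXb)
            dE[self.pad_id] = 0.0
        grads["E"] = dE
        _ = mask  # masking already encoded in alpha / argmax
        return grads

    def predict_batch(self, ids: np.ndarray) -> np.ndarray:
        """Probabilities ``(batch, |L|)`` in evaluation mode (no dropout)."""
        return self.forward_batch(ids, train=False)["yhat"]

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Single-archive checkpoint: config JSON + named tensors, bit-exact."""
        cfg_json = json.dumps({"pad_id": self.pad_id, **asdict(self.config)})
        np.savez(
            Path(path),
            __config__=np.frombuffer(cfg_json.encode(), dtype=np.uint8),
            **self.params,
        )

    @classmethod
    def load(cls, path: str | Path) -> "SWAMModel":
        with np.load(Path(path)) as archive:
            cfg = json.loads(bytes(archive["__config__"]).decode())
            pad_id = cfg.pop("pad_id")
            model = cls.__new__(cls)
            model.config = ModelConfig(**cfg)
            model.pad_id = pad_id
            model.params = {name: archive[name].copy() for name in _PARAM_NAMES}
        return model


def forward(
    token_ids: Sequence[int],
    model: SWAMModel,
    train: bool = False,
    dropout_rng: np.random.Generator | None = None,
) -> ForwardState:
    """Run one document through the network and return all intermediates.

    Output follows the single-document convention: X is d_e × N, H is
    d_c × N, A is |L| × N attention weights (per-label variant) or the
    length-d_c pool argmax (max-pool variant), V is d_c × |L|.
    """
    ids = np.asarray(token_ids, dtype=np.int64)[None, :]
    cache = model.forward_batch(ids, train=train, dropout_rng=dropout_rng)
    if model.config.attention == "per_label":
        A = cache["alpha"][0]
        V = cache["V"][0].T
    else:
        A = cache["argmax"][0]
        V = np.repeat(cache["v"][0][:, None], model.config.n_labels, axis=1)
    return ForwardState(
        X=cache["Xb"][0].T, H=cache["Hb"][0].T, A=A, V=V, yhat=cache["yhat"][0]
    )
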