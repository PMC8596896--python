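"""Word representations: seeded random init or CBOW pretraining.

The supervised model consumes a ``|vocab| × d_e`` embedding matrix whose
rows align with the vocabulary ids (PAD row all zeros).  Rows can come from
continuous-bag-of-words (CBOW) pretraining with negative sampling on the
training corpus — the classic word2vec objective: predict a center word
from the mean of its context window — or from a uniform random
initialization for experiments where pretraining is not the point.
Embeddings are fine-tuned during supervised training unless frozen.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from swam.preprocessing import Vocabulary

__all__ = ["EmbeddingMatrix", "random_embeddings", "pretrain_cbow", "lookup"]


@dataclass
class EmbeddingMatrix:
    """``|vocab| × d_e`` matrix with provenance metadata."""

    matrix: np.ndarray
    d_e: int
    provenance: str  # "pretrained_cbow" | "random" | "loaded"
    seed: int | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != self.d_e:
            raise ValueError("embedding matrix shape inconsistent with d_e")


def random_embeddings(
    vocab: Vocabulary, d_e: int = 100, seed: int = 0
) -> EmbeddingMatrix:
    """Uniform rows on ``[-0.5/d_e, 0.5/d_e]`` (the word2vec init range); zero PAD."""
    rng = np.random.default_rng(seed)
    mat = rng.uniform(-0.5 / d_e, 0.5 / d_e, size=(len(vocab), d_e))
    mat[vocab.pad_id] = 0.0
    return EmbeddingMatrix(matrix=mat, d_e=d_e, provenance="random", seed=seed)


def lookup(token_ids: Sequence[int], emb: EmbeddingMatrix) -> np.ndarray:
    """Row-gather a token-id sequence into the ``d_e × N`` input matrix X."""
    ids = np.asarray(token_ids, dtype=np.int64)
    return emb.matrix[ids].T


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30.0, 30.0)))


def pretrain_cbow(
    encoded_docs: Sequence[np.ndarray],
    vocab: Vocabulary,
    d_e: int = 100,
    window: int = 5,
    epochs: int = 5,
    negative: int = 5,
    lr: float = 0.025,
    seed: int = 0,
) -> EmbeddingMatrix:
    """Pretrain CBOW embeddings with negative sampling on encoded documents.

    For every position the mean of the context-window input vectors predicts
    the center word against ``negative`` noise words drawn from the unigram
    distribution raised to 3/4 — the standard word2vec CBOW objective.  The
    learning rate decays linearly over all updates.  Training is
    single-threaded and fully deterministic under ``seed``.

    Tokens never seen as a center word (and PAD) keep their seeded random
    initialization; the PAD row is zeroed in the returned matrix.

    Parameters
    ----------
    encoded_docs:
        Documents as id arrays from the same preprocessing pipeline the
        supervised model uses, so embedding rows align with model input ids.
    d_e:
        Embedding size; 100 is the conventional choice for discharge-summary
        coding.
    """
    if len(encoded_docs) == 0:
        raise ValueError("cannot pretrain embeddings on an empty corpus")
    V = len(vocab)
    rng = np.random.default_rng(seed)
    w_in = rng.uniform(-0.5 / d_e, 0.5 / d_e, size=(V, d_e))
    w_out = np.zeros((V, d_e))

    counts = np.zeros(V, dtype=np.float64)
    for doc in encoded_docs:
        np.add.at(counts, np.asarray(doc, dtype=np.int64), 1.0)
    counts[vocab.pad_id] = 0.0
    noise = counts ** 0.75
    total = noise.sum()
    if total == 0:
        raise ValueError("corpus contains no usable tokens")
    noise /= total

    n_positions = int(sum(len(d) for d in encoded_docs))
    total_updates = max(1, n_positions * epochs)
    seen_center = np.zeros(V, dtype=bool)
    step = 0
    for _epoch in range(epochs):
        for doc in encoded_docs:
            ids = np.asarray(doc, dtype=np.int64)
            n = len(ids)
            for pos in range(n):
                step += 1
                center = ids[pos]
                if center == vocab.pad_id:
                    continue
                # dynamic window, as in the reference word2vec implementation
                b = int(rng.integers(1, window + 1))
                lo, hi = max(0, pos - b), min(n, pos + b + 1)
                context = np.concatenate([ids[lo:pos], ids[pos + 1 : hi]])
                context = context[context != vocab.pad_id]
                if len(context) == 0:
                    continue
                seen_center[center] = True
                alpha = lr * max(1e-4, 1.0 - step / total_updates)
                h = w_in[context].mean(axis=0)
                targets = np.empty(1 + negative, dtype=np.int64)
                targets[0] = center
                targets[1:] = rng.choice(V, size=negative, p=noise)
                labels = np.zeros(1 + negative)
                labels[0] = 1.0
                out = w_out[targets]
                grad = (_sigmoid(out @ h) - labels) * alpha  # (1+neg,)
                dh = grad @ out
                w_out[targets] -= np.outer(grad, h)
                w_in[context] -= dh / len(context)

    # unseen tokens keep the random init; PAD is zeroed by convention
    mat = w_in.copy()
    mat[vocab.pad_id] = 0.0
    _ = seen_center  # retained for introspection/debugging of tiny corpora
    return EmbeddingMatrix(matrix=mat, d_e=d_e, provenance="pretrained_cbow", seed=seed)
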