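"""Mini-batch training with early stopping on validation macro-F1.

The optimizer is Adam (no weight decay) on the batch-mean, label-summed
binary cross-entropy.  After every epoch the model is scored on the
validation split at the decision threshold; training stops once validation
macro-F1 has failed to strictly improve for ``patience`` consecutive
epochs (default 10), and the parameters from the best epoch are returned.
Two seeds govern a run: ``init_seed`` (parameter initialization and
dropout) and ``data_seed`` (the per-epoch shuffling of the training
documents).  Holding both fixed makes a run bit-reproducible; varying only
``data_seed`` is the data-order shuffle experiment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from swam.evaluation import macro_micro
from swam.model import ModelConfig, SWAMModel
from swam.preprocessing import Dataset, TokenizedDoc

__all__ = [
    "TrainConfig",
    "TrainLog",
    "train",
    "grid_search",
    "reshuffle_and_retrain",
    "predict_dataset",
    "DEFAULT_GRID",
]

# hyperparameter search ranges for the learning rate, filter width, filter
# count and dropout (the d_c endpoints are the wide/narrow ablation pair)
DEFAULT_GRID: dict[str, tuple] = {
    "lr": (0.0001, 0.0003, 0.001, 0.003),
    "k": tuple(range(1, 11)),
    "d_c": (50, 100, 200, 300, 400, 500),
    "dropout": (0.2, 0.4, 0.6, 0.8),
}


@dataclass
class TrainConfig:
    """Optimization settings; defaults follow the tuned protocol."""

    lr: float = 0.001
    batch_size: int = 16
    max_epochs: int = 200
    patience: int = 10
    data_seed: int = 0
    init_seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.patience < 1 or self.max_epochs < 1:
            raise ValueError("batch_size, patience and max_epochs must be >= 1")


@dataclass
class TrainLog:
    """Per-epoch trace of a training run."""

    train_loss: list[float] = field(default_factory=list)
    valid_f1_macro: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stop_reason: str = ""

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("epoch\ttrain_loss\tvalid_f1_macro\n")
            for i, (loss, f1) in enumerate(zip(self.train_loss, self.valid_f1_macro)):
                fh.write(f"{i}\t{loss:.6f}\t{f1:.6f}\n")
            fh.write(f"# best_epoch={self.best_epoch} stop_reason={self.stop_reason}\n")


class _Adam:
    """Adaptive moment estimation over a dict of parameter tensors."""

    def __init__(self, params: dict[str, np.ndarray], lr: float) -> None:
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps
            )


def _pad_batch(docs: Sequence[TokenizedDoc], pad_id: int) -> tuple[np.ndarray, np.ndarray]:
    """Stack variable-length docs into a padded id matrix plus label matrix."""
    n_max = max(len(d.token_ids) for d in docs)
    ids = np.full((len(docs), n_max), pad_id, dtype=np.int64)
    for i, d in enumerate(docs):
        ids[i, : len(d.token_ids)] = d.token_ids
    y = np.stack([d.label_vector for d in docs]).astype(np.float64)
    return ids, y


def predict_dataset(
    model: SWAMModel, docs: Sequence[TokenizedDoc], batch_size: int = 16
) -> np.ndarray:
    """Score every document; returns a ``docs × |L|`` probability matrix.

    Documents are bucketed by length inside each batch boundary only to the
    extent of padding to the batch max, so scores are independent of batch
    composition (padding positions are masked out of the heads).
    """
    out = np.zeros((len(docs), model.config.n_labels))
    for start in range(0, len(docs), batch_size):
        chunk = docs[start : start + batch_size]
        ids, _ = _pad_batch(chunk, model.pad_id)
        out[start : start + len(chunk)] = model.predict_batch(ids)
    return out


def _valid_f1(model: SWAMModel, docs: Sequence[TokenizedDoc], batch_size: int) -> float:
    scores = predict_dataset(model, docs, batch_size=batch_size)
    truth = np.stack([d.label_vector for d in docs])
    decisions = (scores >= model.config.threshold).astype(np.int8)
    f1_macro, _ = macro_micro(decisions, truth)
    return f1_macro


def train(
    dataset: Dataset,
    model_config: ModelConfig,
    train_config: TrainConfig,
    embedding: np.ndarray | None = None,
    verbose: bool = False,
) -> tuple[SWAMModel, TrainLog]:
    """Fit a SWAM model on ``dataset.train``, early-stopped on ``dataset.valid``.

    Parameters
    ----------
    embedding:
        Optional pretrained ``|vocab| × d_e`` matrix; absent, embeddings are
        randomly initialized from ``init_seed``.

    Returns
    -------
    (model at the best validation epoch, per-epoch log).

    Raises
    ------
    FloatingPointError
        If the training loss becomes non-finite (divergence).
    """
    if not dataset.train or not dataset.valid:
        raise ValueError("training requires non-empty train and valid splits")
    if embedding is None:
        from swam.embeddings import random_embeddings

        embedding = random_embeddings(
            dataset.vocab, d_e=model_config.d_e, seed=train_config.init_seed
        ).matrix
    model = SWAMModel(
        model_config,
        embedding,
        pad_id=dataset.vocab.pad_id,
        seed=train_config.init_seed,
    )
    optimizer = _Adam(model.params, lr=train_config.lr)
    data_rng = np.random.default_rng(train_config.data_seed)
    dropout_rng = np.random.default_rng(train_config.init_seed + 1)

    log = TrainLog()
    best_f1 = -np.inf
    best_params: dict[str, np.ndarray] | None = None
    stale = 0
    # sort once by length so batches are mostly homogeneous; the per-epoch
    # permutation then shuffles whole batches, preserving the data-order
    # seed's role while keeping padding waste low
    order0 = sorted(range(len(dataset.train)), key=lambda i: len(dataset.train[i].token_ids))
    batches = [
        order0[s : s + train_config.batch_size]
        for s in range(0, len(order0), train_config.batch_size)
    ]
    for epoch in range(train_config.max_epochs):
        epoch_loss = 0.0
        for b in data_rng.permutation(len(batches)):
            docs = [dataset.train[i] for i in batches[b]]
            ids, y = _pad_batch(docs, model.pad_id)
            cache = model.forward_batch(ids, train=True, dropout_rng=dropout_rng)
            loss = model.loss(cache, y)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged: non-finite loss at epoch {epoch}"
                )
            # backward_batch returns a zero embedding gradient when
            # freeze_embeddings is set, so Adam leaves E untouched
            grads = model.backward_batch(cache, y)
            optimizer.step(model.params, grads)
            epoch_loss += loss * len(docs)
        epoch_loss /= len(dataset.train)
        f1 = _valid_f1(model, dataset.valid, train_config.batch_size)
        log.train_loss.append(epoch_loss)
        log.valid_f1_macro.append(f1)
        if verbose:
            print(f"epoch {epoch}: loss {epoch_loss:.4f}  valid macro-F1 {f1:.4f}")
        if f1 > best_f1:
            best_f1 = f1
            best_params = {k: v.copy() for k, v in model.params.items()}
            log.best_epoch = epoch
            stale = 0
        else:
            stale += 1
            if stale >= train_config.patience:
                log.stop_reason = "patience_exhausted"
                break
    else:
        log.stop_reason = "max_epochs"
    if best_params is not None:
        model.params = best_params
    return model, log


def grid_search(
    dataset: Dataset,
    grid: dict[str, Sequence] | None = None,
    base_model: ModelConfig | None = None,
    base_train: TrainConfig | None = None,
    verbose: bool = False,
) -> pd.DataFrame:
    """Exhaustive search over the hyperparameter grid.

    ``grid`` maps a subset of {lr, k, d_c, dropout} to candidate values;
    every combination is trained with the same seeds (held fixed across
    grid points for comparability) and scored by best validation macro-F1.
    Returns a DataFrame sorted by descending score with the winner first.
    """
    grid = dict(DEFAULT_GRID if grid is None else grid)
    base_model = base_model or ModelConfig(n_labels=len(dataset.label_space))
    base_train = base_train or TrainConfig()
    names = sorted(grid)
    rows = []
    for combo in itertools.product(*(grid[n] for n in names)):
        cell = dict(zip(names, combo))
        mc = replace(
            base_model,
            **{k: v for k, v in cell.items() if k in ("k", "d_c", "dropout")},
        )
        tc = replace(base_train, **{k: v for k, v in cell.items() if k == "lr"})
        _model, log = train(dataset, mc, tc)
        rows.append({**cell, "valid_f1_macro": max(log.valid_f1_macro),
                     "best_epoch": log.best_epoch})
        if verbose:
            print(f"grid cell {cell}: macro-F1 {rows[-1]['valid_f1_macro']:.4f}")
    table = pd.DataFrame(rows).sort_values(
        "valid_f1_macro", ascending=False, kind="stable"
    ).reset_index(drop=True)
    table["best"] = False
    if len(table):
        table.loc[0, "best"] = True
    return table


def reshuffle_and_retrain(
    dataset: Dataset,
    model_config: ModelConfig,
    train_config: TrainConfig,
    data_seed: int,
    embedding: np.ndarray | None = None,
) -> tuple[SWAMModel, TrainLog]:
    """Retrain with an identical configuration but a different data-order seed.

    Everything except the order in which training batches are visited is
    held fixed, which isolates the effect of data order on which
    label-specific snippets a (narrow) model manages to learn.
    """
    tc = replace(train_config, data_seed=data_seed)
    return train(dataset, model_config, tc, embedding=embedding)
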