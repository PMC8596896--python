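"""Metric suite for multi-label code assignment.

Macro-averaged metrics are computed per label and then averaged (they
weight rare and frequent codes equally, which is what exposes the
zero-precision labels the width ablation is about); micro-averaged metrics
treat every (document, code) pair as one prediction.  P@n is the fraction
of the n highest-scored labels per document that are truly present,
averaged over documents.  Zero-denominator precision/recall/F1 are defined
as 0 — the per-label reports must be able to say "precision 0" for a label
the model never predicts.

Also here: the unigram bag-of-words one-vs-rest logistic-regression
baseline and the paired document-bootstrap significance test.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import sparse
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from swam.preprocessing import Dataset, TokenizedDoc

__all__ = [
    "MetricsReport",
    "per_label_prf",
    "macro_micro",
    "auc_macro_micro",
    "precision_at_n",
    "evaluate_scores",
    "bow_logreg_baseline",
    "paired_bootstrap",
]


@dataclass
class MetricsReport:
    """All headline metrics plus the per-label breakdown."""

    auc_macro: float
    auc_micro: float
    f1_macro: float
    f1_micro: float
    p_at_n: float
    n: int
    per_label: list[tuple[str, float, float, float, int]] = field(default_factory=list)
    skipped_auc_labels: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    def per_label_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("code\tprecision\trecall\tf1\tsupport\n")
            for code, p, r, f1, support in self.per_label:
                fh.write(f"{code}\t{p:.4f}\t{r:.4f}\t{f1:.4f}\t{support}\n")

    def zero_precision_labels(self) -> set[str]:
        """Codes with test positives but precision 0 (never predicted or
        never correctly)."""
        return {code for code, p, _r, _f1, sup in self.per_label if sup > 0 and p == 0.0}


def _prf_from_counts(tp: float, fp: float, fn: float) -> tuple[float, float, float]:
    p = tp / (tp + fp) if tp + fp > 0 else 0.0
    r = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2 * p * r / (p + r) if p + r > 0 else 0.0
    return p, r, f1


def per_label_prf(
    decisions: np.ndarray, truth: np.ndarray
) -> list[tuple[float, float, float, int]]:
    """Per-label (precision, recall, F1, support) from binary matrices.

    Both arguments are ``docs × |L|`` binary arrays.  Zero-denominator cases
    are 0 by convention.
    """
    decisions = np.asarray(decisions)
    truth = np.asarray(truth)
    if decisions.shape != truth.shape:
        raise ValueError("decisions and truth must have identical shapes")
    out = []
    for j in range(truth.shape[1]):
        d, t = decisions[:, j], truth[:, j]
        tp = float(np.sum((d == 1) & (t == 1)))
        fp = float(np.sum((d == 1) & (t == 0)))
        fn = float(np.sum((d == 0) & (t == 1)))
        p, r, f1 = _prf_from_counts(tp, fp, fn)
        out.append((p, r, f1, int(t.sum())))
    return out


def macro_micro(decisions: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    """(macro-F1, micro-F1).

    Macro is the unweighted mean of per-label F1; micro flattens all
    (document, code) pairs into one binary problem.
    """
    per_label = per_label_prf(decisions, truth)
    f1_macro = float(np.mean([f1 for _p, _r, f1, _s in per_label]))
    d = np.asarray(decisions).ravel()
    t = np.asarray(truth).ravel()
    tp = float(np.sum((d == 1) & (t == 1)))
    fp = float(np.sum((d == 1) & (t == 0)))
    fn = float(np.sum((d == 0) & (t == 1)))
    _p, _r, f1_micro = _prf_from_counts(tp, fp, fn)
    return f1_macro, f1_micro


def auc_macro_micro(
    scores: np.ndarray, truth: np.ndarray, label_names: Sequence[str] | None = None
) -> tuple[float, float, list[str]]:
    """(macro-AUC, micro-AUC, skipped labels).

    Macro averages per-label ROC-AUC over labels that have both a positive
    and a negative in ``truth``; degenerate labels are skipped and returned.
    Micro is ROC-AUC over the flattened (document, code) pairs.
    """
    scores = np.asarray(scores, dtype=np.float64)
    truth = np.asarray(truth)
    if label_names is None:
        label_names = [str(j) for j in range(truth.shape[1])]
    aucs, skipped = [], []
    for j in range(truth.shape[1]):
        t = truth[:, j]
        if t.min() == t.max():
            skipped.append(str(label_names[j]))
            continue
        aucs.append(roc_auc_score(t, scores[:, j]))
    auc_macro = float(np.mean(aucs)) if aucs else 0.5
    t_flat = truth.ravel()
    if t_flat.min() == t_flat.max():
        auc_micro = 0.5
    else:
        auc_micro = float(roc_auc_score(t_flat, scores.ravel()))
    return auc_macro, auc_micro, skipped


def precision_at_n(scores: np.ndarray, truth: np.ndarray, n: int = 5) -> float:
    """Mean over documents of the fraction of the top-n scored labels that
    are true.

    Ties are broken by ascending label index, so the result is deterministic
    and invariant under any strictly monotone transform of the scores.
    """
    scores = np.asarray(scores, dtype=np.float64)
    truth = np.asarray(truth)
    if n > scores.shape[1]:
        raise ValueError(f"n={n} exceeds the number of labels {scores.shape[1]}")
    # stable sort on -score keeps ascending label index among ties
    order = np.argsort(-scores, axis=1, kind="stable")[:, :n]
    hits = np.take_along_axis(truth, order, axis=1)
    return float(hits.mean())


def evaluate_scores(
    scores: np.ndarray,
    truth: np.ndarray,
    label_names: Sequence[str],
    threshold: float = 0.5,
    n: int = 5,
) -> MetricsReport:
    """Full report from a ``docs × |L|`` score matrix and binary truth."""
    decisions = (np.asarray(scores) >= threshold).astype(np.int8)
    prf = per_label_prf(decisions, truth)
    f1_macro, f1_micro = macro_micro(decisions, truth)
    auc_ma, auc_mi, skipped = auc_macro_micro(scores, truth, label_names)
    n_eff = min(n, len(label_names))
    return MetricsReport(
        auc_macro=auc_ma,
        auc_micro=auc_mi,
        f1_macro=f1_macro,
        f1_micro=f1_micro,
        p_at_n=precision_at_n(scores, truth, n=n_eff),
        n=n_eff,
        per_label=[
            (str(code), p, r, f1, s) for code, (p, r, f1, s) in zip(label_names, prf)
        ],
        skipped_auc_labels=skipped,
    )


def _bow_matrix(docs: Sequence[TokenizedDoc], vocab_size: int) -> sparse.csr_matrix:
    rows, cols, vals = [], [], []
    for i, doc in enumerate(docs):
        ids, counts = np.unique(doc.token_ids, return_counts=True)
        rows.extend([i] * len(ids))
        cols.extend(ids.tolist())
        vals.extend(counts.tolist())
    return sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(docs), vocab_size), dtype=np.float64
    )


def bow_logreg_baseline(
    dataset: Dataset,
    split: str = "test",
    C: float = 1.0,
    threshold: float = 0.5,
    n: int = 5,
) -> MetricsReport:
    """One-vs-rest logistic regression on unigram bag-of-words counts.

    Fits one binary classifier per code on the training split and evaluates
    on ``split`` with the same metric suite used for the neural models.
    Labels without a positive training example are skipped with a warning
    and scored 0 everywhere.
    """
    V = len(dataset.vocab)
    X_train = _bow_matrix(dataset.train, V)
    y_train = np.stack([d.label_vector for d in dataset.train])
    eval_docs = dataset.splits[split]
    X_eval = _bow_matrix(eval_docs, V)
    y_eval = np.stack([d.label_vector for d in eval_docs])
    scores = np.zeros((len(eval_docs), y_train.shape[1]))
    for j in range(y_train.shape[1]):
        if y_train[:, j].sum() == 0:
            warnings.warn(
                f"label {dataset.label_space.codes[j]} has no training positives; "
                "baseline scores it 0",
                RuntimeWarning,
            )
            continue
        if y_train[:, j].min() == y_train[:, j].max():
            continue
        clf = LogisticRegression(C=C, max_iter=1000, solver="liblinear")
        clf.fit(X_train, y_train[:, j])
        scores[:, j] = clf.predict_proba(X_eval)[:, 1]
    return evaluate_scores(
        scores, y_eval, dataset.label_space.codes, threshold=threshold, n=n
    )


def paired_bootstrap(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    truth: np.ndarray,
    metric: Callable[[np.ndarray, np.ndarray], float],
    n_resamples: int = 10_000,
    seed: int = 0,
) -> float:
    """One-sided paired bootstrap over documents.

    Resamples documents with replacement ``n_resamples`` times and returns
    the fraction of resamples in which ``metric(A) < metric(B)``, counting
    exact ties as 1/2 — so identical models yield p = 0.5 and small values
    mean model A beats model B more consistently than resampling noise
    explains.  Deterministic under ``seed``.
    """
    scores_a = np.asarray(scores_a)
    scores_b = np.asarray(scores_b)
    truth = np.asarray(truth)
    if scores_a.shape != scores_b.shape or scores_a.shape != truth.shape:
        raise ValueError("both score matrices and truth must share one shape")
    if n_resamples < 100:
        warnings.warn("fewer than 100 bootstrap resamples", RuntimeWarning)
    rng = np.random.default_rng(seed)
    n_docs = truth.shape[0]
    worse = 0.0
    for _ in range(n_resamples):
        idx = rng.integers(0, n_docs, size=n_docs)
        m_a = metric(scores_a[idx], truth[idx])
        m_b = metric(scores_b[idx], truth[idx])
        if m_a < m_b:
            worse += 1.0
        elif m_a == m_b:
            worse += 0.5
    return worse / n_resamples
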