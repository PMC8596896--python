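import numpy as np
import pytest
from sklearn.metrics import f1_score

from swam.evaluation import (
    auc_macro_micro,
    evaluate_scores,
    macro_micro,
    paired_bootstrap,
    per_label_prf,
    precision_at_n,
)

RNG = np.random.default_rng(77)


def auc_pair_oracle(score, truth):
    """O(n²) Mann–Whitney pair count (ties worth 1/2)."""
    pos, neg = score[truth == 1], score[truth == 0]
    total = sum(
        1.0 if a > b else (0.5 if a == b else 0.0) for a in pos for b in neg
    )
    return total / (len(pos) * len(neg))


def test_per_label_prf_conventions():
    truth = np.array([[1, 1], [1, 0], [0, 1], [0, 0]])
    decisions = np.array([[0, 1], [0, 0], [0, 1], [0, 1]])
    prf = per_label_prf(decisions, truth)
    assert prf[0] == (0.0, 0.0, 0.0, 2)  # never predicted -> all zero
    p, r, f1, support = prf[1]  # TP=2 FP=1 FN=0
    assert (p, r, support) == (2 / 3, 1.0, 2)
    assert f1 == pytest.approx(0.8)
    perfect = per_label_prf(truth, truth)
    assert all(row[:3] == (1.0, 1.0, 1.0) for row in perfect)


def test_macro_micro_agree_with_sklearn():
    decisions = (RNG.random((30, 5)) < 0.4).astype(int)
    truth = (RNG.random((30, 5)) < 0.3).astype(int)
    f1_ma, f1_mi = macro_micro(decisions, truth)
    assert f1_ma == pytest.approx(
        f1_score(truth, decisions, average="macro", zero_division=0)
    )
    assert f1_mi == pytest.approx(
        f1_score(truth, decisions, average="micro", zero_division=0)
    )


def test_micro_f1_flattened_pair_definition():
    """Micro over flattened pairs equals the aggregate-count formula."""
    decisions = (RNG.random((20, 4)) < 0.5).astype(int)
    truth = (RNG.random((20, 4)) < 0.5).astype(int)
    _, f1_mi = macro_micro(decisions, truth)
    f1_flat = f1_score(truth.ravel(), decisions.ravel(), zero_division=0)
    assert f1_mi == pytest.approx(f1_flat)


def test_auc_against_pair_count_oracle():
    scores = RNG.random((15, 3))
    truth = np.zeros((15, 3), dtype=int)
    truth[:7] = (RNG.random((7, 3)) < 0.6).astype(int)
    truth[0] = 1  # ensure positives exist
    auc_ma, auc_mi, skipped = auc_macro_micro(scores, truth)
    expected = [
        auc_pair_oracle(scores[:, j], truth[:, j])
        for j in range(3)
        if truth[:, j].min() != truth[:, j].max()
    ]
    assert auc_ma == pytest.approx(np.mean(expected), abs=1e-9)
    assert auc_mi == pytest.approx(
        auc_pair_oracle(scores.ravel(), truth.ravel()), abs=1e-9
    )


def test_auc_degenerate_label_skipped_and_random_scores_near_half():
    truth = np.zeros((200, 2), dtype=int)
    truth[:, 0] = (RNG.random(200) < 0.5).astype(int)
    scores = RNG.random((200, 2))
    auc_ma, _auc_mi, skipped = auc_macro_micro(scores, truth, ["a", "b"])
    assert skipped == ["b"]
    assert abs(auc_ma - 0.5) < 0.15  # scores independent of truth


def test_precision_at_n_brute_force_and_tie_break():
    scores = RNG.random((3, 6))
    truth = (RNG.random((3, 6)) < 0.5).astype(int)
    expected = np.mean(
        [
            sum(truth[i, j] for j in sorted(range(6), key=lambda j: (-scores[i, j], j))[:4]) / 4
            for i in range(3)
        ]
    )
    assert precision_at_n(scores, truth, n=4) == pytest.approx(expected)
    # explicit tie: equal scores resolved by ascending label index
    s = np.array([[0.5, 0.5, 0.1]])
    t = np.array([[0, 1, 0]])
    assert precision_at_n(s, t, n=1) == 0.0  # label 0 wins the tie
    with pytest.raises(ValueError):
        precision_at_n(s, t, n=4)


def test_precision_at_n_monotone_invariance():
    scores = RNG.random((10, 8))
    truth = (RNG.random((10, 8)) < 0.4).astype(int)
    base = precision_at_n(scores, truth, n=5)
    for transform in (lambda x: x**3, lambda x: 1 / (1 + np.exp(-5 * x)), lambda x: 10 * x - 2):
        assert precision_at_n(transform(scores), truth, n=5) == base


def test_metrics_invariant_under_document_shuffle():
    scores = RNG.random((25, 6))
    truth = (RNG.random((25, 6)) < 0.4).astype(int)
    truth[0] = 1
    truth[1] = 0
    perm = RNG.permutation(25)
    rep1 = evaluate_scores(scores, truth, list("abcdef"))
    rep2 = evaluate_scores(scores[perm], truth[perm], list("abcdef"))
    assert rep1.f1_macro == pytest.approx(rep2.f1_macro)
    assert rep1.auc_macro == pytest.approx(rep2.auc_macro)
    assert rep1.p_at_n == pytest.approx(rep2.p_at_n)


def test_paired_bootstrap_symmetry_dominance_and_determinism():
    truth = (RNG.random((40, 4)) < 0.5).astype(int)
    truth[:3] = 1
    scores = RNG.random((40, 4))

    def metric(s, t):
        return precision_at_n(s, t, n=2)

    p_same = paired_bootstrap(scores, scores, truth, metric, n_resamples=500, seed=1)
    assert p_same == 0.5  # every resample ties; ties count 1/2

    better = 0.9 * truth + 0.1 * scores  # strictly dominates on every doc
    p_dom = paired_bootstrap(better, scores, truth, metric, n_resamples=500, seed=1)
    assert p_dom < 0.05

    p_a = paired_bootstrap(scores, better, truth, metric, n_resamples=300, seed=9)
    p_b = paired_bootstrap(scores, better, truth, metric, n_resamples=300, seed=9)
    assert p_a == p_b

    with pytest.warns(RuntimeWarning):
        paired_bootstrap(scores, scores, truth, metric, n_resamples=50, seed=0)
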