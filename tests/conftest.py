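import numpy as np
import pytest

from swam.corpus_io import RawRecord
from swam.model import ModelConfig, SWAMModel


@pytest.fixture
def toy_records():
    """Ten documents over four patients with hand-countable token frequencies.

    Document frequencies of the content tokens:
      fever   -> 6 docs   cough -> 4 docs   pain -> 3 docs
      rash    -> 2 docs   vertigo -> 1 doc
    '100' never survives the alphabetic filter; '100ml' always does (5 docs).
    """
    texts = [
        "fever cough 100ml 100",
        "fever pain 100ml",
        "fever cough rash",
        "fever cough 100ml",
        "fever pain vertigo",
        "fever rash 100 100ml",
        "cough pain 100ml",
        "cough 100",
        "100 100",
        "plain 100",
    ]
    codes = [
        {"a", "b"}, {"a"}, {"a", "c"}, {"b"}, {"a"},
        {"b", "c"}, {"c"}, {"a"}, {"b"}, {"a"},
    ]
    return [
        RawRecord(patient_id=f"p{i % 4}", doc_id=f"d{i}", text=t, codes=c)
        for i, (t, c) in enumerate(zip(texts, codes))
    ]


@pytest.fixture
def micro_model():
    """A tiny per-label-attention model with deterministic parameters."""
    rng = np.random.default_rng(7)
    cfg = ModelConfig(n_labels=2, d_e=4, d_c=3, k=3, dropout=0.0)
    emb = rng.normal(size=(9, 4))
    emb[0] = 0.0
    return SWAMModel(cfg, emb, seed=11)


def finite_difference_grads(model, ids, y, eps=1e-6):
    """Central finite differences of the batch loss for every parameter."""
    num = {}
    for name, P in model.params.items():
        g = np.zeros_like(P)
        it = np.nditer(P, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            old = P[idx]
            P[idx] = old + eps
            lp = model.loss(model.forward_batch(ids), y)
            P[idx] = old - eps
            lm = model.loss(model.forward_batch(ids), y)
            P[idx] = old
            g[idx] = (lp - lm) / (2 * eps)
        num[name] = g
    return num
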