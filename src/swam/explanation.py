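"""Attention-based snippet explanations.

For the per-label attention head, the argmax of α_ℓ marks the document
position whose convolution window contributed most to the prediction of
code ℓ; the explanation is the k-token window of raw tokens aligned with
that convolution window (left offset ⌊(k−1)/2⌋, matching the padding
convention, clipped at document edges).  For the max-pool head there is no
α; the anchor is the pooled argmax position of the filter with the largest
|β_ℓ,j · v_j| contribution to the label's logit.

``filter_snippet_map`` supports the division-of-labor analysis: for each
convolution filter, the document windows with the highest activation —
after training on planted-snippet data, label-dedicated filters
concentrate on one snippet string.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from swam.model import ForwardState, SWAMModel, forward
from swam.preprocessing import TokenizedDoc, Vocabulary, decode

__all__ = [
    "SnippetExplanation",
    "snippet_window",
    "extract_snippet",
    "explain_dataset",
    "filter_snippet_map",
]


@dataclass
class SnippetExplanation:
    """The most informative k-token window for one (document, code) pair."""

    doc_id: str
    code: str
    snippet: list[str]
    position: int  # 0-based token index of the window start
    center: int  # the argmax position of α_ℓ (window anchor)
    attention: float
    score: float


def snippet_window(n_tokens: int, anchor: int, k: int) -> tuple[int, int]:
    """Token span [start, stop) of the convolution window anchored at a position.

    With pad-left ⌊(k−1)/2⌋, the window at position n covers original tokens
    ``n - ⌊(k−1)/2⌋ … n - ⌊(k−1)/2⌋ + k - 1``; the span is clipped to the
    document.  A document shorter than k yields the whole document.
    """
    if n_tokens <= k:
        return 0, n_tokens
    start = anchor - (k - 1) // 2
    start = max(0, min(start, n_tokens - k))
    return start, start + k


def extract_snippet(
    state: ForwardState,
    doc_tokens: Sequence[str],
    code: str,
    label_index: int,
    model: SWAMModel,
    doc_id: str = "",
) -> SnippetExplanation:
    """Extract the most informative snippet for one code from a forward pass.

    Ties in the attention weights break toward the earliest position
    (numpy argmax convention).
    """
    k = model.config.k
    n = len(doc_tokens)
    if model.config.attention == "per_label":
        alpha = state.A[label_index]
        anchor = int(np.argmax(alpha))
        weight = float(alpha[anchor])
    else:
        contrib = model.params["B"][:, label_index] * state.V[:, label_index]
        j_star = int(np.argmax(np.abs(contrib)))
        anchor = int(state.A[j_star])
        weight = float(state.V[j_star, label_index])
    start, stop = snippet_window(n, anchor, k)
    return SnippetExplanation(
        doc_id=doc_id,
        code=code,
        snippet=list(doc_tokens[start:stop]),
        position=start,
        center=anchor,
        attention=weight,
        score=float(state.yhat[label_index]),
    )


def explain_dataset(
    model: SWAMModel,
    docs: Sequence[TokenizedDoc],
    vocab: Vocabulary,
    codes: Sequence[str],
    only_positive_decisions: bool = True,
) -> list[SnippetExplanation]:
    """Explanations for every (document, code) pair, by default only where
    the model's decision is positive (score ≥ threshold)."""
    out: list[SnippetExplanation] = []
    for doc in docs:
        state = forward(doc.token_ids, model)
        tokens = decode(doc.token_ids, vocab)
        for j, code in enumerate(codes):
            if only_positive_decisions and state.yhat[j] < model.config.threshold:
                continue
            out.append(
                extract_snippet(state, tokens, code, j, model, doc_id=doc.doc_id)
            )
    return out


def filter_snippet_map(
    model: SWAMModel,
    docs: Sequence[TokenizedDoc],
    vocab: Vocabulary,
    top_m: int = 5,
) -> list[list[dict]]:
    """For each convolution filter, its ``top_m`` highest-activating windows.

    Returns one list per filter of dicts with ``doc_id``, ``position``
    (window start), ``activation`` and ``snippet`` (the k raw tokens),
    sorted by descending activation across the whole document set.
    """
    d_c, k = model.config.d_c, model.config.k
    if top_m == 0:
        return [[] for _ in range(d_c)]
    best: list[list[tuple[float, str, int, list[str]]]] = [[] for _ in range(d_c)]
    for doc in docs:
        state = forward(doc.token_ids, model)
        tokens = decode(doc.token_ids, vocab)
        H = state.H  # d_c × N
        n = H.shape[1]
        take = min(top_m, n)
        for j in range(d_c):
            idx = np.argpartition(-H[j], take - 1)[:take]
            for pos in idx:
                start, stop = snippet_window(n, int(pos), k)
                best[j].append(
                    (float(H[j, pos]), doc.doc_id, start, tokens[start:stop])
                )
            best[j].sort(key=lambda t: (-t[0], t[1], t[2]))
            del best[j][top_m:]
    return [
        [
            {"activation": act, "doc_id": did, "position": pos, "snippet": snip}
            for act, did, pos, snip in rows
        ]
        for rows in best
    ]
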