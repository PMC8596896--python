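"""Planted-snippet corpus generator.

The generator emulates the statistical structure the shallow-and-wide
architecture assumes about clinical notes: most of a document is
uninformative, and each code is signalled by one or more short
label-specific ("non-generic") phrases, plus optional "generic" phrases
shared by a small group of labels, all scattered at uniformly random
positions inside long stretches of noise tokens.  Noise tokens follow a
Zipf-like long-tail distribution so the minimum-document-frequency
vocabulary filter is actually exercised.  Snippet vocabularies are
disjoint from the noise vocabulary by default so ground-truth audits of
extracted explanations are unambiguous.

With ``plant_prob = 1`` the corpus is exactly separable: a
string-matching oracle (:func:`bayes_optimal_reference`) attains macro-F1
1.0, giving the ceiling against which trained models are compared.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from swam.corpus_io import RawRecord

__all__ = [
    "SyntheticSpec",
    "PlantedSnippet",
    "SyntheticTruth",
    "generate_corpus",
    "bayes_optimal_reference",
    "match_snippets",
]


@dataclass
class SyntheticSpec:
    """Generative parameters for a planted-snippet corpus.

    Defaults are the desk-scale study conditions: 10 labels with two
    dedicated 3-token snippet phrases each, three generic snippets shared
    by label pairs, 300-token documents, 2000 documents over 400 patients,
    fully separable (``plant_prob = 1``).
    """

    n_labels: int = 10
    snippets_per_label: int = 2
    snippet_len: int = 3
    n_generic: int = 3
    generic_group_size: int = 2
    vocab_noise: int = 5000
    doc_len: int = 300
    label_prob: float = 0.3
    plant_prob: float = 1.0
    n_docs: int = 2000
    n_patients: int = 400
    seed: int = 0
    hard_mode: bool = False  # snippet tokens drawn from the noise vocabulary

    def __post_init__(self) -> None:
        for name in ("n_labels", "snippets_per_label", "snippet_len",
                     "vocab_noise", "doc_len", "n_docs", "n_patients"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.label_prob < 1.0):
            raise ValueError("label_prob must be in (0, 1)")
        if not (0.0 < self.plant_prob <= 1.0):
            raise ValueError("plant_prob must be in (0, 1]")
        if self.n_generic < 0 or self.generic_group_size < 2:
            raise ValueError("n_generic >= 0 and generic_group_size >= 2 required")


@dataclass
class PlantedSnippet:
    """One planted phrase occurrence: where it sits and which label owns it."""

    phrase: str
    position: int  # token index of the first snippet token
    label: str
    generic: bool = False


@dataclass
class SyntheticTruth:
    """Ground truth sidecar: planted snippets per doc_id."""

    snippets: dict[str, list[PlantedSnippet]] = field(default_factory=dict)
    label_phrases: dict[str, list[str]] = field(default_factory=dict)
    generic_phrases: dict[str, list[str]] = field(default_factory=dict)


def write_truth(truth: SyntheticTruth, path) -> None:
    """Write the ground-truth sidecar as JSON-lines.

    The first line carries the phrase inventories (``doc_id`` null); each
    following line lists the planted snippets of one document.
    """
    import json
    from pathlib import Path

    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(
            json.dumps(
                {
                    "doc_id": None,
                    "label_phrases": truth.label_phrases,
                    "generic_phrases": truth.generic_phrases,
                }
            )
            + "\n"
        )
        for doc_id, snippets in truth.snippets.items():
            fh.write(
                json.dumps(
                    {
                        "doc_id": doc_id,
                        "snippets": [
                            {
                                "phrase": s.phrase,
                                "position": s.position,
                                "label": s.label,
                                "generic": s.generic,
                            }
                            for s in snippets
                        ],
                    }
                )
                + "\n"
            )


def read_truth(path) -> SyntheticTruth:
    """Inverse of :func:`write_truth`."""
    import json
    from pathlib import Path

    truth = SyntheticTruth()
    with Path(path).open(encoding="utf-8") as fh:
        header = json.loads(fh.readline())
        truth.label_phrases = header["label_phrases"]
        truth.generic_phrases = header["generic_phrases"]
        for line in fh:
            if not line.strip():
                continue
            row = json.loads(line)
            truth.snippets[row["doc_id"]] = [
                PlantedSnippet(**s) for s in row["snippets"]
            ]
    return truth


def _label_codes(n: int) -> list[str]:
    # clinical-code-looking labels: "c00.0", "c01.0", ...
    return [f"c{i:02d}.0" for i in range(n)]


def _make_phrases(spec: SyntheticSpec, rng: np.random.Generator) -> tuple[dict, dict]:
    """Build mutually distinct snippet phrases per label plus generic phrases."""
    codes = _label_codes(spec.n_labels)
    label_phrases: dict[str, list[str]] = {}
    for li, code in enumerate(codes):
        label_phrases[code] = [
            " ".join(
                f"sig{li:02d}x{si}t{j}" for j in range(spec.snippet_len)
            )
            for si in range(spec.snippets_per_label)
        ]
    generic_phrases: dict[str, list[str]] = {c: [] for c in codes}
    for gi in range(spec.n_generic):
        group = rng.choice(spec.n_labels, size=min(spec.generic_group_size, spec.n_labels), replace=False)
        phrase = " ".join(f"gen{gi:02d}t{j}" for j in range(spec.snippet_len))
        for li in group:
            generic_phrases[codes[li]].append(phrase)
    if spec.hard_mode:
        # overlap with the noise vocabulary: rebuild phrases from noise words
        for code in codes:
            label_phrases[code] = [
                " ".join(
                    f"w{int(w):05d}"
                    for w in rng.integers(0, spec.vocab_noise, size=spec.snippet_len)
                )
                for _ in range(spec.snippets_per_label)
            ]
    return label_phrases, generic_phrases


def generate_corpus(
    spec: SyntheticSpec,
) -> tuple[list[RawRecord], SyntheticTruth]:
    """Generate a planted-snippet corpus, fully deterministic under the seed.

    For each document: labels are independent Bernoulli(``label_prob``)
    draws, resampled until at least one is true; each true label plants one
    of its non-generic phrases with probability ``plant_prob`` at a uniform
    position; each generic phrase whose group contains a true label is
    planted likewise; remaining positions are Zipf(1.1)-distributed noise
    words.  Overlapping insertions are resolved by redrawing the position.
    Documents are assigned round-robin to ``n_patients`` patients.
    """
    rng = np.random.default_rng(spec.seed)
    codes = _label_codes(spec.n_labels)
    label_phrases, generic_phrases = _make_phrases(spec, rng)
    # invert generic map: phrase -> owning labels
    generic_owner: dict[str, list[str]] = {}
    for code, phrases in generic_phrases.items():
        for ph in phrases:
            generic_owner.setdefault(ph, []).append(code)

    # Zipf-like noise distribution over a synthetic word list
    ranks = np.arange(1, spec.vocab_noise + 1, dtype=np.float64)
    p_noise = ranks ** -1.1
    p_noise /= p_noise.sum()
    noise_words = np.array([f"w{i:05d}" for i in range(spec.vocab_noise)])

    truth = SyntheticTruth(
        label_phrases=label_phrases, generic_phrases=generic_phrases
    )
    records: list[RawRecord] = []
    for di in range(spec.n_docs):
        while True:
            y = rng.random(spec.n_labels) < spec.label_prob
            if y.any():
                break
        true_codes = [codes[i] for i in np.flatnonzero(y)]
        n = int(spec.doc_len)
        tokens = noise_words[rng.choice(spec.vocab_noise, size=n, p=p_noise)].tolist()

        planned: list[tuple[str, str, bool]] = []  # (phrase, label, generic)
        for code in true_codes:
            if rng.random() < spec.plant_prob:
                phrase = label_phrases[code][
                    int(rng.integers(len(label_phrases[code])))
                ]
                planned.append((phrase, code, False))
        for phrase, owners in generic_owner.items():
            if any(c in true_codes for c in owners) and rng.random() < spec.plant_prob:
                planned.append((phrase, owners[0], True))

        occupied = np.zeros(n, dtype=bool)
        doc_snippets: list[PlantedSnippet] = []
        for phrase, code, generic in planned:
            words = phrase.split()
            if len(words) > n:
                raise ValueError("document too short to hold a snippet")
            for _attempt in range(1000):
                start = int(rng.integers(0, n - len(words) + 1))
                if not occupied[start : start + len(words)].any():
                    break
            else:
                raise ValueError("could not place snippet without overlap")
            occupied[start : start + len(words)] = True
            tokens[start : start + len(words)] = words
            doc_snippets.append(
                PlantedSnippet(phrase=phrase, position=start, label=code,
                               generic=generic)
            )
        doc_id = f"d{di:05d}"
        truth.snippets[doc_id] = doc_snippets
        records.append(
            RawRecord(
                patient_id=f"p{di % spec.n_patients:05d}",
                doc_id=doc_id,
                text=" ".join(tokens),
                codes=set(true_codes),
            )
        )
    return records, truth


def match_snippets(tokens: Sequence[str], phrases: Sequence[str]) -> bool:
    """True iff any phrase occurs as a contiguous token run in ``tokens``."""
    joined = " " + " ".join(tokens) + " "
    return any(" " + ph + " " in joined for ph in phrases)


def bayes_optimal_reference(
    spec_or_truth: SyntheticSpec | SyntheticTruth,
    records: Sequence[RawRecord],
    truth: SyntheticTruth | None = None,
):
    """Score the string-matching oracle "predict ℓ iff one of ℓ's non-generic
    phrases occurs" with the standard metric suite.

    At ``plant_prob = 1`` this classifier is exact (macro-F1 1.0); at lower
    plant probability its per-label recall ≈ plant_prob with precision 1,
    giving the performance ceiling for trained models on the same corpus.
    """
    from swam.evaluation import evaluate_scores
    from swam.preprocessing import tokenize

    if isinstance(spec_or_truth, SyntheticTruth):
        truth = spec_or_truth
    if truth is None:
        raise ValueError("need a SyntheticTruth carrying the label phrases")
    if len(records) == 0:
        raise ValueError("empty corpus")
    codes = sorted(truth.label_phrases)
    scores = np.zeros((len(records), len(codes)))
    y = np.zeros_like(scores, dtype=np.int8)
    for i, rec in enumerate(records):
        tokens = tokenize(rec.text)
        for j, code in enumerate(codes):
            if match_snippets(tokens, truth.label_phrases[code]):
                scores[i, j] = 1.0
            y[i, j] = 1 if code in rec.codes else 0
    return evaluate_scores(scores, y, codes, threshold=0.5, n=min(5, len(codes)))
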