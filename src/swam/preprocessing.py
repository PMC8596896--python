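"""Raw records → integer-encoded documents with a top-k label space.

The pipeline mirrors standard clinical-NLP practice for discharge-summary
coding: lowercase, split on non-alphanumeric runs, drop tokens without any
alphabetic character (``"100"`` goes, ``"100ml"`` stays), keep tokens that
appear in at least ``min_doc_freq`` training documents (default 3), map the
rest to ``UNK``, truncate each document to its first ``max_len`` tokens
(default 2500), restrict labels to the ``k`` most frequent codes (default
50), and split train/validation/test by patient so no patient's documents
leak across partitions.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from swam.corpus_io import RawRecord

__all__ = [
    "PAD_TOKEN",
    "UNK_TOKEN",
    "Vocabulary",
    "LabelSpace",
    "TokenizedDoc",
    "SplitAssignment",
    "tokenize",
    "build_vocabulary",
    "encode",
    "decode",
    "select_top_labels",
    "split_by_patient",
    "prepare_dataset",
    "Dataset",
]

PAD_TOKEN = "<pad>"
UNK_TOKEN = "UNK"

_TOKEN_SPLIT = re.compile(r"[^a-z0-9]+")
_HAS_ALPHA = re.compile(r"[a-z]")


def tokenize(text: str) -> list[str]:
    """Lowercase, split on non-alphanumeric runs, drop purely numeric tokens.

    A token is kept only if it contains at least one ASCII letter after
    lowercasing, so ``"Gave 100 ml"`` → ``["gave", "ml"]`` and ``"100ml
    saline"`` → ``["100ml", "saline"]``.
    """
    tokens = _TOKEN_SPLIT.split(text.lower())
    return [t for t in tokens if t and _HAS_ALPHA.search(t)]


@dataclass
class Vocabulary:
    """Token↔id maps with reserved PAD (id 0) and UNK (id 1) entries.

    ``stats`` records how the vocabulary was built: total distinct token
    types seen, how many were dropped by the alphabetic filter (only
    non-zero when built from raw text) and how many failed the
    document-frequency threshold.
    """

    token_to_id: dict[str, int]
    id_to_token: list[str]
    min_doc_freq: int
    stats: dict[str, int] = field(default_factory=dict)

    pad_id: int = 0
    unk_id: int = 1

    def __len__(self) -> int:
        return len(self.id_to_token)

    def __contains__(self, token: str) -> bool:
        return token in self.token_to_id

    def get(self, token: str) -> int:
        return self.token_to_id.get(token, self.unk_id)

    def save(self, path: str | Path) -> None:
        """Write a two-column (token, id) text file plus a JSON stats sidecar."""
        path = Path(path)
        with path.open("w", encoding="utf-8") as fh:
            for idx, tok in enumerate(self.id_to_token):
                fh.write(f"{tok}\t{idx}\n")
        sidecar = path.with_suffix(path.suffix + ".stats.json")
        sidecar.write_text(
            json.dumps({"min_doc_freq": self.min_doc_freq, **self.stats}, indent=2)
        )

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        path = Path(path)
        id_to_token: list[str] = []
        with path.open(encoding="utf-8") as fh:
            for line in fh:
                tok, idx = line.rstrip("\n").split("\t")
                assert int(idx) == len(id_to_token), "vocabulary file out of order"
                id_to_token.append(tok)
        sidecar = path.with_suffix(path.suffix + ".stats.json")
        stats = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        min_df = stats.pop("min_doc_freq", 0)
        return cls(
            token_to_id={t: i for i, t in enumerate(id_to_token)},
            id_to_token=id_to_token,
            min_doc_freq=min_df,
            stats=stats,
        )


@dataclass
class LabelSpace:
    """Ordered list of retained codes (descending train frequency, ties by code)."""

    codes: list[str]
    code_to_index: dict[str, int]

    @property
    def k(self) -> int:
        return len(self.codes)

    def __len__(self) -> int:
        return len(self.codes)

    def vector(self, codes: Iterable[str]) -> np.ndarray:
        y = np.zeros(len(self.codes), dtype=np.int8)
        for c in codes:
            idx = self.code_to_index.get(c)
            if idx is not None:
                y[idx] = 1
        return y

    def save(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.codes) + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "LabelSpace":
        codes = Path(path).read_text(encoding="utf-8").split()
        return cls(codes=codes, code_to_index={c: i for i, c in enumerate(codes)})


@dataclass
class TokenizedDoc:
    """One encoded document: id sequence (≤ max_len) plus its label vector."""

    doc_id: str
    patient_id: str
    token_ids: np.ndarray
    label_vector: np.ndarray


@dataclass
class SplitAssignment:
    """Patient → partition map; every document follows its patient."""

    assignment: dict[str, str]
    fractions: tuple[float, float, float]
    seed: int

    def partition_of(self, patient_id: str) -> str:
        return self.assignment[patient_id]


def build_vocabulary(
    train_docs: Sequence[Sequence[str]], min_doc_freq: int = 3
) -> Vocabulary:
    """Build the vocabulary from TRAINING documents only.

    A token type is retained iff it contains an alphabetic character (assumed
    already enforced by :func:`tokenize`) and occurs in at least
    ``min_doc_freq`` distinct training documents.  Retained tokens are
    ordered by descending document frequency, ties broken alphabetically, so
    the id assignment is deterministic.
    """
    if len(train_docs) == 0:
        raise ValueError("cannot build a vocabulary from an empty training set")
    doc_freq: Counter[str] = Counter()
    n_alpha_dropped = 0
    for doc in train_docs:
        kept = set()
        for tok in set(doc):
            if _HAS_ALPHA.search(tok):
                kept.add(tok)
            else:
                n_alpha_dropped += 1
        doc_freq.update(kept)
    retained = sorted(
        (t for t, c in doc_freq.items() if c >= min_doc_freq),
        key=lambda t: (-doc_freq[t], t),
    )
    id_to_token = [PAD_TOKEN, UNK_TOKEN] + retained
    return Vocabulary(
        token_to_id={t: i for i, t in enumerate(id_to_token)},
        id_to_token=id_to_token,
        min_doc_freq=min_doc_freq,
        stats={
            "types_seen": len(doc_freq) + n_alpha_dropped,
            "types_dropped_alphabetic": n_alpha_dropped,
            "types_dropped_frequency": len(doc_freq) - len(retained),
        },
    )


def encode(
    doc: Sequence[str], vocab: Vocabulary, max_len: int = 2500
) -> np.ndarray:
    """Map tokens to ids (OOV → UNK) and truncate to the first ``max_len``."""
    ids = [vocab.get(t) for t in doc[:max_len]]
    return np.asarray(ids, dtype=np.int64)


def decode(token_ids: Sequence[int], vocab: Vocabulary) -> list[str]:
    """Inverse of :func:`encode` up to OOV tokens, which come back as UNK."""
    return [vocab.id_to_token[int(i)] for i in token_ids]


def select_top_labels(
    records: Sequence[RawRecord], k: int = 50
) -> tuple[LabelSpace, list[RawRecord]]:
    """Keep the ``k`` most frequent codes; drop records with none of them.

    Frequencies are counted over the full record set before splitting.
    Retained records keep only their retained codes.  Ordering of the label
    space is by descending frequency with ties broken by code string.
    """
    freq: Counter[str] = Counter()
    for rec in records:
        freq.update(rec.codes)
    if len(freq) < k:
        raise ValueError(f"corpus has {len(freq)} distinct codes, need at least {k}")
    top = sorted(freq, key=lambda c: (-freq[c], c))[:k]
    space = LabelSpace(codes=top, code_to_index={c: i for i, c in enumerate(top)})
    kept_codes = set(top)
    filtered = []
    for rec in records:
        retained = rec.codes & kept_codes
        if retained:
            filtered.append(
                RawRecord(rec.patient_id, rec.doc_id, rec.text, retained)
            )
    return space, filtered


def split_by_patient(
    records: Sequence[RawRecord],
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> SplitAssignment:
    """Randomly partition patients into train/valid/test with the given seed.

    All documents of a patient land in the same partition, so no patient can
    appear in two of them.  Fractions must sum to 1.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    patients = sorted({rec.patient_id for rec in records})
    if len(patients) < 3:
        raise ValueError(f"need at least 3 patients to split, got {len(patients)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    n_train = int(round(fractions[0] * len(patients)))
    n_valid = int(round(fractions[1] * len(patients)))
    assignment: dict[str, str] = {}
    for rank, idx in enumerate(order):
        if rank < n_train:
            part = "train"
        elif rank < n_train + n_valid:
            part = "valid"
        else:
            part = "test"
        assignment[patients[idx]] = part
    return SplitAssignment(assignment=assignment, fractions=fractions, seed=seed)


@dataclass
class Dataset:
    """Fully preprocessed corpus ready for training."""

    vocab: Vocabulary
    label_space: LabelSpace
    train: list[TokenizedDoc]
    valid: list[TokenizedDoc]
    test: list[TokenizedDoc]

    @property
    def splits(self) -> dict[str, list[TokenizedDoc]]:
        return {"train": self.train, "valid": self.valid, "test": self.test}


def prepare_dataset(
    records: Sequence[RawRecord],
    k: int = 50,
    min_doc_freq: int = 3,
    max_len: int = 2500,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> Dataset:
    """Run the whole pipeline: label filter → patient split → vocab → encode.

    Label frequencies are counted on the full corpus before splitting; the
    vocabulary is built from the training partition only, so validation and
    test tokens never influence it.
    """
    label_space, filtered = select_top_labels(records, k=k)
    split = split_by_patient(filtered, fractions=fractions, seed=seed)
    tokenized = {rec.doc_id: tokenize(rec.text) for rec in filtered}
    train_tokens = [
        tokenized[rec.doc_id]
        for rec in filtered
        if split.partition_of(rec.patient_id) == "train"
    ]
    vocab = build_vocabulary(train_tokens, min_doc_freq=min_doc_freq)
    buckets: dict[str, list[TokenizedDoc]] = {"train": [], "valid": [], "test": []}
    for rec in filtered:
        part = split.partition_of(rec.patient_id)
        buckets[part].append(
            TokenizedDoc(
                doc_id=rec.doc_id,
                patient_id=rec.patient_id,
                token_ids=encode(tokenized[rec.doc_id], vocab, max_len=max_len),
                label_vector=label_space.vector(rec.codes),
            )
        )
    return Dataset(
        vocab=vocab,
        label_space=label_space,
        train=buckets["train"],
        valid=buckets["valid"],
        test=buckets["test"],
    )
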