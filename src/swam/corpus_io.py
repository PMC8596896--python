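"""Readers and writers for the package's external data formats.

Canonical corpus format is JSON-lines — one object per document with keys
``patient_id``, ``doc_id``, ``text`` and ``codes`` (a list of code strings).
Clinical text routinely contains commas, semicolons and newlines, so a
line-delimited JSON container is the only delimiter-safe choice; CSV is
supported as a convenience with codes joined by ``";"``.  Word vectors use
the word2vec text format (header line ``V D`` followed by one token and D
floats per line).  All files are UTF-8.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "RawRecord",
    "PredictionRecord",
    "CorpusFormatError",
    "read_corpus",
    "write_corpus",
    "read_word2vec_text",
    "write_word2vec_text",
    "write_predictions",
    "read_predictions",
    "write_explanations",
    "read_explanations",
]


class CorpusFormatError(ValueError):
    """Raised when an input file violates the documented corpus schema."""


@dataclass
class RawRecord:
    """One clinical document: free text plus its set of code labels."""

    patient_id: str
    doc_id: str
    text: str
    codes: set[str] = field(default_factory=set)


@dataclass
class PredictionRecord:
    """Per-document model output: a probability and a binary decision per code."""

    doc_id: str
    scores: dict[str, float]
    decisions: dict[str, int]


_REQUIRED_COLUMNS = ("patient_id", "doc_id", "text", "codes")


def _check_columns(row: dict, where: str) -> None:
    for col in _REQUIRED_COLUMNS:
        if col not in row:
            raise CorpusFormatError(f"{where}: missing required column '{col}'")


def read_corpus(path: str | Path, format: str | None = None) -> list[RawRecord]:
    """Read a labeled document corpus from a JSON-lines or CSV file.

    Parameters
    ----------
    path:
        Input file.  If ``format`` is None it is inferred from the suffix
        (``.csv`` → csv, anything else → jsonl).
    format:
        ``"jsonl"`` or ``"csv"``.  In CSV, the ``codes`` cell holds
        ``";"``-joined code strings.

    Returns
    -------
    list of :class:`RawRecord` in file order, codes deduplicated.

    Raises
    ------
    CorpusFormatError
        On a missing column or a duplicate ``doc_id``.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format not in ("jsonl", "csv"):
        raise ValueError(f"unknown corpus format: {format!r}")

    records: list[RawRecord] = []
    seen: set[str] = set()
    if format == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                row = json.loads(line)
                _check_columns(row, f"{path}:{lineno}")
                codes = row["codes"]
                if isinstance(codes, str):
                    codes = [c for c in codes.split(";") if c]
                records.append(
                    RawRecord(
                        patient_id=str(row["patient_id"]),
                        doc_id=str(row["doc_id"]),
                        text=str(row["text"]),
                        codes={str(c) for c in codes},
                    )
                )
    else:
        with path.open(encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            for lineno, row in enumerate(reader, start=2):
                _check_columns(row, f"{path}:{lineno}")
                codes = {c for c in (row["codes"] or "").split(";") if c}
                records.append(
                    RawRecord(
                        patient_id=row["patient_id"],
                        doc_id=row["doc_id"],
                        text=row["text"],
                        codes=codes,
                    )
                )
    for rec in records:
        if rec.doc_id in seen:
            raise CorpusFormatError(f"{path}: duplicate doc_id '{rec.doc_id}'")
        seen.add(rec.doc_id)
    return records


def write_corpus(records: Iterable[RawRecord], path: str | Path) -> None:
    """Write records as canonical JSON-lines (codes sorted for byte stability)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(
                json.dumps(
                    {
                        "patient_id": rec.patient_id,
                        "doc_id": rec.doc_id,
                        "text": rec.text,
                        "codes": sorted(rec.codes),
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_word2vec_text(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read embeddings in the word2vec text format.

    Returns ``(tokens, matrix)`` with ``matrix`` of shape ``V × D`` and rows
    in file order.

    Raises
    ------
    CorpusFormatError
        If the header does not match the number or width of the rows.
    """
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise CorpusFormatError(f"{path}: malformed word2vec header {header!r}")
        n_vec, dim = int(header[0]), int(header[1])
        tokens: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split(" ")
            if len(parts) < 2:
                continue
            if len(parts) != dim + 1:
                raise CorpusFormatError(
                    f"{path}:{lineno}: expected {dim} values, got {len(parts) - 1}"
                )
            tokens.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    if len(tokens) != n_vec:
        raise CorpusFormatError(
            f"{path}: header promises {n_vec} vectors, file has {len(tokens)}"
        )
    return tokens, np.asarray(rows, dtype=np.float64)


def write_word2vec_text(
    tokens: Sequence[str], matrix: np.ndarray, path: str | Path
) -> None:
    """Write embeddings in the word2vec text format (full float precision)."""
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[0] != len(tokens):
        raise ValueError("matrix must be 2-D with one row per token")
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"{matrix.shape[0]} {matrix.shape[1]}\n")
        for tok, row in zip(tokens, matrix):
            fh.write(tok + " " + " ".join(repr(float(v)) for v in row) + "\n")


def write_predictions(records: Iterable[PredictionRecord], path: str | Path) -> None:
    """Write predictions as TSV: one row per (doc_id, code, score, decision)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("doc_id\tcode\tscore\tdecision\n")
        for rec in records:
            for code in rec.scores:
                fh.write(
                    f"{rec.doc_id}\t{code}\t{rec.scores[code]:.6f}\t"
                    f"{rec.decisions[code]}\n"
                )


def read_predictions(path: str | Path) -> list[PredictionRecord]:
    """Read the TSV prediction format back into records (rows grouped by doc)."""
    path = Path(path)
    by_doc: dict[str, PredictionRecord] = {}
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["doc_id", "code", "score", "decision"]:
            raise CorpusFormatError(f"{path}: unexpected prediction header {header}")
        for line in fh:
            doc_id, code, score, decision = line.rstrip("\n").split("\t")
            rec = by_doc.setdefault(doc_id, PredictionRecord(doc_id, {}, {}))
            rec.scores[code] = float(score)
            rec.decisions[code] = int(decision)
    return list(by_doc.values())


def write_explanations(records: Iterable, path: str | Path) -> None:
    """Write snippet explanations as JSON-lines, one object per (doc, code).

    ``records`` are :class:`swam.explanation.SnippetExplanation` dataclasses
    (or any dataclass with equivalent fields).
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(dataclasses.asdict(rec), ensure_ascii=False) + "\n")


def read_explanations(path: str | Path) -> list:
    """Read JSON-lines explanations back into dataclass objects."""
    from swam.explanation import SnippetExplanation

    out = []
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                out.append(SnippetExplanation(**json.loads(line)))
    return out
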