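"""Parsers and I/O for the three corpus dialects.

Three kinds of raw sequence records are supported:

* ``aurignacian`` — engraved-sign codings where each UTF-8 character is one
  sign token. Annotation markup is stripped: ``!`` marks broken pieces,
  round brackets enclose signs that are not visually discrete, square
  brackets enclose signs that are not in linear order; bracketed spans are
  removed wholesale. Underscores separate parts of an object and are kept
  as ordinary tokens.
* ``protocuneiform`` — CDLI-style transliterations: whitespace-separated
  sign names (``N01``, ``UDU~a`` ...), with numeric repetition notation
  ``k(SIGN)`` expanded into k adjacent tokens and standalone underscores
  marking visual groups.
* ``modern_text`` — lines of modern written language; each UTF-8 character
  (including internal whitespace) is a token, punctuation and characters
  outside the script's character set are dropped.

Records that are empty after cleaning are never silently discarded: the
single-record parsers raise :class:`EmptySequenceError`, and the batch
cleaner counts them in a :class:`PreprocessingReport`.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .sequence import TokenSequence

DIALECTS = ("aurignacian", "protocuneiform", "modern_text")

#: Default CDLI annotation markup stripped from protocuneiform
#: transliterations (damage / uncertainty / correction markers and the
#: brackets around partially broken sign names). The set is configurable
#: because the full annotation grammar varies between corpus exports.
DEFAULT_PROTOCUNEIFORM_ANNOTATIONS: tuple[str, ...] = (r"[#?!]", r"[\[\]]")

_REPEAT_RE = re.compile(r"^(\d+)\((.+)\)$")


class MalformedRecordError(ValueError):
    """Raised when a raw record cannot be parsed under its dialect's grammar."""

    def __init__(self, source_id: str, reason: str):
        self.source_id = source_id
        self.reason = reason
        super().__init__(f"malformed record {source_id!r}: {reason}")


class EmptySequenceError(ValueError):
    """Raised when a record has no tokens left after cleaning."""

    def __init__(self, source_id: str):
        self.source_id = source_id
        super().__init__(f"record {source_id!r} is empty after cleaning")


@dataclass(frozen=True)
class RawRecord:
    """One uncleaned sequence record as distributed in a corpus table."""

    source_id: str
    corpus_label: str
    dialect: str
    raw: str
    script_charset: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.dialect not in DIALECTS:
            raise ValueError(
                f"unknown dialect {self.dialect!r}; expected one of {DIALECTS}"
            )


@dataclass
class PreprocessingReport:
    """Bookkeeping for a batch cleaning pass."""

    n_input: int = 0
    n_kept: int = 0
    n_empty: int = 0
    empty_source_ids: list[str] = field(default_factory=list)


def parse_aurignacian(record: RawRecord) -> TokenSequence:
    """Clean an engraved-sign coding and split it into one-character tokens.

    Removes ``!`` annotation marks and spans enclosed in round or square
    brackets (non-discrete and non-linear signs respectively). Nested,
    overlapping, or unbalanced brackets are rejected as malformed.
    """
    if record.dialect != "aurignacian":
        raise ValueError(f"expected dialect 'aurignacian', got {record.dialect!r}")
    out: list[str] = []
    open_bracket: str | None = None
    for ch in record.raw.strip():
        if ch in "([":
            if open_bracket is not None:
                raise MalformedRecordError(record.source_id, "nested brackets")
            open_bracket = ch
        elif ch in ")]":
            if open_bracket is None or {"(": ")", "[": "]"}[open_bracket] != ch:
                raise MalformedRecordError(
                    record.source_id, f"unbalanced bracket {ch!r}"
                )
            open_bracket = None
        elif open_bracket is not None or ch == "!":
            continue
        else:
            out.append(ch)
    if open_bracket is not None:
        raise MalformedRecordError(record.source_id, "unclosed bracket")
    if not out:
        raise EmptySequenceError(record.source_id)
    return TokenSequence(tuple(out), record.corpus_label, record.source_id)


def parse_protocuneiform(
    record: RawRecord,
    annotation_patterns: Sequence[str] = DEFAULT_PROTOCUNEIFORM_ANNOTATIONS,
) -> TokenSequence:
    """Expand a transliteration into sign-name tokens.

    Whitespace delimits tokens and is never itself a token. Repetition
    notation ``k(SIGN)`` expands to k adjacent copies of SIGN; standalone
    underscores (visual-group separators) are kept as tokens.
    """
    if record.dialect != "protocuneiform":
        raise ValueError(f"expected dialect 'protocuneiform', got {record.dialect!r}")
    text = record.raw
    for pat in annotation_patterns:
        text = re.sub(pat, "", text)
    tokens: list[str] = []
    for word in text.split():
        m = _REPEAT_RE.match(word)
        if m:
            tokens.extend([m.group(2)] * int(m.group(1)))
        elif word.count("(") != word.count(")"):
            raise MalformedRecordError(record.source_id, f"unclosed parenthesis in {word!r}")
        elif re.match(r"^[^(]*\(", word) and not _REPEAT_RE.match(word):
            # parenthesized but not k(SIGN): either a malformed repetition
            # count or markup the annotation patterns did not cover
            raise MalformedRecordError(
                record.source_id, f"non-integer repetition count in {word!r}"
            )
        else:
            tokens.append(word)
    if not tokens:
        raise EmptySequenceError(record.source_id)
    return TokenSequence(tuple(tokens), record.corpus_label, record.source_id)


def parse_modern_text(record: RawRecord) -> TokenSequence:
    """Tokenize a line of modern writing into single UTF-8 characters.

    Punctuation (Unicode general categories ``P*``) is removed. If the
    record carries a ``script_charset``, characters outside it are removed
    as well (whitespace is always retained: a space is a sign). Case is
    preserved — upper and lower case are distinct sign types.
    """
    if record.dialect != "modern_text":
        raise ValueError(f"expected dialect 'modern_text', got {record.dialect!r}")
    out: list[str] = []
    for ch in record.raw.strip():
        if unicodedata.category(ch).startswith("P"):
            continue
        if ch.isspace():
            out.append(" ")
            continue
        if record.script_charset is not None and ch not in record.script_charset:
            continue
        out.append(ch)
    if not out:
        raise EmptySequenceError(record.source_id)
    return TokenSequence(tuple(out), record.corpus_label, record.source_id)


_PARSERS = {
    "aurignacian": parse_aurignacian,
    "protocuneiform": parse_protocuneiform,
    "modern_text": parse_modern_text,
}


def parse_record(record: RawRecord) -> TokenSequence:
    """Dispatch a record to its dialect's parser."""
    return _PARSERS[record.dialect](record)


def clean_corpus(
    records: Iterable[RawRecord],
) -> tuple[list[TokenSequence], PreprocessingReport]:
    """Parse a batch of records, dropping (and counting) empty-after-cleaning ones.

    Malformed records are not tolerated and propagate as
    :class:`MalformedRecordError`.
    """
    report = PreprocessingReport()
    kept: list[TokenSequence] = []
    for rec in records:
        report.n_input += 1
        try:
            kept.append(parse_record(rec))
            report.n_kept += 1
        except EmptySequenceError:
            report.n_empty += 1
            report.empty_source_ids.append(rec.source_id)
    return kept, report


def subsample_corpus(
    sequences: Sequence[TokenSequence], n_target: int, seed: int
) -> list[TokenSequence]:
    """Uniform random subsample without replacement, capped at the corpus size.

    Used to avoid over-representing the large subcorpora: each is cut down
    to a common target (1,000 in the study design) before classification.
    """
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    n = min(n_target, len(sequences))
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(sequences), size=n, replace=False)
    return [sequences[i] for i in sorted(idx)]


def to_canonical_text(seq: TokenSequence, dialect: str) -> str:
    """Render a cleaned sequence back to its dialect's canonical raw form."""
    if dialect == "protocuneiform":
        return " ".join(seq.tokens)
    return "".join(seq.tokens)


def read_sequence_table(path: str | Path) -> list[RawRecord]:
    """Read a delimited table of raw records.

    Expects columns ``source_id``, ``corpus_label``, ``dialect``, ``raw``;
    the delimiter is taken from the extension (``.tsv`` → tab, else comma).
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    required = {"source_id", "corpus_label", "dialect", "raw"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        RawRecord(r.source_id, r.corpus_label, r.dialect, r.raw)
        for r in df.itertuples(index=False)
    ]


def write_token_table(
    sequences: Iterable[TokenSequence], path: str | Path, delimiter: str = " "
) -> None:
    """Write one row per cleaned sequence, tokens joined by ``delimiter``."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    rows = [
        {
            "source_id": s.source_id,
            "corpus_label": s.corpus_label,
            "n_tokens": s.n_tokens,
            "n_types": s.n_types,
            "tokens": delimiter.join(s.tokens),
        }
        for s in sequences
    ]
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
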