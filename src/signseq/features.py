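"""Per-sequence statistical features.

Four statistics summarize the "statistical fingerprint" of a symbol
sequence s = (t'_1, ..., t'_n) over a vocabulary of m distinct sign types:

* **type-token ratio** TTR = m / n — lexical diversity baseline;
* **unigram entropy** H = -sum_t p(t) log2 p(t) with the maximum-likelihood
  (plug-in) probabilities p(t) = f_t / n, in bits per sign;
* **entropy rate** h — the increasing-window LZ78 estimator
  h = (1/n) * sum_{i=2..n} log2(i) / L_i, where L_i is one plus the length
  of the longest contiguous subsequence starting at position i that also
  occurs entirely within the prefix (positions 1..i-1). Repetitive
  sequences yield long matches, hence low rates;
* **repetition rate** r — the fraction of adjacent identical token pairs.
  Two normalizations exist: ``sproat`` divides the count of adjacent
  repeats by sum_t (f_t - 1) (the number of *possible* repeats), ``lsmo``
  ("length minus one") divides by n - 1. lsmo is the default.

All logarithms are base 2. Values are never rounded internally.

Degenerate conventions (single-token sequences, zero denominators) return
0 so every feature is total and bounded; see the individual functions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .sequence import TokenSequence

RepetitionVariant = Literal["sproat", "lsmo"]


@dataclass(frozen=True)
class TypeDistribution:
    """Maximum-likelihood (plug-in) probabilities over a sequence's sign types."""

    probabilities: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.probabilities.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"probabilities sum to {total!r}, not 1")
        if any(p <= 0 for p in self.probabilities.values()):
            raise ValueError("probabilities must lie in (0, 1]")


@dataclass(frozen=True)
class FeatureVector:
    """The four per-sequence statistics, plus bookkeeping counts."""

    unigram_entropy: float
    entropy_rate: float
    ttr: float
    repetition_rate: float
    repetition_variant: RepetitionVariant
    n_tokens: int
    n_types: int

    def as_array(self) -> np.ndarray:
        """Feature order (H, h, TTR, r) used throughout classification."""
        return np.array(
            [self.unigram_entropy, self.entropy_rate, self.ttr, self.repetition_rate]
        )


FEATURE_COLUMNS = ("H", "h", "TTR", "r")


def type_probabilities(seq: TokenSequence) -> TypeDistribution:
    """Relative token frequencies p̂(t) = f_t / n for every sign type."""
    n = seq.n_tokens
    counts: dict[str, int] = {}
    for t in seq.tokens:
        counts[t] = counts.get(t, 0) + 1
    return TypeDistribution({t: f / n for t, f in counts.items()})


def ttr(seq: TokenSequence) -> float:
    """Type-token ratio m / n, in (0, 1]."""
    return seq.n_types / seq.n_tokens


def unigram_entropy(seq: TokenSequence) -> float:
    """Plug-in Shannon entropy of the sign-type distribution, bits/sign."""
    probs = type_probabilities(seq).probabilities
    return float(-sum(p * math.log2(p) for p in probs.values())) + 0.0


def lz78_match_lengths(seq: TokenSequence) -> np.ndarray:
    """L_i for positions i = 2..n of the increasing-window estimator.

    ``L_i`` is one plus the length of the longest contiguous run starting
    at position i that also occurs *entirely within* positions 1..i-1.
    Returns an array of length n-1 (element 0 corresponds to i=2).

    Implemented with an O(n^2) longest-common-prefix recurrence
    lcp[j, i] = lcp[j+1, i+1] + 1 if token_j == token_i else 0,
    so a match starting at prefix position j has usable length
    min(lcp[j, i], i - j).
    """
    toks = np.asarray(seq.tokens, dtype=object)
    n = len(toks)
    if n <= 1:
        return np.zeros(0, dtype=np.int64)
    codes = pd.factorize(toks)[0]
    lcp = np.zeros((n + 1, n + 1), dtype=np.int64)
    for j in range(n - 1, -1, -1):
        eq = codes[j] == codes[j + 1 :]
        lcp[j, j + 1 : n][eq] = lcp[j + 1, j + 2 : n + 1][eq] + 1
    out = np.empty(n - 1, dtype=np.int64)
    for i in range(1, n):
        j = np.arange(i)
        out[i - 1] = 1 + np.minimum(lcp[j, i], i - j).max()
    return out


def entropy_rate_terms(seq: TokenSequence) -> list[tuple[int, float]]:
    """Per-position contributions (i, log2(i)/L_i) for i = 2..n."""
    lengths = lz78_match_lengths(seq)
    return [(i, math.log2(i) / L) for i, L in zip(range(2, seq.n_tokens + 1), lengths)]


def entropy_rate_lz78(seq: TokenSequence) -> float:
    """Increasing-window LZ78 entropy-rate estimate, bits/sign.

    A single-token sequence returns 0 by convention. The estimator is
    known to overestimate for short repetitive sequences (match lengths
    shrink as i approaches n); no correction is applied.
    """
    n = seq.n_tokens
    if n <= 1:
        return 0.0
    lengths = lz78_match_lengths(seq)
    i = np.arange(2, n + 1)
    return float(np.sum(np.log2(i) / lengths) / n)


def repetition_rate(seq: TokenSequence, variant: RepetitionVariant = "lsmo") -> float:
    """Adjacent-repetition rate in [0, 1] under the chosen normalization.

    ``lsmo`` divides the number of positions j with t'_j = t'_{j+1} by
    n - 1; ``sproat`` divides by sum_t (f_t - 1) = n - m. A zero
    denominator (single token, or all-unique sequence under ``sproat``)
    returns 0.
    """
    n = seq.n_tokens
    if n <= 1:
        return 0.0
    r_adj = sum(a == b for a, b in zip(seq.tokens, seq.tokens[1:]))
    denom = n - 1 if variant == "lsmo" else n - seq.n_types
    if denom == 0:
        return 0.0
    return r_adj / denom


def compute_feature_vector(
    seq: TokenSequence, variant: RepetitionVariant = "lsmo"
) -> FeatureVector:
    """Assemble the four statistics into one vector (H, h, TTR, r)."""
    return FeatureVector(
        unigram_entropy=unigram_entropy(seq),
        entropy_rate=entropy_rate_lz78(seq),
        ttr=ttr(seq),
        repetition_rate=repetition_rate(seq, variant),
        repetition_variant=variant,
        n_tokens=seq.n_tokens,
        n_types=seq.n_types,
    )


def convergence_profile(seq: TokenSequence) -> list[tuple[int, float]]:
    """Entropy-rate estimates on every prefix, for stabilization diagnostics.

    Returns (w, h estimated on the first w tokens) for w = 2..n. The final
    entry equals :func:`entropy_rate_lz78` of the whole sequence. Within a
    window of length w the forward extent of a match is additionally
    capped at w - i + 1, so the profile is computed from one pass of the
    full-sequence match table rather than n quadratic recomputations.
    """
    n = seq.n_tokens
    if n <= 1:
        return []
    # uncapped containment-limited match length at each position (0-indexed i0):
    # A_i0 = max_{j0 < i0} min(lcp[j0, i0], i0 - j0); within a window of w
    # tokens L = 1 + min(A_i0, w - i0 - 1 + 1) ... forward room is w - i0 - 1
    # tokens beyond position i0 itself, i.e. match length <= w - i0.
    toks = np.asarray(seq.tokens, dtype=object)
    codes = pd.factorize(toks)[0]
    lcp = np.zeros((n + 1, n + 1), dtype=np.int64)
    for j in range(n - 1, -1, -1):
        eq = codes[j] == codes[j + 1 :]
        lcp[j, j + 1 : n][eq] = lcp[j + 1, j + 2 : n + 1][eq] + 1
    A = np.empty(n, dtype=np.int64)
    A[0] = 0
    for i in range(1, n):
        j = np.arange(i)
        A[i] = np.minimum(lcp[j, i], i - j).max()
    i0 = np.arange(1, n)  # 0-indexed positions 1..n-1, i.e. i = 2..n
    numer = np.log2(i0 + 1)
    profile = []
    for w in range(2, n + 1):
        L = 1 + np.minimum(A[i0[: w - 1]], w - i0[: w - 1])
        profile.append((w, float(np.sum(numer[: w - 1] / L) / w)))
    return profile


def feature_table(
    sequences: Iterable[TokenSequence], variant: RepetitionVariant = "lsmo"
) -> pd.DataFrame:
    """Per-sequence feature table: one row per sequence.

    Columns: source_id, corpus_label, n_tokens, n_types, H, h, TTR, r.
    """
    rows = []
    for s in sequences:
        fv = compute_feature_vector(s, variant)
        rows.append(
            {
                "source_id": s.source_id,
                "corpus_label": s.corpus_label,
                "n_tokens": fv.n_tokens,
                "n_types": fv.n_types,
                "H": fv.unigram_entropy,
                "h": fv.entropy_rate,
                "TTR": fv.ttr,
                "r": fv.repetition_rate,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "source_id",
            "corpus_label",
            "n_tokens",
            "n_types",
            "H",
            "h",
            "TTR",
            "r",
        ],
    )
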