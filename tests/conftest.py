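from __future__ import annotations

import math

import pytest

from signseq.sequence import TokenSequence

# The seven reference sequences with their published feature values
# (token count, type count, H, h, TTR, r at 2 d.p.). Raw forms are given
# in each dialect's uncleaned notation.
REFERENCE_ROWS = [
    # (label, dialect, raw, n_tokens, n_types, H, h, TTR, r)
    ("TeDDi (Basque)", "modern_text", "Mila esker maitea", 17, 11, 3.29, 2.19, 0.65, 0.0),
    (
        "TeDDi (Chinese strokes)",
        "modern_text",
        "etao etao aieeeaetn eaaieeeeto taieetso oodtshn etasee",
        54,
        10,
        2.89,
        1.99,
        0.19,
        0.17,
    ),
    ("Uruk III", "protocuneiform", "N01 _ NAGA~a _ DU _ PAP~a", 7, 5, 2.13, 1.43, 0.71, 0.0),
    ("Uruk IV", "protocuneiform", "N14 N14 _ N01 N01 N01 _ UDU~a", 8, 4, 1.91, 1.37, 0.5, 0.43),
    ("Uruk V", "protocuneiform", "N01 N01 N01", 3, 1, 0.0, 0.43, 0.33, 1.0),
    ("Aurignacian", "aurignacian", "XX_vvvvvvvv_vvvv", 16, 3, 1.06, 1.04, 0.19, 0.73),
]


def brute_force_match_lengths(tokens: tuple[str, ...]) -> list[int]:
    """Independent O(n^3) oracle for the increasing-window L_i values.

    For each position i (1-indexed, from 2), enumerate every candidate
    start j and length l and keep the longest contiguous match starting at
    i that lies entirely within positions 1..i-1.
    """
    n = len(tokens)
    out = []
    for i in range(1, n):  # 0-indexed start of the suffix
        best = 0
        for j in range(i):
            max_len = min(i - j, n - i)  # containment in prefix + available suffix
            length = 0
            while length < max_len and tokens[j + length] == tokens[i + length]:
                length += 1
            best = max(best, length)
        out.append(best + 1)
    return out


def brute_force_entropy_rate(tokens: tuple[str, ...]) -> float:
    n = len(tokens)
    if n <= 1:
        return 0.0
    lengths = brute_force_match_lengths(tokens)
    return sum(math.log2(i) / L for i, L in zip(range(2, n + 1), lengths)) / n


@pytest.fixture
def aurignacian_example() -> TokenSequence:
    return TokenSequence(tuple("XX_vvvvvvvv_vvvv"), "Aurignacian", "vhc0096")


@pytest.fixture
def uruk_v_example() -> TokenSequence:
    return TokenSequence(("N01", "N01", "N01"), "UrukV", "p-uruk5")
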