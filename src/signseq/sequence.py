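"""Core container for a tokenized symbol sequence.

A sequence is an ordered concatenation of sign *tokens*; its *vocabulary*
is the set of distinct sign *types*. The group-separator token ``"_"``,
where present, is an ordinary token and participates in every statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class TokenSequence:
    """An ordered sequence of sign tokens from one object or text line.

    Parameters
    ----------
    tokens
        The sign tokens, in reading order. Each token is an atomic string
        (a single character for character-tokenized dialects, a sign name
        such as ``"N01"`` for transliterated ones).
    corpus_label
        Subcorpus the sequence belongs to (e.g. ``"Aurignacian"``, ``"UrukV"``).
    source_id
        Identifier of the originating object or line.
    """

    tokens: tuple[str, ...]
    corpus_label: str = ""
    source_id: str = ""
    vocabulary: frozenset[str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.tokens) == 0:
            raise ValueError(f"empty token sequence (source_id={self.source_id!r})")
        if not all(isinstance(t, str) and t for t in self.tokens):
            raise ValueError(
                f"tokens must be non-empty strings (source_id={self.source_id!r})"
            )
        object.__setattr__(self, "tokens", tuple(self.tokens))
        object.__setattr__(self, "vocabulary", frozenset(self.tokens))

    @property
    def n_tokens(self) -> int:
        """Sequence length in tokens (n)."""
        return len(self.tokens)

    @property
    def n_types(self) -> int:
        """Number of distinct sign types (m = |V|)."""
        return len(self.vocabulary)

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self):
        return iter(self.tokens)
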