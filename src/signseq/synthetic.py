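"""Synthetic corpora and artifact metadata with known statistical structure.

The sequence generator is a first-order Markov source with a single
"stickiness" parameter rho: at every step the previous token is repeated
with probability rho, otherwise a token is drawn uniformly from the rest
of the vocabulary. The adjacent-repetition rate of such a source is rho in
expectation, so the generator directly spans the [0, 1] repetition-rate
range observed across corpora — from highly repetitive engraved-sign
regimes (high rho, small vocabulary, short sequences) to modern writing
(low rho, large vocabulary, longer lines).

Sequence lengths follow a shifted negative binomial (non-negative,
right-skewed, like empirical sequence-length distributions) whose
parameters are solved from a target *median* length, since corpora are
summarized by median lengths (7–28 tokens across the study's subcorpora).

The metadata generator emulates per-object predictors (object type,
material, site, preservation, volume, date) and builds a response as a
linear predictor from an effect map plus Gaussian noise — the structure a
linear regression of information density on artifact metadata assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .features import RepetitionVariant, feature_table
from .sequence import TokenSequence

#: Factor levels mirroring the artifact metadata: first level is the
#: regression reference level.
DEFAULT_OBJECT_TYPES = (
    "tool",
    "anthropomorph_figurine",
    "zoomorph_figurine",
    "tube_flute",
    "personal_ornament",
    "undetermined",
)
DEFAULT_MATERIALS = ("antler", "ivory", "bone")
DEFAULT_SITES = ("Geissenkloesterle", "Hohle_Fels", "Vogelherd", "Hohlenstein_Stadel")
DEFAULT_PRESERVATIONS = ("almost_complete", "complete", "fragmented")


@dataclass(frozen=True)
class CorpusSpec:
    """Parameters of one synthetic subcorpus."""

    n_sequences: int
    vocabulary_size: int
    self_repeat_prob: float
    length_median: int = 10
    length_dispersion: float = 3.0
    group_separator_rate: float = 0.0
    label: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vocabulary_size < 1:
            raise ValueError("vocabulary_size must be >= 1")
        for name in ("self_repeat_prob", "group_separator_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be >= 1")
        if self.length_median < 1:
            raise ValueError("length_median must be >= 1")


@dataclass(frozen=True)
class MetadataSpec:
    """Parameters of a synthetic artifact-metadata table.

    ``effect_map`` holds additive shifts on the response: keys are either
    ``(factor_name, level)`` for factor levels or a continuous predictor
    name (``"volume"``, ``"max_date"``) mapped to a per-unit slope.
    Reference levels carry no shift by construction.
    """

    n_objects: int
    object_type_probs: Mapping[str, float] = field(
        default_factory=lambda: {t: 1 / 6 for t in DEFAULT_OBJECT_TYPES}
    )
    material_probs: Mapping[str, float] = field(
        default_factory=lambda: {"antler": 0.1, "ivory": 0.7, "bone": 0.2}
    )
    site_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "Geissenkloesterle": 0.25,
            "Hohle_Fels": 0.3,
            "Vogelherd": 0.35,
            "Hohlenstein_Stadel": 0.1,
        }
    )
    preservation_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "almost_complete": 0.4,
            "complete": 0.2,
            "fragmented": 0.4,
        }
    )
    volume_log_mean: float = 3.0  # cm^3, lognormal
    volume_log_sd: float = 1.0
    date_range: tuple[float, float] = (30_000.0, 40_000.0)  # years BP
    intercept: float = 1.0  # bits/sign at reference levels
    effect_map: Mapping = field(default_factory=dict)
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        for name in ("object_type_probs", "material_probs", "site_probs", "preservation_probs"):
            probs = getattr(self, name)
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} sums to {total}, not 1")


def _nbinom_params_for_median(median: int, dispersion: float) -> tuple[float, float]:
    """Solve the (r, p) of a 1-shifted negative binomial with the given median."""
    target = median - 1  # median of the unshifted NB
    lo, hi = 1e-3, 1e4
    for _ in range(80):
        mu = (lo + hi) / 2
        p = dispersion / (dispersion + mu)
        if stats.nbinom.median(dispersion, p) < target:
            lo = mu
        else:
            hi = mu
    mu = (lo + hi) / 2
    return dispersion, dispersion / (dispersion + mu)


def _draw_lengths(spec: CorpusSpec, rng: np.random.Generator) -> np.ndarray:
    r, p = _nbinom_params_for_median(spec.length_median, spec.length_dispersion)
    return 1 + rng.negative_binomial(r, p, size=spec.n_sequences)


def generate_sign_corpus(spec: CorpusSpec) -> list[TokenSequence]:
    """Draw a corpus of sticky-Markov token sequences.

    With probability ``group_separator_rate`` a position emits the group
    separator ``"_"``; otherwise with probability ``self_repeat_prob`` the
    previous token is repeated, else a uniform draw from the vocabulary
    excluding the previous token. Byte-identical for identical spec+seed.
    """
    rng = np.random.default_rng(spec.seed)
    vocab = [f"s{i:02d}" for i in range(spec.vocabulary_size)]
    lengths = _draw_lengths(spec, rng)
    out: list[TokenSequence] = []
    for k, length in enumerate(lengths):
        toks: list[str] = []
        prev: str | None = None
        for _ in range(int(length)):
            if spec.group_separator_rate > 0 and rng.random() < spec.group_separator_rate:
                tok = "_"
            elif prev is not None and rng.random() < spec.self_repeat_prob:
                tok = prev
            else:
                choices = [v for v in vocab if v != prev] or vocab
                tok = choices[rng.integers(len(choices))]
            toks.append(tok)
            prev = tok
        out.append(
            TokenSequence(tuple(toks), corpus_label=spec.label, source_id=f"{spec.label}-{k:05d}")
        )
    return out


def generate_artifact_metadata(spec: MetadataSpec) -> pd.DataFrame:
    """Draw an artifact-metadata table with a linear-model response.

    Returns one row per object with columns ``object_type``, ``material``,
    ``site``, ``preservation``, ``volume`` (cm^3), ``max_date`` (years BP)
    and the response ``entropy_rate`` = intercept + effects + N(0, noise_sd^2).
    """
    rng = np.random.default_rng(spec.seed)

    def draw_factor(probs: Mapping[str, float]) -> np.ndarray:
        levels = list(probs)
        p = np.array([probs[level] for level in levels])
        return rng.choice(levels, size=spec.n_objects, p=p / p.sum())

    df = pd.DataFrame(
        {
            "source_id": [f"obj{i:04d}" for i in range(spec.n_objects)],
            "object_type": draw_factor(spec.object_type_probs),
            "material": draw_factor(spec.material_probs),
            "site": draw_factor(spec.site_probs),
            "preservation": draw_factor(spec.preservation_probs),
            "volume": rng.lognormal(spec.volume_log_mean, spec.volume_log_sd, spec.n_objects),
            "max_date": rng.uniform(*spec.date_range, spec.n_objects),
        }
    )
    linpred = np.full(spec.n_objects, spec.intercept, dtype=float)
    for key, effect in spec.effect_map.items():
        if isinstance(key, tuple):
            factor, level = key
            linpred += np.where(df[factor] == level, effect, 0.0)
        else:
            linpred += effect * df[key].to_numpy()
    df["entropy_rate"] = linpred + rng.normal(0.0, spec.noise_sd, spec.n_objects)
    return df


def generate_labeled_dataset(
    spec_a: CorpusSpec,
    spec_b: CorpusSpec,
    variant: RepetitionVariant = "lsmo",
) -> pd.DataFrame:
    """Two synthetic corpora, featurized and concatenated with labels.

    The result feeds the pairwise classification protocol directly.
    """
    if spec_a.label == spec_b.label:
        raise ValueError("corpus specs must carry distinct labels")
    seqs = generate_sign_corpus(spec_a) + generate_sign_corpus(spec_b)
    return feature_table(seqs, variant)
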