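# Methods

## Sequences and preprocessing

A sequence is an ordered tuple of sign tokens `s = (t'_1, …, t'_n)` over
a vocabulary of `m` distinct sign types. Three input dialects are
supported, each with its own cleaning grammar:

- **Engraved-artifact codings** (`aurignacian`): every UTF-8 character is
  a token. Cleaning removes `!` annotation marks, round-bracketed spans
  (signs not visually discrete) and square-bracketed spans (signs not in
  linear order). Nested, overlapping, or unbalanced brackets are rejected
  as malformed rather than guessed at — the markup grammar does not
  define a meaning for them. Underscores separate parts of an object and
  are ordinary tokens.
- **Protocuneiform transliterations** (`protocuneiform`): whitespace
  splits sign names; `k(SIGN)` expands to `k` adjacent tokens; standalone
  `_` group separators are tokens. Annotation markup is stripped by a
  configurable regex list (default: `#?!` markers and square brackets),
  since transliteration conventions vary between corpus exports.
- **Modern text lines** (`modern_text`): every UTF-8 character including
  whitespace is a token; Unicode punctuation categories are removed, and
  characters outside an optional per-script character set are dropped.
  Case is preserved — upper- and lowercase letters are distinct types.

Sequences that are empty after cleaning are excluded from all statistics
but counted in a preprocessing report, so corpus attrition is always
visible. Subsampling to a common corpus size (the study design uses
1,000) is uniform without replacement and seeded; the pipeline config
chooses whether subsampling runs before or after empty-sequence
filtering, since either order is defensible and the reference counts do
not pin one down.

## The four statistics

All logarithms are base 2; nothing is rounded internally.

- `TTR = m / n`, in (0, 1].
- `H = −Σ_t p̂(t) log₂ p̂(t)` with plug-in probabilities `p̂(t) = f_t/n`.
  Only the maximum-likelihood estimator is provided: smoothing
  estimators are strongly correlated with it on language-like data, and
  the plug-in form is the one the reference values use. `H ≤ log₂ m`
  holds by construction and is property-tested.
- The **entropy rate** uses the increasing-window LZ78 estimator
  `ĥ = (1/n) Σ_{i=2}^{n} log₂(i)/L_i`, where `L_i` is one plus the
  length of the longest contiguous subsequence starting at `i` that also
  occurs *entirely within* positions `1..i−1`. The containment rule
  matters: for `(a, a, a)` the match at position 2 is capped at length 1
  by the prefix boundary, giving `ĥ ≈ 0.43` rather than a smaller value —
  this convention is what reproduces the reference values. The estimator
  overestimates for short repetitive sequences (late positions cannot
  have long forward runs); no correction is applied, matching the
  reference treatment. `convergence_profile` exposes the estimate on
  every prefix for stabilization diagnostics.

  Implementation: a longest-common-prefix table
  `lcp[j,i] = lcp[j+1,i+1]+1` if the tokens match, computed in O(n²),
  with the usable match length `min(lcp[j,i], i−j)`. Tests verify exact
  agreement with an exhaustive O(n³) scan on random sequences. Prefix
  profiles reuse the same table with a per-window forward cap instead of
  recomputing per prefix.
- The **repetition rate** counts positions with `t'_j = t'_{j+1}`. The
  default normalization is `n − 1` ("lsmo"); the alternative divides by
  `Σ_t (f_t − 1) = n − m` ("sproat") and is kept behind a flag. Both lie
  in [0, 1].

Degenerate conventions: a single-token sequence has entropy rate 0 and
repetition rate 0; a vanishing sproat denominator (all-unique sequence)
returns 0. These keep every feature total and bounded; no reference
value exercises them, so the choice is free and is documented here.

## Synthetic data

The sequence generator is the simplest source whose adjacent-repetition
rate is directly controlled: a first-order Markov chain that repeats the
previous token with probability ρ and otherwise draws uniformly from the
rest of the vocabulary. Its stationary adjacent-repeat frequency is ρ,
so mean lsmo repetition rates track ρ (verified to ±0.02 at length 200),
and entropy rates fall monotonically as ρ rises. An optional
group-separator rate interleaves `_` tokens. Lengths follow a 1-shifted
negative binomial solved numerically from a target median (defaults in
the 7–28 token range the study corpora span), because empirical
sequence-length distributions are non-negative and right-skewed and the
corpora are summarized by medians. Sequences are byte-identical under a
fixed spec and seed.

The metadata generator mirrors the artifact predictors: object type
(six levels, reference "tool"), material (reference "antler"), site
(reference "Geissenkloesterle"), preservation (three levels, reference
"almost_complete"), lognormal volume in cm³, and uniform dates in
30,000–40,000 BP. The response is a linear predictor from an effect map
plus Gaussian noise (default intercept 1.0 bits/sign, noise SD 0.2 —
entropy rates for short engraved sequences live roughly in [0, 2]).

What the generator does *not* emulate: realistic sign-type frequency
profiles, within-object correlation between sequence statistics and
metadata (features and metadata are drawn independently unless an
effect is injected), or cross-corpus length/vocabulary interactions.
Passing calibration tests therefore demonstrates that the inference
machinery is correct under its stated model, not that the archaeological
conclusions themselves reproduce — those require the deposited corpora.

## Classification

Pairwise only. Features are z-scored with parameters fitted on the
training partition; the split is stratified at exactly 2/3 : 1/3 (the
published example split 324 → 216/108 is exact thirds, which a literal
0.67 cannot produce). KNN uses Euclidean distance with a default K grid
of 1, 3, …, 25 (odd to avoid vote ties). MLP architectures are sampled
uniformly with depth ≤ 4 and width ≤ 5 per layer; the training recipe is
fixed (relu, adam, tol 1e-4 over 50 epochs, 2000-epoch cap) and a run
that hits the epoch cap is flagged non-converged and excluded from
summaries rather than erroring.

The accuracy baseline is the no-information rate: the majority-class
fraction of the *training* labels. Significance uses the exact one-sided
binomial tail `P(X ≥ successes | X ~ Bin(n_test, NIR))` — exact rather
than a normal approximation because test sets run as small as ~100.
P-values are Bonferroni-multiplied by the number of runs and capped at
1; summaries report the percentage significant at α = 0.05. Type-I
control of this procedure is verified by simulation on identically
distributed pairs.

PCA uses the correlation-matrix convention (z-scored features) so
loadings are comparable across the mixed-unit features, with the sign of
each component fixed by forcing the unigram-entropy loading
non-negative.

## Regression

OLS with treatment (dummy) coding; the intercept is the response mean at
the reference factor levels. The model ladder starts at the intercept
model, adds volume, date, and object type cumulatively (the
theoretically motivated order), then tries site, preservation, material,
and three interactions on top of the base; the minimum-AIC rung is
selected, and the whole ladder is reported so the comparison is
inspectable. AIC uses the Gaussian log-likelihood including constants —
only differences matter and the ladder ordering is the claim, not
absolute values. Rank-deficient designs are rejected with the collinear
columns named. The response defaults to entropy rate but is a parameter.

Semipartial R² of a term is `R²(full) − R²(full − term)`, with a
one-sided 95% interval `[lower, 1]`: the lower bound is the 5th
percentile of the statistic over 1,000 nonparametric bootstrap
resamples of the rows (resamples that lose a factor level entirely are
skipped). The one-sided form matches how the effect size is reported in
the reference analysis; the exact interval construction there is
unstated, so the bootstrap is a documented choice, not an asserted
equivalence.

Diagnostics are flags, never failures: Shapiro–Wilk for residual
normality, Breusch–Pagan for homoscedasticity (undefined and skipped for
intercept-only models), a degenerate-residual flag when residual
variance is numerically zero.

## Problem sizes

Unit and property tests run at desk scale (sequences ≤ 64 tokens,
corpora of 60–300 sequences). Calibration studies use 40–50 seeded
replicates with corpora of ~120 sequences or metadata tables of 300–400
rows — sizes at which the binomial test, CI coverage, and AIC selection
claims are already stable, chosen as the package's own test design. The
i.i.d. convergence check for the entropy-rate estimator uses 20
replicates at n = 2000 over a 4-type alphabet.

## Known limitations

- The LZ78 estimator's short-sequence overestimation bias is inherited
  by design; comparisons across corpora with very different length
  distributions should keep this in mind.
- The classifier sweep is not hyperparameter optimization; it reproduces
  a fixed protocol (K grid, random small architectures).
- No mixed-effects or spatial structure in the regression; sites enter
  as a plain factor.
- Parsers accept local tables only; no corpus downloading.
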