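# Methods

This note documents the models, parameter choices, and numerical
conventions behind `qcla`, and what the synthetic experiments do and do not
establish.

## The measurement problem

Four emotional states — harmony, satisfaction, depression, anxiety — form
two *confusable pairs*: constructs that are theoretically distinct but
highly correlated when measured with rating scales (PHQ-9 vs GAD-7; SWLS
vs HILS). The pipeline tests whether five free-listed descriptive words,
embedded in a semantic vector space, separate the members of each pair
better than the scales do. The unit of analysis is one rater's evaluation
of one narrative; all evaluations of the same narrative are statistically
dependent, which drives the grouped cross-validation below.

## Synthetic study generator

The generator emulates only the statistical structure the analysis is
sensitive to; its defaults are the study conditions used throughout the
tests.

- **Design:** 297 Phase-1 authors with balanced emotions; 434 Phase-2
  readers, each narrative read once or twice (a uniformly chosen subset of
  narratives is read twice); 34/434 readers flagged professional (the
  share of professionals in the design this emulates; no mechanism beyond
  a random flag is modeled).
- **Lexicons:** 40 words per emotion, seeded with high-association
  vocabulary (sad, anxious, happy, calm, …) and padded with synthetic
  tokens. Confusable pairs share `round(overlap × size)` words
  (default overlap 0.2); cross-valence overlap is structurally zero.
- **Word responses:** five distinct words per response; each slot comes
  from the true emotion's lexicon with probability `1 − word_noise`
  (default noise 0.2) and otherwise from another emotion's.
- **Rating scales:** a 4-dimensional latent Gaussian with per-emotion mean
  profiles and correlation 0.85 within valence / −0.6 across valence
  (positive definite). Totals are obtained by the probability integral
  transform onto each scale's legal total range, then split at random into
  range-respecting items. The Gaussian-copula grade correlation
  `(6/π)·asin(ρ/2) ≈ 0.84` for ρ = 0.85 keeps empirical total correlations
  within ±0.05 of the target. The mean profiles give depression/anxiety a
  smaller within-pair separation (0.3 latent SD) than satisfaction/harmony
  (0.4), so the scales' dominant confusion is the depression–anxiety
  block. The published study does not report its empirical inter-scale
  correlations, so these latent parameters are plausible rather than
  calibrated.
- **Randomness:** one master seed; each stage (phase-1 words, phase-2
  words, scales, pairing, roles) draws from its own stream at a fixed
  offset, so stages are individually reproducible and the dataset is
  byte-identical under a repeated seed.

What the generator deliberately does **not** model: narrative text bodies,
demographics, item-level factor structure beyond a common per-scale latent,
response styles (acquiescence, central tendency), or any non-random
reader–narrative assignment. Passing recovery tests therefore show the
pipeline recovers planted structure under the stated noise; they say
nothing about real-language effect sizes.

## Encoders

The mock encoder maps a token to a unit pseudo-random vector seeded by a
SHA-256 hash of the token (stable across processes), plus, for lexicon
words, `signal` (default 1.0) times the mean of the class directions of
the lexicons containing it. Shared confusable-pair words thus sit midway
between two class directions, and out-of-lexicon tokens are pure noise.
With `word_noise = 0` and disjoint lexicons the four classes are linearly
separable by construction — the basis of the 100%-accuracy control. In
768 dimensions random unit noise projects onto any fixed class-difference
direction with SD ≈ 1/√768, which is why a signal of 1.0 dominates.

A response embedding is the unweighted mean of its word embeddings.
Whether the original analysis encoded the five words jointly or averaged
per-word vectors is not documented; mean pooling is the convention of
prior question-based assessment work, keeps the mock geometry analyzable,
and is the documented default rather than a claim. No vector normalization
is applied before classification; unit normalization appears only inside
the semantic t-test, where the procedure specifies it.

## Cleaning

Lowercase and trim; drop raters who failed a control question; remove
"n/a"/"na" placeholders and multi-token entries; collapse *successively*
repeated words (adjacent duplicates only — non-adjacent repeats are kept,
the literal reading of "successive"); drop a record only when no word
survives. Spell correction is off by default because the original pass was
human-in-the-loop; when enabled it replaces a word only on a unique
Damerau–Levenshtein distance-1 dictionary match (covering the classic
transposition typo) and otherwise retains the original. Cleaning is
idempotent and always precedes embedding, for both phases.

## Classification protocol

- **Folds:** narratives (not records) are shuffled and greedily assigned,
  most-read first, to the smallest fold — sizes stay as even as the
  multiplicities allow, and no narrative spans folds. The leakage
  invariant is asserted at run time, not assumed.
- **Compression:** per-fold SVD of the raw (uncentered) training matrix;
  centering is a config switch. The dimension ladder 1, 2, 3, 5, …, 517,
  768 is truncated at the feature dimensionality, which is itself always a
  candidate (so the 4-dim scales ladder is 1, 2, 3, 4).
- **Inner selection:** 5-fold grouped cross-validation *within* the
  training partition, choosing the ladder entry with the fewest
  miscategorizations (classification) or smallest squared error
  (regression), ties to the smallest m. Training error would be
  non-increasing in m and always saturate the ladder; an inner
  cross-validation is the reading consistent with intermediate selected
  dimensionalities (the default words run here averages ≈ 64 of 768).
- **Model:** multinomial logistic regression by maximum likelihood with a
  ridge term of 10⁻⁶ for numerical stability on separable data (scikit-learn
  lbfgs, C = 10⁶, tol 10⁻⁴; an independent scipy optimization of the same
  penalized likelihood reproduces its predictions in the test suite).
  Argmax ties break by the fixed class order harmony, satisfaction,
  depression, anxiety. For the continuous scale scores, ordinary least
  squares replaces the multinomial model under the identical protocol.

## Comparison statistics

The two-proportion chi-square is the closed form
`χ² = N(p₁−p₂)²/(4·p̄(1−p̄))` with `p̄ = (p₁+p₂)/2` — the Pearson
chi-square of a 2×2 table with two groups of N/2, which it equals exactly
whenever the implied counts are integers. Reported p-values are the
χ²₁ survival function without continuity correction; `φ = √(χ²/N)`. From
published percentages this form reproduces the printed statistics 16.10,
8.41, 5.88, 3.50, 0.12, and 0.04 to two decimals. One published anxiety
contrast (45.63, involving a 0% cell) is *not* reproduced by this form
(it gives ≈ 49.25, ≈ 46.31 with Yates correction); its original
computation is unknown and the value is used here only through the
φ-relation. Since no CI method for φ is documented, the interval is a
seeded 2,000-resample bootstrap over the implied 2×2 table.

Fisher r-to-z machinery: CI `tanh(atanh r ± z₀.₉₇₅/√(n−3))`; two
correlations sharing n are compared with
`z = (atanh r₂ − atanh r₁)/√(2/(n−3))`, two-sided. Per-class precision
with zero positive predictions is reported as missing, never zero.

## Semantic t-test

The t-test's sampling unit is the per-occurrence similarity of a word
(occurrence-level, the default; the alternative — one similarity per
unique word — would leave no within-word variance to test). A word's
occurrences are split into at most 10 folds; for each fold the difference
vector is rebuilt with that fold's occurrences removed from their
aggregate, so the measured word never contributes to its own contrast.
One-sided test (association *greater* than zero); Bonferroni divisor =
number of unique words with ≥ 2 occurrences in that emotion's family;
zero-variance similarity sets take the t = ±∞ convention with p ∈ {0, 1};
singletons are reported with undefined t and excluded from clouds. Word
clouds pool Phase-1 and Phase-2 occurrences by default (a switch restricts
the pool).

## Problem sizes and determinism

The shipped experiments use the full default design (297 + 434 records;
400 lay-reader analysis subset) for the recovery, chance, and separability
runs, and scaled-down configurations (40 authors / 60 readers, 12-word
lexicons) for unit tests. All fold assignments, bootstrap draws, and mock
embeddings flow from explicit seeds; reports embed the seed and a
configuration hash, and repeated runs are byte-identical.

## Known limitations

- The mock encoder's geometry is far cleaner than a trained language
  model's; synthetic accuracies (≈ 94% words vs ≈ 61% scales at the
  default noise) are upper-range illustrations of the words-over-scales
  gap, not predictions of real-data effect sizes.
- The latent scale correlations and mean profiles are design choices, not
  estimates from the deposited data.
- Inter-rater agreement on synthetic data can favor words (readers of the
  same narrative share its lexicon signature); with human raters the
  scales' coarser categories may agree more often, so this statistic is
  structural, not comparable across data sources.
- The chi-square closed form assumes two equal groups; contrasts of
  dependent proportions (same raters under two measures) inherit whatever
  approximation that entails in the original reporting.
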