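# qcla — question-based computational language assessment

`qcla` is an evaluation pipeline for a question in computational
psychometrics: do open-ended **descriptive-word responses**, quantified as
semantic embeddings, categorize emotional states more accurately than
standardized **rating scales**?

The setting is a two-phase design. Phase-1 participants each write a
narrative about a period of *harmony*, *satisfaction*, *depression*, or
*anxiety*, summarize it in five single words, and complete four rating
scales — PHQ-9 (depression, 9 items, total 0–27), GAD-7 (anxiety, 7 items,
total 0–21), SWLS (life satisfaction) and HILS (harmony in life; 5 items
each, totals 5–35). Phase-2 readers evaluate those narratives the same way
without knowing the condition. The pipeline asks which measure — the five
words or the four scales — better recovers the narrative's true emotional
state.

## The method

- **Features.** Each word is mapped to a 768-dimensional embedding; a
  response is the unweighted mean of its word vectors. Competing feature
  sets: embeddings only (768), scale totals only (4), both (772), or the
  26 item-level scale answers.
- **Categorization.** 10-fold cross-validated multinomial logistic
  regression, with folds grouped by narrative so no narrative ever spans a
  train/test split. Within each fold the training features are compressed
  by SVD and the number of leading dimensions m is selected by an inner
  5-fold search over the ladder 1, 2, 3, 5, 7, …, 517, 768 (fewest
  miscategorizations, ties to the smallest m). Every record receives
  exactly one out-of-fold prediction.
- **Comparison statistics.** Percent correct per feature set; a
  two-proportion chi-square `χ² = N(p₁−p₂)²/(4·p̄(1−p̄))` with effect size
  `φ = √(χ²/N)` and a bootstrap CI; per-class accuracy and precision from
  the confusion matrix; pairwise inter-rater agreement on multiply-read
  narratives; and, for continuous scores, matched-narrative Pearson
  correlations compared through Fisher's r-to-z transform.
- **Word clouds.** A semantic t-test: each unique word's cosine against the
  unit-normalized difference between one emotion's aggregate semantic
  representation and the other three's (leave-out folds keep the measured
  word out of its own contrast), one-sided t-tests with Bonferroni
  correction, top-25 words per emotion.

Because the original participant data and a pretrained transformer are not
bundled, the package ships a first-class **synthetic study generator**:
emotion lexicons with controllable overlap between the confusable pairs
(depression↔anxiety, satisfaction↔harmony), word sampling with an
off-lexicon noise rate, rating-scale items from a latent-Gaussian copula
correlated 0.85 within valence, and Phase-2 pairing where every narrative
is read once or twice. A deterministic mock encoder gives lexicon words a
class direction, so the recovery experiments have known ground truth. A
real encoder can be plugged in through the same one-token → one-vector
contract.

## Worked example

```bash
python analysis/01_simulate.py     # generate the default two-phase study
python analysis/02_categorize.py   # words vs scales categorization
```

The default study (297 authors, 434 readers, word noise 0.2, seed 42)
prints:

```
analysis subset: 400 Phase-2 lay readers

    words:  93.5% correct (mean dims 63.7)
   scales:  61.3% correct (mean dims 4.0)
 combined:  92.8% correct (mean dims 68.2)
    items:  53.5% correct (mean dims 18.3)

words vs scales: chi2(1, 400) = 59.41, p = 1.3e-14, phi = 0.39 [0.30, 0.46]

scales confusion matrix (rows=true, cols=predicted; order harmony, satisfaction, depression, anxiety):
[[65 20  7 11]
 [17 61  8 11]
 [11  4 55 25]
 [ 9  9 23 64]]
```

Reading this: word embeddings categorize 93.5% of the 400 lay-reader
responses correctly versus 61.3% for the scale totals — a significant gap
(χ², φ) — and the scales' largest error block confuses depression with
anxiety (25 + 23 off-diagonal records), exactly the within-valence
confusion their correlated generating distributions predict. Adding scales
to words (`combined`) does not improve on words alone.
`analysis/03_compare_measures.py` (continuous scores, rater agreement) and
`analysis/04_word_clouds.py` (semantic t-test clouds) continue the
analysis; a thin CLI (`qcla simulate|run|contrast|report`) wraps the same
library calls.

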