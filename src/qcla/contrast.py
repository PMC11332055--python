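"""Semantic t-test contrasts and word-cloud tables.

For one target emotion, all word occurrences from that emotion are summed
into one semantic representation and normalized to unit length; the
occurrences from the other three emotions are aggregated the same way.  The
unit-normalized difference of the two aggregates is the contrast direction.
Each unique word's association with the target emotion is the dot product
of its unit-normalized embedding with that direction (the cosine of the
angle between them).

A 10-fold leave-out scheme keeps the measured word out of its own contrast:
a word's occurrences are split into folds, and for each fold the difference
vector is rebuilt with that fold's occurrences removed from whichever
aggregate they belong to.  A one-sample, one-sided t-test asks whether the
word's per-occurrence similarities exceed zero, Bonferroni-corrected over
the unique words tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .records import EMOTIONS, ValidationError


@dataclass
class ContrastResult:
    """One word's association with one emotion's contrast."""

    word: str
    emotion: str
    similarity: float  # mean per-occurrence cosine against the contrast
    t_value: float
    p_value: float
    p_bonferroni: float
    frequency: int


def aggregate_unit_vector(embeddings: Sequence[np.ndarray]) -> np.ndarray:
    """Sum a set of embeddings and normalize to unit length."""
    if len(embeddings) == 0:
        raise ValidationError("cannot aggregate zero embeddings")
    total = np.sum(np.asarray(embeddings, dtype=float), axis=0)
    norm = np.linalg.norm(total)
    if norm == 0:
        raise ValidationError("aggregate is the zero vector")
    return total / norm


def difference_vector(target_agg: np.ndarray, other_agg: np.ndarray) -> np.ndarray:
    """Unit-normalized difference of two aggregate representations."""
    diff = np.asarray(target_agg, dtype=float) - np.asarray(other_agg, dtype=float)
    norm = np.linalg.norm(diff)
    if norm == 0:
        raise ValidationError("aggregates are identical; difference undefined")
    return diff / norm


def word_similarity(word_vec: np.ndarray, diff_vec: np.ndarray) -> float:
    """Cosine of the word against the contrast direction (word vector is
    unit-normalized first; the contrast direction must already be unit)."""
    w = np.asarray(word_vec, dtype=float)
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValidationError("zero word vector")
    return float((w / norm) @ np.asarray(diff_vec, dtype=float))


def _one_sided_t(similarities: np.ndarray) -> tuple[float, float]:
    """One-sample t against 0, H1: mean > 0; zero-variance convention
    t = ±inf with p in {0, 1}, and t = 0 / p = 0.5 for an all-zero sample."""
    n = len(similarities)
    mean = float(np.mean(similarities))
    sd = float(np.std(similarities, ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, 0.5
        return (math.inf, 0.0) if mean > 0 else (-math.inf, 1.0)
    t = mean / (sd / math.sqrt(n))
    return t, float(sps.t.sf(t, df=n - 1))


def semantic_t_test(
    words: Sequence[str],
    emotions: Sequence[str],
    vectors: Mapping[str, np.ndarray],
    target_emotion: str,
    k: int = 10,
    rng=None,
) -> list[ContrastResult]:
    """Score every unique word against one emotion's contrast.

    Parameters
    ----------
    words, emotions:
        Aligned per-occurrence token and emotion-label sequences (one entry
        per occurrence of a word in a response).
    vectors:
        Token → embedding map.
    target_emotion:
        The emotion contrasted against the other three.
    k:
        Number of leave-out folds for the difference vector (capped at the
        word's occurrence count).

    Words with a single occurrence yield ``t = nan`` and are excluded from
    the Bonferroni family and from the word clouds.
    """
    if target_emotion not in EMOTIONS:
        raise ValidationError(f"unknown emotion {target_emotion!r}")
    if len(words) != len(emotions):
        raise ValidationError("words and emotions must align")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    words = np.asarray(words, dtype=object)
    is_target = np.asarray([e == target_emotion for e in emotions])
    vecs = np.vstack([vectors[w] for w in words]).astype(float)
    sum_target = vecs[is_target].sum(axis=0)
    sum_other = vecs[~is_target].sum(axis=0)
    if not is_target.any() or is_target.all():
        raise ValidationError("need occurrences on both sides of the contrast")

    unique_words, frequencies = np.unique(words, return_counts=True)
    n_tested = int(np.sum(frequencies >= 2))

    results: list[ContrastResult] = []
    for word, freq in zip(unique_words, frequencies):
        occ = np.flatnonzero(words == word)
        v_word = vectors[word]
        sims: list[float] = []
        folds = np.array_split(rng.permutation(occ), min(k, len(occ)))
        for fold in folds:
            if len(fold) == 0:
                continue
            in_t = is_target[fold]
            s_t = sum_target - vecs[fold[in_t]].sum(axis=0)
            s_o = sum_other - vecs[fold[~in_t]].sum(axis=0)
            nt, no = np.linalg.norm(s_t), np.linalg.norm(s_o)
            if nt == 0 or no == 0:
                raise ValidationError(
                    f"aggregate degenerates to zero when leaving out {word!r}"
                )
            diff = difference_vector(s_t / nt, s_o / no)
            sims.extend(word_similarity(v_word, diff) for _ in fold)
        if freq < 2:
            results.append(
                ContrastResult(
                    word=str(word), emotion=target_emotion,
                    similarity=float(np.mean(sims)), t_value=math.nan,
                    p_value=math.nan, p_bonferroni=math.nan, frequency=int(freq),
                )
            )
            continue
        t, p = _one_sided_t(np.asarray(sims))
        results.append(
            ContrastResult(
                word=str(word), emotion=target_emotion,
                similarity=float(np.mean(sims)), t_value=t, p_value=p,
                p_bonferroni=min(1.0, p * n_tested), frequency=int(freq),
            )
        )
    return results


def contrast_all_emotions(
    words: Sequence[str],
    emotions: Sequence[str],
    vectors: Mapping[str, np.ndarray],
    k: int = 10,
    seed: int = 0,
) -> dict[str, list[ContrastResult]]:
    """Run the contrast for each of the four emotions (one RNG stream each,
    derived from the seed)."""
    return {
        emotion: semantic_t_test(
            words, emotions, vectors, emotion, k=k,
            rng=np.random.default_rng(seed + i),
        )
        for i, emotion in enumerate(EMOTIONS)
    }


def top_words(
    results: Sequence[ContrastResult] | Mapping[str, Sequence[ContrastResult]],
    k: int = 25,
    alpha: float = 0.05,
) -> "object":
    """Word-cloud table: up to ``k`` Bonferroni-significant words with the
    highest t-values, weighted by occurrence frequency.

    Accepts one emotion's results or the per-emotion mapping; returns a
    pandas DataFrame with columns (emotion, word, t, p_bonferroni,
    frequency, similarity).
    """
    import pandas as pd

    if isinstance(results, Mapping):
        frames = [top_words(r, k=k, alpha=alpha) for r in results.values()]
        return pd.concat(frames, ignore_index=True)
    rows = [
        r for r in results
        if math.isfinite(r.t_value) and r.p_bonferroni < alpha
    ]
    rows.sort(key=lambda r: -r.t_value)
    return pd.DataFrame(
        [
            {
                "emotion": r.emotion, "word": r.word, "t": r.t_value,
                "p_bonferroni": r.p_bonferroni, "frequency": r.frequency,
                "similarity": r.similarity,
            }
            for r in rows[:k]
        ],
        columns=["emotion", "word", "t", "p_bonferroni", "frequency", "similarity"],
    )
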