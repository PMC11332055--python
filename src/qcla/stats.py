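"""Comparative statistics for the words-versus-scales evaluation.

Covers the confusion matrix with per-class accuracy and precision, the
two-proportion chi-square contrast with the phi effect size and a bootstrap
confidence interval, pairwise Pearson correlations of multinomial
coefficients, pairwise inter-rater agreement on multiply-read narratives,
and matched-narrative correlations compared through Fisher's r-to-z
transformation.

The two-proportion test uses the closed form

    chi2 = N * (p1 - p2)^2 / (4 * pbar * (1 - pbar)),   pbar = (p1 + p2) / 2

i.e. a 2x2 Pearson chi-square for two groups of N/2 observations each,
which it equals exactly whenever the implied cell counts are integral.
phi = sqrt(chi2 / N).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .records import EMOTIONS, ValidationError


# ---------------------------------------------------------------------------
# confusion matrix, accuracy, precision


@dataclass
class ConfusionMatrix:
    """4x4 count matrix: rows = empirical emotion, columns = predicted."""

    counts: np.ndarray
    labels: tuple[str, ...] = EMOTIONS

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def percent_correct(self) -> float:
        return float(np.trace(self.counts) / self.total * 100.0)


def confusion(true_labels: Sequence[str], predicted_labels: Sequence[str]) -> ConfusionMatrix:
    if len(true_labels) != len(predicted_labels):
        raise ValidationError("label lists must have equal length")
    index = {e: i for i, e in enumerate(EMOTIONS)}
    counts = np.zeros((4, 4), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            raise ValidationError(f"label outside the four classes: {t!r}/{p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts)


def class_accuracy_precision(
    cm: ConfusionMatrix, emotion: str
) -> tuple[float, Optional[float]]:
    """Per-class accuracy (TP+TN over all) and precision (TP over predicted
    positives), both as percentages; precision is ``None`` when the class is
    never predicted."""
    if emotion not in cm.labels:
        raise ValidationError(f"unknown emotion {emotion!r}")
    i = cm.labels.index(emotion)
    tp = cm.counts[i, i]
    fp = cm.counts[:, i].sum() - tp
    fn = cm.counts[i, :].sum() - tp
    tn = cm.total - tp - fp - fn
    accuracy = (tp + tn) / cm.total * 100.0
    precision = None if tp + fp == 0 else tp / (tp + fp) * 100.0
    return float(accuracy), precision


# ---------------------------------------------------------------------------
# two-proportion chi-square and phi


@dataclass
class ComparisonStat:
    """A words-versus-scales proportion contrast."""

    p1: float
    p2: float
    N: int
    chi2: float
    df: int
    p_value: float
    phi: float
    phi_ci: Optional[tuple[float, float]] = None

    def to_dict(self) -> dict:
        return {
            "p1": self.p1, "p2": self.p2, "N": self.N, "chi2": self.chi2,
            "df": self.df, "p_value": self.p_value, "phi": self.phi,
            "phi_ci": list(self.phi_ci) if self.phi_ci else None,
        }


def two_proportion_chi2(p1: float, p2: float, N: int) -> ComparisonStat:
    """Chi-square contrast of two proportions over a printed total N
    (two groups of N/2), with phi = sqrt(chi2/N)."""
    if not (0.0 <= p1 <= 1.0 and 0.0 <= p2 <= 1.0):
        raise ValidationError("proportions must lie in [0, 1]")
    if N <= 0:
        raise ValidationError("N must be positive")
    pbar = (p1 + p2) / 2.0
    if pbar in (0.0, 1.0):
        raise ValidationError("pooled proportion is degenerate (0 or 1)")
    chi2 = N * (p1 - p2) ** 2 / (4.0 * pbar * (1.0 - pbar))
    return ComparisonStat(
        p1=p1, p2=p2, N=N, chi2=float(chi2), df=1,
        p_value=float(sps.chi2.sf(chi2, df=1)), phi=float(math.sqrt(chi2 / N)),
    )


def phi_from_chi2(chi2: float, N: int) -> float:
    """Effect size phi = sqrt(chi2 / N) for a 2x2 association."""
    if chi2 < 0 or N <= 0:
        raise ValidationError("need chi2 >= 0 and N > 0")
    return float(math.sqrt(chi2 / N))


def phi_ci(
    p1: float, p2: float, N: int,
    confidence: float = 0.95, n_boot: int = 2000, rng=None,
) -> tuple[float, float]:
    """Seeded bootstrap percentile interval for the (signed) phi of a
    two-proportion contrast with group sizes N/2 each."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    n_group = max(1, int(round(N / 2)))
    a = int(round(p1 * n_group))
    b = int(round(p2 * n_group))
    draws_a = rng.binomial(n_group, a / n_group, size=n_boot) / n_group
    draws_b = rng.binomial(n_group, b / n_group, size=n_boot) / n_group
    pbar = (draws_a + draws_b) / 2.0
    ok = (pbar > 0) & (pbar < 1)
    chi2 = np.zeros(n_boot)
    chi2[ok] = N * (draws_a[ok] - draws_b[ok]) ** 2 / (4 * pbar[ok] * (1 - pbar[ok]))
    phis = np.sign(draws_a - draws_b) * np.sqrt(chi2 / N)
    alpha = (1.0 - confidence) / 2.0
    lo, hi = np.quantile(phis, [alpha, 1.0 - alpha])
    point = math.copysign(math.sqrt(two_proportion_chi2(p1, p2, N).chi2 / N), p1 - p2)
    return (float(min(lo, point)), float(max(hi, point)))


# ---------------------------------------------------------------------------
# correlations


@dataclass
class CorrelationStat:
    r: float
    n: int
    ci95: tuple[float, float]
    z_fisher: float


def fisher_ci(r: float, n: int, confidence: float = 0.95) -> CorrelationStat:
    """Pearson r with its Fisher r-to-z confidence interval."""
    if not -1.0 <= r <= 1.0:
        raise ValidationError("r must lie in [-1, 1]")
    if n <= 3:
        raise ValidationError("need n > 3 for a Fisher interval")
    if abs(r) == 1.0:  # atanh diverges; interval degenerates to the point
        return CorrelationStat(r=float(r), n=int(n), ci95=(float(r), float(r)),
                               z_fisher=math.copysign(math.inf, r))
    z = math.atanh(r)
    half = sps.norm.ppf(0.5 + confidence / 2.0) / math.sqrt(n - 3)
    return CorrelationStat(
        r=float(r), n=int(n),
        ci95=(float(math.tanh(z - half)), float(math.tanh(z + half))),
        z_fisher=float(z),
    )


def compare_correlations(r1: float, r2: float, n: int) -> tuple[float, float]:
    """Two-sided test of r1 vs r2 from two same-size samples via
    z = (atanh r2 - atanh r1) / sqrt(2 / (n - 3))."""
    if n <= 3:
        raise ValidationError("need n > 3 to compare correlations")
    z = (math.atanh(r2) - math.atanh(r1)) / math.sqrt(2.0 / (n - 3))
    return float(z), float(2.0 * sps.norm.sf(abs(z)))


def coefficient_correlations(
    coef_by_class: Mapping[str, np.ndarray]
) -> dict:
    """Pairwise Pearson correlations between per-class coefficient vectors,
    with Fisher-z 95% intervals.

    High absolute correlations between two classes' coefficients mean the
    model separates them along nearly the same direction — i.e. it confuses
    the constructs."""
    classes = list(coef_by_class)
    vectors = {c: np.asarray(v, dtype=float).ravel() for c, v in coef_by_class.items()}
    n_coef = {c: len(v) for c, v in vectors.items()}
    if min(n_coef.values()) < 2:
        raise ValidationError("need at least two coefficients per class")
    r = np.eye(len(classes))
    cis: dict[tuple[str, str], tuple[float, float]] = {}
    for i, ci_ in enumerate(classes):
        for j in range(i + 1, len(classes)):
            cj = classes[j]
            if np.ptp(vectors[ci_]) == 0 or np.ptp(vectors[cj]) == 0:
                raise ValidationError(
                    f"constant coefficient vector for {ci_!r} or {cj!r}"
                )
            rij = float(sps.pearsonr(vectors[ci_], vectors[cj]).statistic)
            r[i, j] = r[j, i] = rij
            n = len(vectors[ci_])
            cis[(ci_, cj)] = fisher_ci(rij, n).ci95 if n > 3 else (math.nan, math.nan)
    return {"classes": classes, "r": r, "ci95": cis}


# ---------------------------------------------------------------------------
# inter-rater agreement


def interrater_agreement(
    narrative_ids: Sequence,
    predicted: Sequence[str],
    true_labels: Sequence[str],
) -> dict:
    """Pairwise agreement over narratives categorized more than once.

    Over all unordered pairs of categorizations of the same narrative:
    ``agreement`` is the percentage of identical pairs; ``correct`` the
    percentage of pairs that agree *and* match the narrative's true label.
    """
    if not len(narrative_ids) == len(predicted) == len(true_labels):
        raise ValidationError("inputs must align")
    by_narrative: dict = {}
    for nid, pred, true in zip(narrative_ids, predicted, true_labels):
        by_narrative.setdefault(nid, []).append((pred, true))
    n_pairs = n_agree = n_correct = 0
    for entries in by_narrative.values():
        for i in range(len(entries)):
            for j in range(i + 1, len(entries)):
                n_pairs += 1
                (pi, ti), (pj, _) = entries[i], entries[j]
                if pi == pj:
                    n_agree += 1
                    if pi == ti:
                        n_correct += 1
    if n_pairs == 0:
        raise ValidationError("no narrative was categorized more than once")
    return {
        "agreement": n_agree / n_pairs * 100.0,
        "correct": n_correct / n_pairs * 100.0,
        "n_pairs": n_pairs,
    }


# ---------------------------------------------------------------------------
# matched-narrative correlations (H3)


def matched_correlations(
    phase1_scores: Sequence[float],
    phase2_scale_scores: Sequence[float],
    phase2_word_predictions: Sequence[float],
) -> dict:
    """Compare how well Phase-2 rating scales versus Phase-2 word-based
    regression predictions recover the Phase-1 authors' scale scores.

    All three inputs are aligned on matched narratives.  Returns both
    Pearson correlations with Fisher intervals and the two-sided p-value
    for their difference.
    """
    x = np.asarray(phase1_scores, dtype=float)
    y_scale = np.asarray(phase2_scale_scores, dtype=float)
    y_words = np.asarray(phase2_word_predictions, dtype=float)
    n = len(x)
    if not (len(y_scale) == len(y_words) == n):
        raise ValidationError("matched inputs must align")
    if n <= 3:
        raise ValidationError("need more than 3 matched narratives")
    r1 = float(sps.pearsonr(x, y_scale).statistic)
    r2 = float(sps.pearsonr(x, y_words).statistic)
    z, p = compare_correlations(r1, r2, n)
    return {
        "scales": fisher_ci(r1, n),
        "words": fisher_ci(r2, n),
        "z": z,
        "p_compare": p,
        "n": n,
    }
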