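"""Synthetic two-phase study generator.

Emulates the statistical structure the downstream analysis assumes, so the
whole pipeline is testable without any data download:

* four equally frequent emotional states (harmony, satisfaction, depression,
  anxiety), each with its own word lexicon;
* controllable lexicon overlap between the confusable construct pairs
  (depression-anxiety and satisfaction-harmony) and zero overlap across
  valence;
* rating-scale totals produced by a latent-Gaussian copula whose correlation
  matrix is strongly positive within valence, so the scales confuse
  depression with anxiety (and satisfaction with harmony) while the word
  lexicons remain mostly separable;
* Phase-2 reader pairing in which every Phase-1 narrative is evaluated at
  least once but no more than twice.

All randomness flows from one master seed; each stage uses its own stream
derived by a fixed offset, so stages are individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm

from .records import EMOTIONS, SCALES, SCALE_NAMES, ResponseRecord, ValidationError

#: Confusable construct pairs: distinct constructs that rating scales
#: struggle to tell apart.
CONFUSABLE_PAIRS: tuple[tuple[str, str], ...] = (
    ("depression", "anxiety"),
    ("satisfaction", "harmony"),
)

# Real seed words per emotion (high-association vocabulary); lists are padded
# with synthetic tokens up to the configured lexicon size.
_SEED_WORDS: dict[str, tuple[str, ...]] = {
    "depression": ("sad", "depressed", "hopeless", "empty", "tired"),
    "anxiety": ("anxious", "worried", "nervous", "tense", "scared"),
    "satisfaction": ("happy", "content", "satisfied", "fulfilled", "proud"),
    "harmony": ("calm", "peaceful", "hopeful", "balanced", "serene"),
}

# Fixed per-stage offsets added to the master seed (stage-level streams).
_STREAM_OFFSETS = {"phase1": 1, "phase2": 2, "scales": 3, "pairing": 4, "roles": 5}


def _default_scale_corr() -> np.ndarray:
    """Latent correlations: 0.85 within valence, -0.6 across valence."""
    within, across = 0.85, -0.6
    c = np.full((4, 4), across)
    # order: phq9, gad7, swls, hils
    c[0, 1] = c[1, 0] = within
    c[2, 3] = c[3, 2] = within
    np.fill_diagonal(c, 1.0)
    return c


def _default_mean_profile() -> dict[str, tuple[float, float, float, float]]:
    """Latent z-score means per emotion for (phq9, gad7, swls, hils).

    Depression and anxiety share elevated negative-affect scores and differ
    only modestly on which of PHQ-9/GAD-7 dominates; likewise satisfaction
    and harmony on SWLS/HILS.  The depression-anxiety separation is kept
    slightly smaller than satisfaction-harmony, mirroring rating scales'
    particular difficulty with anxiety.
    """
    return {
        "harmony": (-0.8, -0.8, 0.6, 1.0),
        "satisfaction": (-0.8, -0.8, 1.0, 0.6),
        "depression": (1.0, 0.7, -0.8, -0.8),
        "anxiety": (0.7, 1.0, -0.8, -0.8),
    }


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic study.

    Defaults reproduce the study conditions downstream stages are evaluated
    under: 297 Phase-1 authors, 434 Phase-2 readers (34 of them
    professionals), five-word responses with 20% off-lexicon noise, and a
    latent depression-anxiety (and satisfaction-harmony) scale correlation
    of 0.85.
    """

    n_phase1: int = 297
    n_phase2: int = 434
    lexicon_size_per_emotion: int = 40
    lexicon_overlap: float = 0.2
    word_noise: float = 0.2
    scale_mean_profile: Mapping[str, Sequence[float]] = field(
        default_factory=_default_mean_profile
    )
    scale_corr: np.ndarray = field(default_factory=_default_scale_corr)
    professional_fraction: float = 34 / 434
    seed: int = 42

    def validate(self) -> None:
        if self.n_phase1 <= 0 or self.n_phase2 <= 0:
            raise ValidationError("sample sizes must be positive")
        if not 0.0 <= self.lexicon_overlap <= 1.0:
            raise ValidationError(
                f"lexicon_overlap must lie in [0, 1], got {self.lexicon_overlap}"
            )
        if not 0.0 <= self.word_noise <= 1.0:
            raise ValidationError(f"word_noise must lie in [0, 1], got {self.word_noise}")
        if not 0.0 <= self.professional_fraction <= 1.0:
            raise ValidationError("professional_fraction must lie in [0, 1]")
        if self.lexicon_size_per_emotion < 5:
            raise ValidationError("lexicon_size_per_emotion must be at least 5")
        corr = np.asarray(self.scale_corr, dtype=float)
        if corr.shape != (4, 4) or not np.allclose(corr, corr.T):
            raise ValidationError("scale_corr must be a symmetric 4x4 matrix")
        if not np.allclose(np.diag(corr), 1.0):
            raise ValidationError("scale_corr must have a unit diagonal")
        if np.linalg.eigvalsh(corr)[0] <= 0:
            raise ValidationError("scale_corr must be positive definite")

    def to_dict(self) -> dict:
        return {
            "n_phase1": self.n_phase1,
            "n_phase2": self.n_phase2,
            "lexicon_size_per_emotion": self.lexicon_size_per_emotion,
            "lexicon_overlap": self.lexicon_overlap,
            "word_noise": self.word_noise,
            "scale_mean_profile": {
                e: list(map(float, v)) for e, v in dict(self.scale_mean_profile).items()
            },
            "scale_corr": np.asarray(self.scale_corr, dtype=float).tolist(),
            "professional_fraction": self.professional_fraction,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "scale_corr" in d:
            d["scale_corr"] = np.asarray(d["scale_corr"], dtype=float)
        return cls(**d)


def build_lexicons(config: GeneratorConfig) -> dict[str, list[str]]:
    """Build the four emotion lexicons.

    Each confusable pair shares ``round(overlap * size)`` words; the shared
    words are listed first so that full overlap makes the two lists
    identical.  Cross-valence lexicons never share a word.
    """
    config.validate()
    size = config.lexicon_size_per_emotion
    n_shared = int(round(config.lexicon_overlap * size))
    lexicons: dict[str, list[str]] = {}
    for e1, e2 in CONFUSABLE_PAIRS:
        shared = [f"{e1[:3]}_{e2[:3]}_shared_{i}" for i in range(n_shared)]
        for emotion in (e1, e2):
            own = list(_SEED_WORDS[emotion][: size - n_shared])
            own += [f"{emotion}_{i}" for i in range(size - n_shared - len(own))]
            lexicons[emotion] = shared + own
    return {e: lexicons[e] for e in EMOTIONS}


def sample_words(
    emotion: str,
    lexicons: Mapping[str, Sequence[str]],
    word_noise: float,
    rng: np.random.Generator,
    n_words: int = 5,
) -> tuple[str, ...]:
    """Draw five descriptive words for one response.

    Each slot comes from the true emotion's lexicon with probability
    ``1 - word_noise`` and otherwise from another emotion's lexicon
    (excluding any word the true lexicon also contains).  Words within one
    response are drawn without replacement.
    """
    own = list(lexicons[emotion])
    own_set = set(own)
    other = sorted(
        {w for e, lex in lexicons.items() if e != emotion for w in lex} - own_set
    )
    words: list[str] = []
    chosen: set[str] = set()
    for _ in range(n_words):
        pool = other if rng.random() < word_noise else own
        avail = [w for w in pool if w not in chosen]
        if not avail:  # tiny lexicons: fall back to reuse
            avail = list(pool)
        w = avail[rng.integers(len(avail))]
        words.append(w)
        chosen.add(w)
    return tuple(words)


def _totals_from_latent(z: np.ndarray) -> np.ndarray:
    """Map latent Gaussian scores to integer scale totals via the probability
    integral transform (Gaussian copula with near-uniform grades)."""
    totals = np.empty_like(z, dtype=int)
    for j, scale in enumerate(SCALE_NAMES):
        n_items, lo, hi = SCALES[scale]
        t_lo, t_hi = n_items * lo, n_items * hi
        levels = t_hi - t_lo + 1
        grade = norm.cdf(z[:, j])
        totals[:, j] = t_lo + np.minimum(levels - 1, np.floor(grade * levels).astype(int))
    return totals


def _split_total_into_items(
    total: int, scale: str, rng: np.random.Generator
) -> tuple[int, ...]:
    """Random item vector with the given sum, each item within its range."""
    n_items, lo, hi = SCALES[scale]
    span = hi - lo
    excess = total - n_items * lo
    items = []
    for slot in range(n_items):
        slots_left = n_items - slot - 1
        low = max(0, excess - slots_left * span)
        high = min(span, excess)
        x = int(rng.integers(low, high + 1))
        items.append(lo + x)
        excess -= x
    return tuple(items)


def sample_scale_items(
    emotion: str, config: GeneratorConfig, rng: np.random.Generator, n: int = 1
) -> list[dict[str, tuple[int, ...]]]:
    """Draw ``n`` sets of item-level scale responses for one emotion.

    Latent scores are multivariate normal with the emotion's mean profile
    and ``scale_corr``; totals come from the copula transform and are then
    split at random into range-respecting items.
    """
    config.validate()
    mean = np.asarray(dict(config.scale_mean_profile)[emotion], dtype=float)
    corr = np.asarray(config.scale_corr, dtype=float)
    z = rng.multivariate_normal(mean, corr, size=n, method="cholesky")
    totals = _totals_from_latent(z)
    out = []
    for row in totals:
        out.append(
            {
                scale: _split_total_into_items(int(row[j]), scale, rng)
                for j, scale in enumerate(SCALE_NAMES)
            }
        )
    return out


def _phase1_emotions(n: int, rng: np.random.Generator) -> list[str]:
    """Balanced assignment (per-emotion counts differ by at most one)."""
    reps = [EMOTIONS[i % 4] for i in range(n)]
    perm = rng.permutation(n)
    return [reps[i] for i in perm]


def generate_dataset(config: GeneratorConfig) -> list[ResponseRecord]:
    """Generate the full two-phase synthetic study.

    Phase 1: ``n_phase1`` authors, one narrative each, emotions balanced.
    Phase 2: ``n_phase2`` readers (must lie in ``[n_phase1, 2*n_phase1]``);
    each narrative is read once or twice, and a configurable fraction of
    readers are flagged as healthcare professionals.
    """
    config.validate()
    if not config.n_phase1 <= config.n_phase2 <= 2 * config.n_phase1:
        raise ValidationError(
            f"n_phase2={config.n_phase2} must lie between n_phase1 and "
            f"2*n_phase1 to read every narrative once or twice"
        )
    lexicons = build_lexicons(config)
    rng_w1 = np.random.default_rng(config.seed + _STREAM_OFFSETS["phase1"])
    rng_w2 = np.random.default_rng(config.seed + _STREAM_OFFSETS["phase2"])
    rng_s = np.random.default_rng(config.seed + _STREAM_OFFSETS["scales"])
    rng_pair = np.random.default_rng(config.seed + _STREAM_OFFSETS["pairing"])
    rng_role = np.random.default_rng(config.seed + _STREAM_OFFSETS["roles"])

    records: list[ResponseRecord] = []
    emotions1 = _phase1_emotions(config.n_phase1, rng_w1)
    items1 = {
        e: iter(sample_scale_items(e, config, rng_s, n=emotions1.count(e)))
        for e in EMOTIONS
    }
    for i, emotion in enumerate(emotions1):
        items = next(items1[emotion])
        records.append(
            ResponseRecord(
                record_id=f"p1_{i:04d}",
                phase=1,
                role="control",
                narrative_id=f"n{i:04d}",
                true_emotion=emotion,
                words=sample_words(emotion, lexicons, config.word_noise, rng_w1),
                **{f"{s}_items": items[s] for s in SCALE_NAMES},
            )
        )

    # Phase-2 pairing: every narrative once, a random subset a second time.
    n_extra = config.n_phase2 - config.n_phase1
    twice = rng_pair.choice(config.n_phase1, size=n_extra, replace=False)
    assignment = list(range(config.n_phase1)) + list(twice)
    assignment = [assignment[i] for i in rng_pair.permutation(len(assignment))]
    n_prof = int(round(config.professional_fraction * config.n_phase2))
    prof_idx = set(rng_role.choice(config.n_phase2, size=n_prof, replace=False).tolist())

    emotions2 = [emotions1[j] for j in assignment]
    items2 = {
        e: iter(sample_scale_items(e, config, rng_s, n=emotions2.count(e)))
        for e in EMOTIONS
    }
    for i, j in enumerate(assignment):
        emotion = emotions1[j]
        items = next(items2[emotion])
        records.append(
            ResponseRecord(
                record_id=f"p2_{i:04d}",
                phase=2,
                role="professional" if i in prof_idx else "control",
                narrative_id=f"n{j:04d}",
                true_emotion=emotion,
                words=sample_words(emotion, lexicons, config.word_noise, rng_w2),
                **{f"{s}_items": items[s] for s in SCALE_NAMES},
            )
        )
    return records
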