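"""Word embeddings and feature-matrix construction.

Encoders map a single token to a fixed-length vector (768 dimensions by
default, matching the uncased transformer used for the real data) and a
five-word response to the unweighted mean of its word vectors.  The encoder
contract is pluggable; the package ships a deterministic mock encoder whose
class geometry is known by construction, which is what makes the synthetic
recovery experiments provable: a token from a synthetic lexicon gets a
seeded pseudo-random unit vector plus its emotion's class direction, so
noise-free classes are linearly separable.
"""

from __future__ import annotations

import hashlib
from typing import Iterable, Mapping, Protocol, Sequence

import numpy as np

from .classification import FeatureMatrix
from .records import SCALE_NAMES, ResponseRecord, ValidationError

FEATURE_SETS = ("words", "scales", "combined", "items")


class Encoder(Protocol):
    """Deterministic token-to-vector contract: the same token must always
    produce bit-identical output, and ``dim`` never changes."""

    name: str
    dim: int

    def encode_word(self, token: str) -> np.ndarray: ...


def _token_seed(token: str, salt: int) -> int:
    """Stable 31-bit seed for a token (independent of hash randomization)."""
    digest = hashlib.sha256(f"{salt}:{token}".encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


class MockEncoder:
    """Deterministic synthetic encoder with known class geometry.

    Every token maps to a unit pseudo-random vector seeded by the token
    itself.  Tokens found in a lexicon additionally receive ``signal`` times
    the mean of the class directions of the emotions whose lexicons contain
    them (shared confusable-pair words therefore sit between the two class
    directions).  Out-of-lexicon tokens are pure seeded noise.
    """

    def __init__(
        self,
        lexicons: Mapping[str, Sequence[str]] | None = None,
        dim: int = 768,
        signal: float = 1.0,
        seed: int = 0,
    ):
        if dim < 1:
            raise ValidationError("encoder dimensionality must be positive")
        self.name = "mock"
        self.dim = dim
        self.signal = signal
        self.seed = seed
        lexicons = lexicons or {}
        rng = np.random.default_rng(seed)
        self._class_dir: dict[str, np.ndarray] = {}
        for emotion in lexicons:
            v = rng.standard_normal(dim)
            self._class_dir[emotion] = v / np.linalg.norm(v)
        self._membership: dict[str, list[str]] = {}
        for emotion, lex in lexicons.items():
            for token in lex:
                self._membership.setdefault(token, []).append(emotion)

    def encode_word(self, token: str) -> np.ndarray:
        if not token or any(ch.isspace() for ch in token):
            raise ValidationError(f"cannot encode empty or multi-token input {token!r}")
        rng = np.random.default_rng(_token_seed(token, self.seed))
        v = rng.standard_normal(self.dim)
        v /= np.linalg.norm(v)
        emotions = self._membership.get(token)
        if emotions:
            direction = np.mean([self._class_dir[e] for e in emotions], axis=0)
            v = v + self.signal * direction
        return v


def encode_word(encoder: Encoder, token: str) -> np.ndarray:
    """Encode one cleaned token."""
    return encoder.encode_word(token)


def encode_response(encoder: Encoder, words: Iterable[str]) -> np.ndarray:
    """Encode a response as the unweighted mean of its word vectors."""
    words = list(words)
    if not words:
        raise ValidationError("cannot encode a response with zero words")
    return np.mean([encoder.encode_word(w) for w in words], axis=0)


def build_feature_matrix(
    records: Sequence[ResponseRecord],
    feature_set: str,
    encoder: Encoder | None = None,
) -> FeatureMatrix:
    """Assemble the design matrix for one feature set.

    ``words``: mean word embeddings (``encoder.dim`` columns, 768 default).
    ``scales``: the four rating-scale totals.
    ``combined``: word embeddings followed by the four totals.
    ``items``: the 26 item-level scale answers (9 + 7 + 5 + 5).
    Row order follows ``records``; narrative ids ride along for grouping.
    """
    if feature_set not in FEATURE_SETS:
        raise ValidationError(
            f"unknown feature_set {feature_set!r}; expected one of {FEATURE_SETS}"
        )
    if not records:
        raise ValidationError("no records to featurize")
    if feature_set in ("words", "combined") and encoder is None:
        raise ValidationError(f"feature_set {feature_set!r} requires an encoder")

    blocks: list[np.ndarray] = []
    if feature_set in ("words", "combined"):
        blocks.append(np.vstack([encode_response(encoder, r.words) for r in records]))
    if feature_set in ("scales", "combined"):
        blocks.append(np.array([r.totals for r in records], dtype=float))
    if feature_set == "items":
        blocks.append(
            np.array(
                [sum((r.items_for(s) for s in SCALE_NAMES), ()) for r in records],
                dtype=float,
            )
        )
    return FeatureMatrix(
        X=np.hstack(blocks),
        narrative_ids=np.array([r.narrative_id for r in records]),
        labels=np.array([r.true_emotion for r in records]),
        feature_set=feature_set,
    )
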