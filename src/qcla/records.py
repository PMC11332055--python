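"""Core record types for the two-phase emotional-narrative study.

A *narrative* is written in Phase 1 by one participant about one of four
emotional states; in Phase 2 other readers evaluate that narrative.  Every
evaluation — the author's own in Phase 1 or a reader's in Phase 2 — is one
:class:`ResponseRecord`: five descriptive words plus item-level answers to
the four standardized rating scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as _replace
from typing import Sequence

#: Fixed class order used everywhere (fold plans, confusion matrices,
#: argmax tie-breaking).
EMOTIONS: tuple[str, ...] = ("harmony", "satisfaction", "depression", "anxiety")

#: Rating scales in canonical order with (number of items, item min, item max).
SCALES: dict[str, tuple[int, int, int]] = {
    "phq9": (9, 0, 3),   # depression severity, total 0-27
    "gad7": (7, 0, 3),   # generalized anxiety, total 0-21
    "swls": (5, 1, 7),   # satisfaction with life, total 5-35
    "hils": (5, 1, 7),   # harmony in life, total 5-35
}

SCALE_NAMES: tuple[str, ...] = tuple(SCALES)


class ValidationError(ValueError):
    """A record or configuration violates a documented range or invariant."""


@dataclass(frozen=True)
class ResponseRecord:
    """One rater's evaluation of one narrative.

    Parameters
    ----------
    record_id:
        Unique identifier of this evaluation.
    phase:
        1 for the narrative's author, 2 for a reader.
    role:
        ``"control"`` (lay rater) or ``"professional"`` (healthcare
        professional; Phase 2 only in the study design).
    narrative_id:
        Identifier of the Phase-1 narrative being evaluated.  Used for
        grouped cross-validation so evaluations of the same narrative never
        span a train/test split.
    true_emotion:
        The emotional state the narrative was written about.
    words:
        The five (post-cleaning possibly fewer) single-token descriptive
        words.
    *_items:
        Item-level rating-scale answers.
    control_passed:
        Whether the rater answered the embedded control questions correctly.
    """

    record_id: str
    phase: int
    role: str
    narrative_id: str
    true_emotion: str
    words: tuple[str, ...]
    phq9_items: tuple[int, ...]
    gad7_items: tuple[int, ...]
    swls_items: tuple[int, ...]
    hils_items: tuple[int, ...]
    control_passed: bool = True
    meta: dict = field(default_factory=dict, compare=False)

    def items_for(self, scale: str) -> tuple[int, ...]:
        return getattr(self, f"{scale}_items")

    def total(self, scale: str) -> int:
        return sum(self.items_for(scale))

    @property
    def totals(self) -> tuple[int, ...]:
        """The four scale totals in canonical order (phq9, gad7, swls, hils)."""
        return tuple(self.total(s) for s in SCALE_NAMES)

    def with_words(self, words: Sequence[str]) -> "ResponseRecord":
        return _replace(self, words=tuple(words))

    def validate(self) -> None:
        """Raise :class:`ValidationError` on any out-of-range field."""
        if self.phase not in (1, 2):
            raise ValidationError(f"phase must be 1 or 2, got {self.phase!r}")
        if self.role not in ("control", "professional"):
            raise ValidationError(f"unknown role {self.role!r}")
        if self.true_emotion not in EMOTIONS:
            raise ValidationError(f"unknown emotion {self.true_emotion!r}")
        if not 1 <= len(self.words) <= 5:
            raise ValidationError(
                f"{self.record_id}: expected 1-5 words, got {len(self.words)}"
            )
        for w in self.words:
            if (not w) or any(ch.isspace() for ch in w):
                raise ValidationError(
                    f"{self.record_id}: word {w!r} is empty or multi-token"
                )
        for scale, (n_items, lo, hi) in SCALES.items():
            items = self.items_for(scale)
            if len(items) != n_items:
                raise ValidationError(
                    f"{self.record_id}: {scale} needs {n_items} items, got {len(items)}"
                )
            for v in items:
                if not lo <= v <= hi:
                    raise ValidationError(
                        f"{self.record_id}: {scale} item {v} outside [{lo}, {hi}]"
                    )
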