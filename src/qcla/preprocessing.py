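"""Deterministic cleaning of descriptive-word responses.

The cleaning rules mirror a manual survey-hygiene pass: case folding,
removal of "N/A" placeholders, collapsing successively repeated words,
rejection of multi-word entries, and dropping raters who failed the
embedded control questions.  An optional dictionary pass corrects a
misspelling only when a unique edit-distance-1 candidate exists; otherwise
the original form is retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .records import ResponseRecord

# Reason codes attached to the cleaning report.
CONTROL_FAILED = "control_failed"
NA_WORD = "na_word"
MULTI_TOKEN = "multi_token"
ADJACENT_DUPLICATE = "adjacent_duplicate"
SPELL_CORRECTED = "spell_corrected"
NO_WORDS_LEFT = "no_words_left"

_NA_FORMS = {"n/a", "na"}


@dataclass
class CleaningOptions:
    """Cleaning switches.

    Spell correction is off by default: the original procedure was a
    human-in-the-loop check that cannot be replayed mechanically.  When
    enabled, ``dictionary`` supplies the reference word list.
    """

    spell_correct: bool = False
    dictionary: Optional[Sequence[str]] = None


@dataclass
class CleaningReport:
    """Bookkeeping for one cleaning pass; input = retained + dropped."""

    n_input: int = 0
    n_retained: int = 0
    n_dropped_records: int = 0
    n_corrected_words: int = 0
    n_removed_words: int = 0
    reasons: dict[str, list[str]] = field(default_factory=dict)

    def note(self, record_id: str, code: str) -> None:
        self.reasons.setdefault(record_id, []).append(code)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "n_dropped_records": self.n_dropped_records,
            "n_corrected_words": self.n_corrected_words,
            "n_removed_words": self.n_removed_words,
            "reasons": self.reasons,
        }


def _edit_distance_leq1(a: str, b: str) -> bool:
    """True when the Damerau-Levenshtein distance of ``a`` and ``b`` is at
    most 1 (one substitution, insertion, deletion, or adjacent swap — the
    classic "hte" -> "the" typo)."""
    if a == b:
        return True
    la, lb = len(a), len(b)
    if abs(la - lb) > 1:
        return False
    if la == lb:
        diff = [i for i, (x, y) in enumerate(zip(a, b)) if x != y]
        if len(diff) == 1:
            return True
        return (
            len(diff) == 2
            and diff[1] == diff[0] + 1
            and a[diff[0]] == b[diff[1]]
            and a[diff[1]] == b[diff[0]]
        )
    if la > lb:
        a, b, la, lb = b, a, lb, la
    # one insertion into the shorter string
    i = j = mismatches = 0
    while i < la and j < lb:
        if a[i] == b[j]:
            i += 1
        else:
            mismatches += 1
            if mismatches > 1:
                return False
        j += 1
    return True


def _spell_correct(word: str, dictionary: Sequence[str]) -> Optional[str]:
    """Return the unique edit-distance-1 dictionary correction, if any."""
    if word in dictionary:
        return None
    hits = [w for w in dictionary if _edit_distance_leq1(word, w)]
    return hits[0] if len(hits) == 1 else None


def clean_words(
    record: ResponseRecord,
    options: CleaningOptions | None = None,
    report: CleaningReport | None = None,
) -> Optional[ResponseRecord]:
    """Clean one record's words; return ``None`` when the record is dropped.

    Rules, in order: drop control-question failures; lowercase and trim
    every entry; discard multi-token entries and "N/A" placeholders;
    optionally spell-correct; collapse immediately repeated words.  A record
    with no surviving word is dropped.
    """
    options = options or CleaningOptions()
    report = report if report is not None else CleaningReport()
    if not record.control_passed:
        report.note(record.record_id, CONTROL_FAILED)
        return None

    cleaned: list[str] = []
    for raw in record.words:
        w = raw.strip().lower()
        if not w or any(ch.isspace() for ch in w):
            report.note(record.record_id, MULTI_TOKEN)
            report.n_removed_words += 1
            continue
        if w in _NA_FORMS:
            report.note(record.record_id, NA_WORD)
            report.n_removed_words += 1
            continue
        if options.spell_correct and options.dictionary is not None:
            fix = _spell_correct(w, options.dictionary)
            if fix is not None:
                report.note(record.record_id, SPELL_CORRECTED)
                report.n_corrected_words += 1
                w = fix
        if cleaned and cleaned[-1] == w:
            report.note(record.record_id, ADJACENT_DUPLICATE)
            report.n_removed_words += 1
            continue
        cleaned.append(w)

    if not cleaned:
        report.note(record.record_id, NO_WORDS_LEFT)
        return None
    return record.with_words(cleaned)


def clean_dataset(
    records: Iterable[ResponseRecord], options: CleaningOptions | None = None
) -> tuple[list[ResponseRecord], CleaningReport]:
    """Clean every record, returning survivors and the aggregate report."""
    report = CleaningReport()
    kept: list[ResponseRecord] = []
    for rec in records:
        report.n_input += 1
        out = clean_words(rec, options, report)
        if out is None:
            report.n_dropped_records += 1
        else:
            kept.append(out)
    report.n_retained = len(kept)
    return kept, report


def forbid_target_word(record: ResponseRecord, emotion: str | None = None) -> list[str]:
    """Flag uses of the condition word itself.

    Phase-1 authors were instructed not to use the name of the emotion they
    wrote about; exact (case-insensitive) matches are flagged, never
    deleted.  Phase-2 readers were not told the condition, so their records
    are never flagged — for them the condition word is legitimate evidence.
    """
    if record.phase != 1:
        return []
    target = (emotion or record.true_emotion).lower()
    return [w for w in record.words if w.lower() == target]
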