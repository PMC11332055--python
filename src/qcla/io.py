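"""Canonical file formats.

Records travel as a UTF-8, tab-delimited table with a header row: one row
per response, words expanded to ``word_1..word_5`` and scale items to
``phq9_1..phq9_9`` etc.  Generator/run configurations and derived results
are JSON.  Row-level read errors are collected with their line numbers
rather than silently dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .records import SCALES, SCALE_NAMES, ResponseRecord, ValidationError

_META_COLS = ["record_id", "phase", "role", "narrative_id", "true_emotion"]
_WORD_COLS = [f"word_{i}" for i in range(1, 6)]
_ITEM_COLS = [
    f"{scale}_{i}" for scale in SCALE_NAMES for i in range(1, SCALES[scale][0] + 1)
]
COLUMNS = _META_COLS + _WORD_COLS + _ITEM_COLS + ["control_passed"]


@dataclass
class RowError:
    line: int
    message: str


def records_to_frame(records: Sequence[ResponseRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row: dict = {
            "record_id": r.record_id,
            "phase": r.phase,
            "role": r.role,
            "narrative_id": r.narrative_id,
            "true_emotion": r.true_emotion,
        }
        for i in range(5):
            row[f"word_{i + 1}"] = r.words[i] if i < len(r.words) else ""
        for scale in SCALE_NAMES:
            for i, v in enumerate(r.items_for(scale), start=1):
                row[f"{scale}_{i}"] = v
        row["control_passed"] = int(r.control_passed)
        rows.append(row)
    return pd.DataFrame(rows, columns=COLUMNS)


def write_records(records: Sequence[ResponseRecord], path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def read_records(path) -> tuple[list[ResponseRecord], list[RowError]]:
    """Parse the canonical TSV; returns (records, row-level errors)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")
    records: list[ResponseRecord] = []
    errors: list[RowError] = []
    for pos, row in enumerate(df.itertuples(index=False)):
        line = pos + 2  # header is line 1
        row = dict(zip(df.columns, row))
        try:
            words = tuple(w for w in (row[c] for c in _WORD_COLS) if w != "")
            items = {
                scale: tuple(
                    int(row[f"{scale}_{i}"]) for i in range(1, SCALES[scale][0] + 1)
                )
                for scale in SCALE_NAMES
            }
            rec = ResponseRecord(
                record_id=row["record_id"],
                phase=int(row["phase"]),
                role=row["role"],
                narrative_id=row["narrative_id"],
                true_emotion=row["true_emotion"],
                words=words,
                control_passed=bool(int(row["control_passed"])),
                **{f"{s}_items": items[s] for s in SCALE_NAMES},
            )
            rec.validate()
            records.append(rec)
        except (ValidationError, ValueError) as e:
            errors.append(RowError(line=line, message=str(e)))
    return records, errors


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)
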