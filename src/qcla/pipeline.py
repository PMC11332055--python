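"""End-to-end experiment orchestration.

``run_experiment`` ties the stages together: obtain records (synthetic
generation or the canonical TSV), clean the word responses, build one
feature matrix per requested feature set, run the grouped cross-validated
categorization, and compute the comparative statistics (confusion,
per-class accuracy/precision, the words-versus-scales proportion contrast,
inter-rater agreement, coefficient correlations) plus, optionally, the
continuous scale-score regression with matched-narrative correlations and
the semantic word-cloud contrasts.

Every artifact embeds the master seed and a hash of the configuration, so
reruns with the mock encoder are bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import io as qio
from .classification import (
    FeatureMatrix,
    cross_validated_categorize,
    ladder_for,
    regress_scale_scores,
)
from .contrast import contrast_all_emotions, top_words
from .embedding import MockEncoder, build_feature_matrix
from .preprocessing import CleaningOptions, clean_dataset
from .records import EMOTIONS, SCALE_NAMES, ResponseRecord, ValidationError
from .stats import (
    class_accuracy_precision,
    coefficient_correlations,
    confusion,
    interrater_agreement,
    matched_correlations,
    phi_ci,
    two_proportion_chi2,
)
from .synthetic import GeneratorConfig, build_lexicons, generate_dataset

log = logging.getLogger("qcla")

# fixed per-stage seed offsets (stage-level reproducibility)
_SEED_OFFSETS = {
    "words": 101, "scales": 102, "combined": 103, "items": 104,
    "regression": 201, "contrast": 301, "bootstrap": 401,
}


@dataclass
class RunConfig:
    """What to run and on which slice of the data.

    Either ``generator`` (synthetic study) or ``input_path`` (canonical
    record TSV) supplies the records.  The default slice is the Phase-2
    lay-reader group, the headline comparison of the study design.
    """

    generator: Optional[GeneratorConfig] = None
    input_path: Optional[str] = None
    feature_sets: tuple[str, ...] = ("words", "scales")
    k: int = 10
    inner_k: int = 5
    seed: int = 42
    phase_filter: Optional[int] = 2
    role_filter: Optional[str] = "control"
    encoder_signal: float = 1.0
    run_regression: bool = False
    run_contrast: bool = False
    outdir: Optional[str] = None
    cleaning: CleaningOptions = field(default_factory=CleaningOptions)

    def config_hash(self) -> str:
        payload = {
            "generator": self.generator.to_dict() if self.generator else None,
            "input_path": self.input_path,
            "feature_sets": list(self.feature_sets),
            "k": self.k, "inner_k": self.inner_k, "seed": self.seed,
            "phase_filter": self.phase_filter, "role_filter": self.role_filter,
            "encoder_signal": self.encoder_signal,
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_records(config: RunConfig) -> list[ResponseRecord]:
    if config.input_path is not None:
        records, errors = qio.read_records(config.input_path)
        if errors:
            raise ValidationError(
                f"{len(errors)} malformed rows, first: "
                f"line {errors[0].line}: {errors[0].message}"
            )
        return records
    if config.generator is None:
        raise ValidationError("RunConfig needs a generator or an input path")
    return generate_dataset(config.generator)


def _subset(records: Sequence[ResponseRecord], config: RunConfig) -> list[ResponseRecord]:
    out = [
        r for r in records
        if (config.phase_filter is None or r.phase == config.phase_filter)
        and (config.role_filter is None or r.role == config.role_filter)
    ]
    if not out:
        raise ValidationError("phase/role filters left no records")
    return out


def make_encoder(config: RunConfig) -> MockEncoder:
    lexicons = build_lexicons(config.generator) if config.generator else None
    return MockEncoder(lexicons=lexicons, signal=config.encoder_signal,
                       seed=config.seed)


def run_experiment(config: RunConfig) -> dict:
    """Run the configured stages; returns (and optionally writes) the report."""
    t0 = time.time()
    all_records = load_records(config)
    log.info("loaded %d records", len(all_records))
    cleaned, cleaning_report = clean_dataset(all_records, config.cleaning)
    log.info("cleaning kept %d/%d records", len(cleaned), len(all_records))
    analysis_records = _subset(cleaned, config)
    log.info("analysis subset: %d records", len(analysis_records))
    encoder = make_encoder(config)

    report: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_records": len(all_records),
        "n_analysis": len(analysis_records),
        "cleaning": cleaning_report.to_dict(),
        "feature_sets": {},
    }

    results = {}
    for fs in config.feature_sets:
        t = time.time()
        features = build_feature_matrix(analysis_records, fs, encoder)
        res = cross_validated_categorize(
            features, k=config.k, inner_k=config.inner_k,
            rng=np.random.default_rng(config.seed + _SEED_OFFSETS[fs]),
        )
        results[fs] = res
        cm = confusion(res.true_labels, res.predicted)
        acc_prec = {
            e: dict(zip(("accuracy", "precision"), class_accuracy_precision(cm, e)))
            for e in EMOTIONS
        }
        agreement = None
        nid = features.narrative_ids
        if len(nid) > len(set(nid.tolist())):
            agreement = interrater_agreement(nid, res.predicted, res.true_labels)
        coef_corr = coefficient_correlations(
            {e: np.concatenate([c[i] for c in res.coefficients])
             for i, e in enumerate(EMOTIONS)}
        )
        report["feature_sets"][fs] = {
            "percent_correct": res.percent_correct,
            "selected_dims": [int(m) for m in res.selected_dims],
            "mean_selected_dims": float(np.mean(res.selected_dims)),
            "confusion": cm.counts.tolist(),
            "confusion_labels": list(EMOTIONS),
            "accuracy_precision": acc_prec,
            "interrater": agreement,
            "coefficient_correlations": {
                "classes": coef_corr["classes"],
                "r": coef_corr["r"].tolist(),
            },
        }
        log.info("feature set %s: %.1f%% correct (%.1fs)",
                 fs, res.percent_correct, time.time() - t)

    if "words" in results and "scales" in results:
        n = len(analysis_records)
        p_words = results["words"].percent_correct / 100.0
        p_scales = results["scales"].percent_correct / 100.0
        stat = two_proportion_chi2(p_words, p_scales, n)
        stat.phi_ci = phi_ci(
            p_words, p_scales, n,
            rng=np.random.default_rng(config.seed + _SEED_OFFSETS["bootstrap"]),
        )
        report["words_vs_scales"] = stat.to_dict()
        log.info("words vs scales: chi2=%.2f p=%.4g phi=%.2f",
                 stat.chi2, stat.p_value, stat.phi)

    if config.run_regression and "words" in results:
        report["h3"] = _run_h3(config, cleaned, analysis_records, encoder)

    if config.run_contrast:
        report["contrast"] = _run_contrast(config, cleaned, encoder)

    log.info("experiment finished in %.1fs", time.time() - t0)
    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        qio.write_json(report, outdir / "report.json")
        for fs, res in results.items():
            qio.write_json(res.to_dict(), outdir / f"classification_{fs}.json")
        if config.run_contrast and "contrast_table" in report.get("contrast", {}):
            import pandas as pd

            pd.DataFrame(report["contrast"]["contrast_table"]).to_csv(
                outdir / "word_clouds.tsv", sep="\t", index=False
            )
    return report


def _run_h3(config, cleaned, analysis_records, encoder) -> dict:
    """Continuous scale-score regression and matched-narrative correlations:
    does a word-based prediction of each rating scale track the Phase-1
    author's own score better than the Phase-2 reader's rating does?"""
    features = build_feature_matrix(analysis_records, "words", encoder)
    totals = np.array([r.totals for r in analysis_records], dtype=float)
    reg = regress_scale_scores(
        features, totals, k=config.k, inner_k=config.inner_k,
        rng=np.random.default_rng(config.seed + _SEED_OFFSETS["regression"]),
    )
    phase1_totals = {
        r.narrative_id: r.totals for r in cleaned if r.phase == 1
    }
    keep = [i for i, r in enumerate(analysis_records)
            if r.narrative_id in phase1_totals]
    out: dict = {"n_matched": len(keep), "scales": {}}
    for j, scale in enumerate(SCALE_NAMES):
        x1 = [phase1_totals[analysis_records[i].narrative_id][j] for i in keep]
        y_scale = [analysis_records[i].totals[j] for i in keep]
        y_words = reg["predictions"][keep, j]
        m = matched_correlations(x1, y_scale, y_words)
        out["scales"][scale] = {
            "r_scales": m["scales"].r, "ci_scales": list(m["scales"].ci95),
            "r_words": m["words"].r, "ci_words": list(m["words"].ci95),
            "z": m["z"], "p_compare": m["p_compare"], "n": m["n"],
        }
    return out


def _run_contrast(config, cleaned, encoder) -> dict:
    """Semantic t-test word clouds, pooling Phase-1 and Phase-2 words."""
    words: list[str] = []
    emotions: list[str] = []
    for r in cleaned:
        words.extend(r.words)
        emotions.extend([r.true_emotion] * len(r.words))
    vectors = {w: encoder.encode_word(w) for w in set(words)}
    by_emotion = contrast_all_emotions(
        words, emotions, vectors, k=config.k,
        seed=config.seed + _SEED_OFFSETS["contrast"],
    )
    table = top_words(by_emotion)
    return {
        "n_occurrences": len(words),
        "n_unique_words": len(vectors),
        "contrast_table": table.to_dict(orient="records"),
    }
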