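"""End-to-end study runner: simulate -> track -> chunk -> featurize -> train -> report.

This is the programmatic equivalent of the CLI's ``run-all``: generate a
synthetic study, extract displacement traces, window them into chunks,
compute and filter features on the training subjects only, then train and
evaluate one model per label scheme on the held-out subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import SCHEMES, TrainedModel, apply_scheme, tune_and_train
from .evaluate import EvaluationReport, evaluate_model
from .features import SelectionResult, extract_features, select_features
from .pipeline_io import RunConfig, stage_seed
from .preprocess import chunk_trace
from .simulate import StudyDesign, default_study_design, iter_study_recordings
from .vibrometry import DisplacementTrace, extract_displacement


def trace_from_ground_truth(positions: np.ndarray, fps: float) -> DisplacementTrace:
    """Wrap a known displacement series as a trace (the simulator's fast mode)."""
    pos = np.asarray(positions, dtype=float)
    cum = pos - pos[0]
    pair = np.diff(cum, axis=0)
    return DisplacementTrace(
        fps=fps, pair_shift=pair, cum_position=cum, peak_height=np.ones(len(pair))
    )


@dataclass
class SchemeResult:
    selection: SelectionResult
    model: TrainedModel
    report: EvaluationReport


@dataclass
class StudyResult:
    feature_table: pd.DataFrame
    train_table: pd.DataFrame
    validation_table: pd.DataFrame
    by_scheme: dict[str, SchemeResult] = field(default_factory=dict)

    def accuracies(self) -> dict[str, float]:
        return {
            name: res.report.metrics["accuracy"] for name, res in self.by_scheme.items()
        }


def build_feature_table(config: RunConfig, design: StudyDesign | None = None) -> pd.DataFrame:
    """Simulate the study and produce the chunk-by-feature table."""
    if design is None:
        design = default_study_design(config.n_subjects)
    chunks = []
    for meta, rec in iter_study_recordings(
        design,
        recordings_per_state=config.recordings_per_state,
        duration_s=config.duration_s,
        fps=config.fps,
        seed=stage_seed(config.seed, "simulate"),
        optics=config.optics,
        render=config.render,
    ):
        if config.render:
            trace = extract_displacement(rec, subpixel=config.subpixel)
        else:
            trace = trace_from_ground_truth(rec, config.fps)
        chunks.extend(
            chunk_trace(
                trace,
                subject_id=meta["subject_id"],
                recording_id=meta["recording_id"],
                time_label=meta["time_label"],
                length=config.chunk_length,
                stride=config.chunk_stride,
            )
        )
    return extract_features(chunks, fps=config.fps)


def run_schemes(
    table: pd.DataFrame,
    config: RunConfig,
    scheme_names: tuple[str, ...] | None = None,
) -> StudyResult:
    """Split by subject, then select features, train, and evaluate per scheme.

    Feature selection runs on training rows only and is recomputed per
    scheme (the labels it tests against change with the merging).
    """
    scheme_names = scheme_names or config.schemes
    val_mask = table["subject_id"] == config.validation_subject
    if not val_mask.any():
        raise ValueError(
            f"validation subject {config.validation_subject!r} not in table"
        )
    train = table[~val_mask].reset_index(drop=True)
    val = table[val_mask].reset_index(drop=True)
    result = StudyResult(feature_table=table, train_table=train, validation_table=val)
    for name in scheme_names:
        if name not in SCHEMES:
            raise ValueError(f"unknown scheme {name!r}; valid: {sorted(SCHEMES)}")
        scheme = SCHEMES[name]
        train_merged = train.copy()
        train_merged["time_label"] = apply_scheme(train["time_label"].tolist(), scheme)
        selection = select_features(
            train_merged, target="time_label", alpha=config.alpha,
            correction=config.correction,
        )
        model = tune_and_train(
            train,
            val,
            scheme,
            trials=config.trials,
            seed=stage_seed(config.seed, f"train_{name}"),
            selection=selection,
        )
        report = evaluate_model(
            model,
            val,
            provenance={
                "config_hash": config.config_hash(),
                "seed": config.seed,
                "scheme": name,
                "n_train": len(train),
                "n_validation": len(val),
            },
        )
        result.by_scheme[name] = SchemeResult(selection=selection, model=model, report=report)
    return result


def run_study(config: RunConfig, design: StudyDesign | None = None) -> StudyResult:
    """The full pipeline for one configuration."""
    table = build_feature_table(config, design)
    return run_schemes(table, config)
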