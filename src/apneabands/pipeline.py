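"""End-to-end orchestration: config, feature extraction, classification.

The pipeline is a thin composition of the library modules — for a fixed
seed its outputs are exactly what calling the module operations directly
would produce. Every run writes its resolved configuration and a manifest
next to its outputs for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classify import (CVResult, SplitSpec, cross_validate, evaluate,
                       make_svm, split_dataset, train_rf, train_svm)
from .features import (FEATURE_COLUMNS, aggregate_recording, feature_vector,
                       features_table)
from .io import Recording, read_labels, read_recording, segment_epochs
from .preprocess import NotchSpec, apply_notch
from .wpd import extract_band_coefficients

logger = logging.getLogger("apneabands")

__all__ = ["PipelineConfig", "extract_features", "run_extract", "run_classify"]


@dataclass
class PipelineConfig:
    """Everything a run needs; fully serializable to YAML."""

    input_dir: str = "."
    labels_csv: str = "labels.csv"
    out_dir: str = "out"
    channel: str = "C3-A2"
    epoch_seconds: float = 30.0
    notch_enabled: bool = True
    notch_f0: float = 50.0
    notch_q: float = 30.0
    wavelet: str = "db8"
    level: int | str = "auto"
    boundary_mode: str = "periodization"
    aggregation: str = "per-recording"  # or "per-epoch"
    model: str = "svm"                  # or "rf"
    kernel: str = "poly2"
    trees: int = 150
    train_fraction: float = 0.9
    cv_folds: int = 10
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


def _recording_features(rec: Recording, config: PipelineConfig) -> list:
    epochs = segment_epochs(rec, config.epoch_seconds)
    if not epochs:
        raise ValueError(f"recording {rec.subject_id} is shorter than one epoch")
    if config.notch_enabled:
        spec = NotchSpec(f0=config.notch_f0, q=config.notch_q, fs=rec.fs)
        epochs = [apply_notch(e, spec) for e in epochs]
    vectors = []
    for e in epochs:
        bc = extract_band_coefficients(
            e, wavelet=config.wavelet, level=config.level,
            mode=config.boundary_mode)
        vectors.append(feature_vector(bc, rec.subject_id, rec.label))
    return vectors


def extract_features(recordings: list[Recording],
                     config: PipelineConfig) -> pd.DataFrame:
    """Feature table for in-memory recordings (no file I/O)."""
    rows = []
    for rec in recordings:
        vectors = _recording_features(rec, config)
        if config.aggregation == "per-recording":
            rows.append(aggregate_recording(vectors))
        else:
            rows.extend(vectors)
    return features_table(rows)


def run_extract(config: PipelineConfig) -> Path:
    """Extract features from every EDF under ``input_dir``; write CSV + manifest.

    Recordings that fail (e.g. missing channel) are reported together at the
    end; features of the readable recordings are still written, to a
    ``partial`` subdirectory when any recording failed.
    """
    in_dir = Path(config.input_dir)
    labels = read_labels(config.labels_csv).set_index("subject_id")["label"]
    edf_paths = sorted(in_dir.glob("*.edf"))
    if not edf_paths:
        raise FileNotFoundError(f"no .edf files under {in_dir}")
    rows, failures = [], []
    for path in edf_paths:
        sid = path.stem
        try:
            rec = read_recording(path, config.channel, subject_id=sid,
                                 label=labels.get(sid))
            vectors = _recording_features(rec, config)
        except Exception as exc:
            failures.append((sid, str(exc)))
            continue
        if config.aggregation == "per-recording":
            rows.append(aggregate_recording(vectors))
        else:
            rows.extend(vectors)
        logger.info("extracted %s: %d epoch(s)", sid, len(vectors))

    out_dir = Path(config.out_dir)
    if failures:
        out_dir = out_dir / "partial"
    out_dir.mkdir(parents=True, exist_ok=True)
    table = features_table(rows)
    csv_path = out_dir / "features.csv"
    table.to_csv(csv_path, index=False, float_format="%.12g")
    config.to_yaml(out_dir / "config.yaml")
    manifest = {
        "config_digest": config.digest(),
        "apneabands_version": __version__,
        "seed": config.seed,
        "n_recordings": len(edf_paths),
        "n_rows": len(table),
        "n_failed": len(failures),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    if failures:
        detail = "; ".join(f"{sid}: {msg}" for sid, msg in failures)
        raise RuntimeError(
            f"{len(failures)} recording(s) failed ({detail}); partial results "
            f"written to {out_dir}"
        )
    logger.info("wrote %d feature rows to %s", len(table), csv_path)
    return csv_path


def _model_factory(config: PipelineConfig):
    from sklearn.ensemble import RandomForestClassifier

    if config.model == "svm":
        return lambda: make_svm(config.kernel)
    if config.model == "rf":
        return lambda: RandomForestClassifier(
            n_estimators=config.trees, oob_score=True, bootstrap=True,
            max_samples=2 / 3, random_state=config.seed)
    raise ValueError(f"unknown model {config.model!r}")


def run_classify(config: PipelineConfig,
                 feature_table: str | Path | pd.DataFrame) -> dict:
    """Hold-out (90/10) and k-fold CV evaluation of the configured model.

    Returns the metrics dictionary and writes it as ``metrics.json`` under
    ``out_dir``. Both evaluation routes are always reported.
    """
    if isinstance(feature_table, (str, Path)):
        feature_table = pd.read_csv(feature_table)
    missing = [c for c in ("subject_id", "label", *FEATURE_COLUMNS)
               if c not in feature_table.columns]
    if missing:
        raise ValueError(f"feature table is missing columns: {missing}")

    train, test = split_dataset(
        feature_table,
        SplitSpec(train_fraction=config.train_fraction, seed=config.seed))
    oob_error = None
    if config.model == "svm":
        model = train_svm(train, kernel=config.kernel)
    else:
        model, oob_error = train_rf(train, n_trees=config.trees, seed=config.seed)
    counts, holdout = evaluate(model, test)
    cv: CVResult = cross_validate(
        feature_table, _model_factory(config), k=config.cv_folds, seed=config.seed)

    result = {
        "model": config.model,
        "kernel": config.kernel if config.model == "svm" else None,
        "seed": config.seed,
        "holdout": {
            **holdout.as_dict(),
            "confusion": {"tp": counts.tp, "tn": counts.tn,
                          "fp": counts.fp, "fn": counts.fn},
            "n_train": len(train), "n_test": len(test),
        },
        "cv": {
            "k": config.cv_folds,
            "mean": cv.mean.as_dict(),
            "per_fold": [m.as_dict() for m in cv.per_fold],
        },
    }
    if oob_error is not None:
        result["oob_error"] = oob_error
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "metrics.json").write_text(json.dumps(result, indent=2, sort_keys=True))
    logger.info("holdout accuracy %.3f; %d-fold CV mean accuracy %.3f",
                holdout.accuracy, config.cv_folds, cv.mean.accuracy)
    return result
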