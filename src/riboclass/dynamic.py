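"""Class-incremental dataset augmentation and retraining.

New riboswitch families keep being discovered, so a classifier over a fixed
set of ligand classes goes stale.  The update mechanism here appends new
labeled families to an existing dataset — keeping every existing class index
unchanged — and retrains a fresh model on the augmented dataset, recording
before/after metrics in an update manifest.  Retraining is from scratch by
default (a warm start from the previous deep model's weights is available
but off by default); families below a minimum-size floor (default 100
sequences, the same floor used to curate the original collection) are
rejected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from .evaluation import EvaluationReport, evaluate_classifier
from .models import (
    ModelSpec,
    SplitIndices,
    TrainedClassifier,
    save_model,
    stratified_split,
    train_on_dataset,
)
from .sequence_io import RiboswitchDataset, read_fasta

__all__ = [
    "DEFAULT_MIN_CLASS_SIZE",
    "UpdateManifest",
    "augment_dataset",
    "update_and_retrain",
]

DEFAULT_MIN_CLASS_SIZE = 100


@dataclass
class UpdateManifest:
    """Record of one class-incremental update."""

    prior_classes: list[str]
    added_classes: list[str]
    resulting_classes: list[str]
    retrain_spec: dict[str, Any]
    metrics_before: dict[str, float] | None = None
    metrics_after: dict[str, float] | None = None
    class_sizes: dict[str, int] = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1))


def augment_dataset(
    dataset: RiboswitchDataset,
    new_class_fastas: Mapping[str, str | Path],
    min_class_size: int = DEFAULT_MIN_CLASS_SIZE,
) -> RiboswitchDataset:
    """Append new labeled families to a dataset, preserving class order.

    ``new_class_fastas`` maps each new family label to its FASTA file.  The
    resulting class manifest is the prior manifest followed by the new labels
    in mapping order, so predictions for existing classes keep their indices.
    An empty mapping returns a dataset identical to the input.

    Raises on a label that already exists and rejects any family smaller
    than ``min_class_size``.
    """
    records = list(dataset.records)
    class_names = list(dataset.class_names)
    seen_ids = {r.id for r in records}
    for label, fasta in new_class_fastas.items():
        if label in class_names:
            raise ValueError(f"class {label!r} already exists in the dataset")
        new_records = read_fasta(fasta, label=label)
        if len(new_records) < min_class_size:
            raise ValueError(
                f"class {label!r} has {len(new_records)} sequences, below the "
                f"minimum class size of {min_class_size}"
            )
        for rec in new_records:
            # incoming FASTA ids may collide with existing records; qualify
            # them with the new class label
            rid = rec.id if rec.id not in seen_ids else f"{label}:{rec.id}"
            seen_ids.add(rid)
            records.append(
                rec if rid == rec.id else type(rec)(rid, rec.sequence, rec.label)
            )
        class_names.append(label)
    return RiboswitchDataset(records, class_names=class_names)


def _summary(report: EvaluationReport) -> dict[str, float]:
    return {k: v for k, v in report.summary_row().items() if v is not None}


def _evaluate_on_split(
    clf: TrainedClassifier, dataset: RiboswitchDataset, split: SplitIndices
) -> EvaluationReport:
    test = dataset.subset(split.test)
    proba = clf.predict_proba_sequences(test.sequences)
    return evaluate_classifier(proba, test.labels, clf.class_names)


def update_and_retrain(
    dataset: RiboswitchDataset,
    new_class_fastas: Mapping[str, str | Path],
    model_family: str,
    config: Mapping[str, Any] | None = None,
    seed: int = 0,
    min_class_size: int = DEFAULT_MIN_CLASS_SIZE,
    previous_model: TrainedClassifier | None = None,
    out_dir: str | Path | None = None,
    **train_kwargs,
) -> tuple[TrainedClassifier, UpdateManifest]:
    """Augment the dataset and rerun the full pipeline on it.

    Split -> featurize/encode -> train -> evaluate, on the augmented
    dataset.  If ``previous_model`` is given, its held-out metrics on the
    *old* classes are recorded as the before-update baseline.  Artifacts, if
    ``out_dir`` is given, go to a fresh directory — nothing existing is
    overwritten.
    """
    augmented = augment_dataset(
        dataset, new_class_fastas, min_class_size=min_class_size
    )
    spec = ModelSpec(model_family, dict(config or {}), random_seed=seed)
    metrics_before = None
    if previous_model is not None:
        old_split = stratified_split(dataset, seed=seed)
        metrics_before = _summary(
            _evaluate_on_split(previous_model, dataset, old_split)
        )
    clf, split = train_on_dataset(augmented, spec, seed=seed, **train_kwargs)
    report = _evaluate_on_split(clf, augmented, split)
    manifest = UpdateManifest(
        prior_classes=list(dataset.class_names),
        added_classes=list(new_class_fastas),
        resulting_classes=list(augmented.class_names),
        retrain_spec={
            "family": spec.family,
            "hyperparameters": {
                k: list(v) if isinstance(v, tuple) else v
                for k, v in spec.hyperparameters.items()
            },
            "random_seed": spec.random_seed,
        },
        metrics_before=metrics_before,
        metrics_after=_summary(report),
        class_sizes=augmented.class_sizes,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        save_model(clf, out_dir / "model")
        manifest.save(out_dir / "update_manifest.json")
    return clf, manifest
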