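"""Training, tuning, persisting, and applying the riboswitch classifiers.

Eight classifier families are supported.  Six conventional ("base") models
consume the 20 standardized k-mer frequency features and are backed by
scikit-learn: decision tree, Gaussian naive Bayes, k-nearest neighbors,
AdaBoost, random forest, and the multi-layer perceptron.  Two deep models
read the integer-encoded sequence directly: a 1-D CNN (two convolutional
layers, max pooling, dropout, flatten, dense softmax) and a bidirectional
LSTM RNN (two bidirectional layers sandwiched by dropout), both built on the
package's numpy network engine (:mod:`riboclass.nn`).

All classifiers expose the same contract: ``predict_proba`` returns one row
per input summing to 1, ordered by the dataset's class manifest, and
``predict`` is its argmax.  A single pipeline seed fans out (via
``numpy.random.SeedSequence``) to the split, weight initialisation and
shuffling, so every run is reproducible.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import joblib
import numpy as np
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.tree import DecisionTreeClassifier

from . import nn
from .featurize import (
    DEFAULT_ENCODING_LENGTH,
    Standardizer,
    encode_sequences,
    kmer_feature_matrix,
)
from .sequence_io import RiboswitchDataset

__all__ = [
    "BASE_FAMILIES",
    "DEEP_FAMILIES",
    "ALL_FAMILIES",
    "ModelSpec",
    "TrainedClassifier",
    "SplitIndices",
    "SearchResult",
    "stratified_split",
    "grid_search_cv",
    "train_base",
    "build_cnn",
    "build_rnn",
    "architecture_summary",
    "train_deep",
    "train_on_dataset",
    "save_model",
    "load_model",
]

BASE_FAMILIES = (
    "decision_tree",
    "gaussian_nb",
    "knn",
    "adaboost",
    "random_forest",
    "mlp",
)
DEEP_FAMILIES = ("cnn", "rnn")
ALL_FAMILIES = BASE_FAMILIES + DEEP_FAMILIES

N_KMER_FEATURES = 20

_MODEL_FORMAT_VERSION = 1

# Legal hyperparameter names per family.
_LEGAL_HYPERPARAMS: dict[str, set[str]] = {
    "decision_tree": {
        "max_features",
        "min_samples_split",
        "min_samples_leaf",
        "max_depth",
        "criterion",
    },
    "gaussian_nb": {"priors", "var_smoothing"},
    "knn": {"n_neighbors", "leaf_size", "weights", "algorithm"},
    "adaboost": {"n_estimators", "learning_rate"},
    "random_forest": {"n_estimators", "max_depth", "criterion"},
    "mlp": {
        "activation",
        "solver",
        "alpha",
        "learning_rate",
        "learning_rate_init",
        "max_iter",
        "hidden_layer_sizes",
    },
    "cnn": {
        "filters",
        "kernel_size",
        "pool_size",
        "dropout",
        "learning_rate",
        "lr_halve_at",
        "epochs",
        "batch_size",
        "encoding_length",
    },
    "rnn": {
        "lstm_units",
        "n_bidirectional_layers",
        "dropout",
        "learning_rate",
        "lr_halve_at",
        "epochs",
        "batch_size",
        "encoding_length",
    },
}

# Defaults for the deep architectures (capacity is configuration, topology is
# fixed: 2 conv layers for the CNN, 2 bidirectional layers for the RNN).
_DEEP_DEFAULTS: dict[str, dict[str, Any]] = {
    "cnn": {
        "filters": (128, 64),
        "kernel_size": 5,
        "pool_size": 4,
        "dropout": 0.3,
        "learning_rate": 1e-3,
        "lr_halve_at": (),
        "epochs": 20,
        "batch_size": 64,
        "encoding_length": DEFAULT_ENCODING_LENGTH,
    },
    "rnn": {
        "lstm_units": 128,
        "n_bidirectional_layers": 2,
        "dropout": 0.2,
        "learning_rate": 1e-3,
        "lr_halve_at": (),
        "epochs": 30,
        "batch_size": 64,
        "encoding_length": DEFAULT_ENCODING_LENGTH,
    },
}


@dataclass(frozen=True)
class ModelSpec:
    """A classifier family with its hyperparameters and seed."""

    family: str
    hyperparameters: Mapping[str, Any] = field(default_factory=dict)
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ALL_FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r}; choose from {ALL_FAMILIES}"
            )
        illegal = set(self.hyperparameters) - _LEGAL_HYPERPARAMS[self.family]
        if illegal:
            raise ValueError(
                f"hyperparameters {sorted(illegal)} are not legal for family "
                f"{self.family!r}"
            )

    def resolved(self) -> dict[str, Any]:
        """Hyperparameters with family defaults filled in (deep families)."""
        out = dict(_DEEP_DEFAULTS.get(self.family, {}))
        out.update(self.hyperparameters)
        return out


def build_cnn(config: Mapping[str, Any] | None = None, seed: int = 0) -> ModelSpec:
    """A CNN spec: two 1-D conv layers -> max pool -> dropout -> softmax."""
    spec = ModelSpec("cnn", dict(config or {}), random_seed=seed)
    _validate_deep_config(spec)
    return spec


def build_rnn(config: Mapping[str, Any] | None = None, seed: int = 0) -> ModelSpec:
    """An RNN spec: two bidirectional LSTM layers sandwiched by dropout."""
    spec = ModelSpec("rnn", dict(config or {}), random_seed=seed)
    _validate_deep_config(spec)
    return spec


def _validate_deep_config(spec: ModelSpec) -> None:
    cfg = spec.resolved()
    positive = ["epochs", "batch_size", "encoding_length"]
    if spec.family == "cnn":
        if len(cfg["filters"]) != 2 or any(f < 1 for f in cfg["filters"]):
            raise ValueError("CNN needs two positive filter counts")
        if any(k < 1 for k in _kernel_pair(cfg["kernel_size"])):
            raise ValueError("kernel sizes must be positive")
        positive += ["pool_size"]
    else:
        if cfg["lstm_units"] < 1:
            raise ValueError("LSTM units must be positive")
        if cfg["n_bidirectional_layers"] != 2:
            raise ValueError("the RNN topology is fixed at 2 bidirectional layers")
    for name in positive:
        if cfg[name] < 1:
            raise ValueError(f"{name} must be positive, got {cfg[name]}")
    if not 0.0 <= cfg["dropout"] < 1.0:
        raise ValueError("dropout must be in [0, 1)")


def _kernel_pair(kernel_size) -> tuple[int, int]:
    """The CNN's two conv layers may share one kernel size or use a pair
    (e.g. a short motif-detecting kernel followed by a wide combining one)."""
    if isinstance(kernel_size, (tuple, list)):
        if len(kernel_size) != 2:
            raise ValueError("kernel_size pair must have two entries")
        return int(kernel_size[0]), int(kernel_size[1])
    return int(kernel_size), int(kernel_size)


def _build_network(spec: ModelSpec, n_classes: int, seed: int) -> nn.Sequential:
    cfg = spec.resolved()
    length = cfg["encoding_length"]
    if spec.family == "cnn":
        f1, f2 = cfg["filters"]
        k1, k2 = _kernel_pair(cfg["kernel_size"])
        conv_out = length - (k1 - 1) - (k2 - 1)
        pooled = conv_out // cfg["pool_size"]
        if pooled < 1:
            raise ValueError("encoding length too short for this CNN config")
        layers: list[nn.Layer] = [
            nn.OneHot(4),
            nn.Conv1D(4, f1, k1),
            nn.Conv1D(f1, f2, k2),
            nn.MaxPool1D(cfg["pool_size"]),
            nn.Dropout(cfg["dropout"]),
            nn.Flatten(),
            nn.Dense(pooled * f2, n_classes),
        ]
    else:
        # second bidirectional layer emits final states only (the flatten is
        # then trivial): a small readout that summarises the whole sequence
        # through the masked recurrence instead of a huge per-position dense
        u = cfg["lstm_units"]
        layers = [
            nn.OneHot(4),
            nn.Dropout(cfg["dropout"]),
            nn.BiLSTM(4, u),
            nn.Dropout(cfg["dropout"]),
            nn.BiLSTM(2 * u, u, return_sequences=False),
            nn.Dropout(cfg["dropout"]),
            nn.Flatten(),
            nn.Dense(2 * u, n_classes),
        ]
    return nn.Sequential(layers, seed=seed)


def architecture_summary(spec: ModelSpec, n_classes: int = 2) -> list[str]:
    """Human-readable layer list of a deep spec (used by ``--summary``)."""
    net = _build_network(spec, n_classes, seed=0)
    return [type(layer).__name__ for layer in net.layers]


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------


@dataclass
class SplitIndices:
    """Disjoint train / validation / test index sets covering the dataset."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray


def _allocate(n_per_class: dict[str, int], fraction: float) -> dict[str, int]:
    """Largest-remainder allocation: per-class counts within 1 of n*fraction."""
    exact = {c: n * fraction for c, n in n_per_class.items()}
    base = {c: int(np.floor(v)) for c, v in exact.items()}
    shortfall = int(round(sum(exact.values()))) - sum(base.values())
    by_remainder = sorted(exact, key=lambda c: exact[c] - base[c], reverse=True)
    for c in by_remainder[:shortfall]:
        base[c] += 1
    return base


def stratified_split(
    labels: Sequence[str] | RiboswitchDataset,
    test_fraction: float = 0.1,
    validation_fraction: float = 0.1,
    seed: int = 0,
) -> SplitIndices:
    """Class-stratified train/validation/test split.

    ``test_fraction`` is taken from the whole dataset; ``validation_fraction``
    is then taken from the remaining training part (the usual
    validation-flag semantics).  Per-class test counts deviate from the
    target fraction by at most one instance (largest-remainder rounding).
    Deterministic given ``seed``.
    """
    if isinstance(labels, RiboswitchDataset):
        labels = [r.label for r in labels]
    labels = np.asarray(labels)
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test fraction must be in (0, 1)")
    if not 0.0 <= validation_fraction < 1.0:
        raise ValueError("validation fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(labels, return_counts=True)
    singletons = [str(c) for c, n in zip(classes, counts) if n < 2]
    if singletons:
        raise ValueError(
            f"classes with a single member cannot be stratified: {singletons}"
        )
    n_test = _allocate(dict(zip(classes, counts)), test_fraction)
    train, val, test = [], [], []
    for cls in classes:
        idx = np.nonzero(labels == cls)[0]
        rng.shuffle(idx)
        k = n_test[str(cls)]
        test.extend(idx[:k])
        rest = idx[k:]
        kv = int(np.floor(len(rest) * validation_fraction + 0.5))
        val.extend(rest[:kv])
        train.extend(rest[kv:])
    return SplitIndices(
        train=np.sort(np.array(train, dtype=int)),
        validation=np.sort(np.array(val, dtype=int)),
        test=np.sort(np.array(test, dtype=int)),
    )


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------


def _make_base_estimator(spec: ModelSpec):
    hp = dict(spec.hyperparameters)
    seed = spec.random_seed
    if spec.family == "decision_tree":
        return DecisionTreeClassifier(random_state=seed, **hp)
    if spec.family == "gaussian_nb":
        return GaussianNB(**hp)
    if spec.family == "knn":
        return KNeighborsClassifier(**hp)
    if spec.family == "adaboost":
        return AdaBoostClassifier(random_state=seed, **hp)
    if spec.family == "random_forest":
        return RandomForestClassifier(random_state=seed, **hp)
    if spec.family == "mlp":
        hp.setdefault("max_iter", 500)
        return MLPClassifier(random_state=seed, **hp)
    raise ValueError(f"{spec.family!r} is not a base family")


@dataclass
class TrainedClassifier:
    """A fitted classifier bound to a fixed class manifest.

    ``kind`` is ``"kmer"`` for the conventional models (inputs: standardized
    20-feature vectors) and ``"sequence"`` for the deep models (inputs:
    integer-encoded sequences).  ``predict_proba_sequences`` accepts raw
    sanitized sequences and performs the featurization/encoding internally.
    """

    spec: ModelSpec
    class_names: list[str]
    kind: str  # "kmer" | "sequence"
    model: Any  # sklearn estimator or nn.Sequential
    standardizer: Standardizer | None = None
    training_history: dict[str, list[float]] | None = None

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def predict_proba(self, inputs: np.ndarray) -> np.ndarray:
        inputs = np.asarray(inputs)
        if self.kind == "kmer":
            if inputs.ndim != 2 or inputs.shape[1] != N_KMER_FEATURES:
                raise ValueError(
                    f"expected (n, {N_KMER_FEATURES}) k-mer features, got "
                    f"{inputs.shape}"
                )
            raw = self.model.predict_proba(inputs)
            # expand to manifest width if a class was absent at fit time
            proba = np.zeros((len(inputs), self.n_classes))
            for col, cls_idx in enumerate(self.model.classes_):
                proba[:, int(cls_idx)] = raw[:, col]
            return proba
        length = self.spec.resolved()["encoding_length"]
        if inputs.ndim != 2 or inputs.shape[1] != length:
            raise ValueError(
                f"expected (n, {length}) encoded sequences, got {inputs.shape}"
            )
        return self.model.predict_proba(inputs)

    def predict(self, inputs: np.ndarray) -> np.ndarray:
        proba = self.predict_proba(inputs)
        return np.asarray(self.class_names)[proba.argmax(axis=1)]

    def prepare_inputs(self, sequences: Sequence[str]) -> np.ndarray:
        """Featurize (and standardize) or encode raw sanitized sequences."""
        if self.kind == "kmer":
            feats = kmer_feature_matrix(sequences)
            if self.standardizer is not None:
                feats = self.standardizer.transform(feats)
            return feats
        return encode_sequences(
            sequences, length=self.spec.resolved()["encoding_length"]
        )

    def predict_proba_sequences(self, sequences: Sequence[str]) -> np.ndarray:
        return self.predict_proba(self.prepare_inputs(sequences))

    def predict_sequences(self, sequences: Sequence[str]) -> np.ndarray:
        proba = self.predict_proba_sequences(sequences)
        return np.asarray(self.class_names)[proba.argmax(axis=1)]


def _labels_to_indices(labels: Sequence[str], class_names: Sequence[str]) -> np.ndarray:
    index = {c: i for i, c in enumerate(class_names)}
    try:
        return np.array([index[l] for l in labels], dtype=int)
    except KeyError as exc:
        raise ValueError(f"label {exc.args[0]!r} not in the class manifest") from exc


def train_base(
    spec: ModelSpec,
    features: np.ndarray,
    labels: Sequence[str],
    class_names: Sequence[str],
    standardizer: Standardizer | None = None,
) -> TrainedClassifier:
    """Fit one conventional classifier on standardized k-mer features."""
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[1] != N_KMER_FEATURES:
        raise ValueError(
            f"base models take {N_KMER_FEATURES} features, got shape "
            f"{features.shape}"
        )
    y = _labels_to_indices(labels, class_names)
    est = _make_base_estimator(spec)
    est.fit(features, y)
    return TrainedClassifier(
        spec=spec,
        class_names=list(class_names),
        kind="kmer",
        model=est,
        standardizer=standardizer,
    )


def train_deep(
    spec: ModelSpec,
    encoded: np.ndarray,
    labels: Sequence[str],
    class_names: Sequence[str],
    validation_fraction: float = 0.1,
    epochs: int | None = None,
    early_stopping_patience: int | None = None,
    verbose: bool = False,
) -> TrainedClassifier:
    """Fit a deep classifier on integer-encoded sequences.

    A stratified ``validation_fraction`` of the training data is held out to
    track per-epoch validation loss/accuracy (and drive optional early
    stopping); the history is stored on the returned classifier.
    """
    if spec.family not in DEEP_FAMILIES:
        raise ValueError(f"{spec.family!r} is not a deep family")
    encoded = np.asarray(encoded)
    cfg = spec.resolved()
    if encoded.ndim != 2 or encoded.shape[1] != cfg["encoding_length"]:
        raise ValueError(
            f"encoded inputs must be (n, {cfg['encoding_length']}), got "
            f"{encoded.shape}"
        )
    if not 0.0 < validation_fraction < 1.0:
        raise ValueError("validation fraction must be in (0, 1)")
    y = _labels_to_indices(labels, class_names)
    seeds = np.random.SeedSequence(spec.random_seed).generate_state(2)
    split = stratified_split(
        list(np.asarray(labels)),
        test_fraction=validation_fraction,
        validation_fraction=0.0,
        seed=int(seeds[0] % 2**31),
    )
    tr, va = split.train, split.test  # "test" slice plays the validation role
    net = _build_network(spec, len(class_names), seed=int(seeds[1] % 2**31))
    net.fit(
        encoded[tr],
        y[tr],
        epochs=epochs if epochs is not None else cfg["epochs"],
        batch_size=cfg["batch_size"],
        lr=cfg["learning_rate"],
        validation_data=(encoded[va], y[va]),
        early_stopping_patience=early_stopping_patience,
        lr_halve_at=tuple(cfg.get("lr_halve_at", ())),
        verbose=verbose,
    )
    return TrainedClassifier(
        spec=spec,
        class_names=list(class_names),
        kind="sequence",
        model=net,
        training_history=net.history,
    )


def train_on_dataset(
    dataset: RiboswitchDataset,
    spec: ModelSpec,
    split: SplitIndices | None = None,
    seed: int = 0,
    **deep_kwargs,
) -> tuple[TrainedClassifier, SplitIndices]:
    """Split, featurize/encode, and fit one classifier on a labeled dataset.

    Convenience wrapper used by the CLI and the dynamic-update pipeline; the
    returned split allows held-out evaluation with
    :func:`riboclass.evaluation.evaluate_classifier`.
    """
    if split is None:
        split = stratified_split(dataset, seed=seed)
    train_idx = np.concatenate([split.train, split.validation])
    seqs = dataset.sequences
    labels = np.asarray(dataset.labels)
    if spec.family in BASE_FAMILIES:
        feats = kmer_feature_matrix(seqs)
        std = Standardizer.fit(feats[train_idx])
        clf = train_base(
            spec,
            std.transform(feats[train_idx]),
            labels[train_idx],
            dataset.class_names,
            standardizer=std,
        )
    else:
        encoded = encode_sequences(
            seqs, length=spec.resolved()["encoding_length"]
        )
        clf = train_deep(
            spec, encoded[train_idx], labels[train_idx], dataset.class_names,
            **deep_kwargs,
        )
    return clf, split


# ---------------------------------------------------------------------------
# grid search
# ---------------------------------------------------------------------------


@dataclass
class SearchResult:
    """Outcome of a combinatorial grid search."""

    results: list[dict[str, Any]]  # combination, mean_score, fold_scores/error
    best: ModelSpec
    best_score: float


def grid_search_cv(
    family: str,
    grid: Mapping[str, Sequence[Any]],
    features: np.ndarray,
    labels: Sequence[str],
    class_names: Sequence[str],
    folds: int = 10,
    seed: int = 0,
    deep_epochs: int | None = None,
) -> SearchResult:
    """Exhaustive grid search scored by stratified k-fold macro F-score.

    Every combination of the grid's Cartesian product is evaluated; a
    combination that fails to fit is recorded with its error and scored as
    worst rather than aborting the search.  Ties break to the first
    combination in deterministic grid order.  Macro-F is the selection
    metric: with heavy class skew it penalises overfitting to large classes.
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    if folds < 2:
        raise ValueError("need at least 2 folds")
    features = np.asarray(features)
    labels = np.asarray(labels)
    y = _labels_to_indices(labels, class_names)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    names = list(grid)
    results: list[dict[str, Any]] = []
    best_combo: dict[str, Any] | None = None
    best_score = -np.inf
    for values in itertools.product(*(grid[n] for n in names)):
        combo = dict(zip(names, values))
        fold_scores: list[float] = []
        error: str | None = None
        try:
            spec = ModelSpec(family, combo, random_seed=seed)
            for tr, va in skf.split(features, y):
                if family in BASE_FAMILIES:
                    clf = train_base(
                        spec, features[tr], labels[tr], class_names
                    )
                else:
                    clf = train_deep(
                        spec,
                        features[tr],
                        labels[tr],
                        class_names,
                        epochs=deep_epochs,
                    )
                pred = clf.predict(features[va])
                fold_scores.append(
                    float(f1_score(labels[va], pred, average="macro"))
                )
            mean_score = float(np.mean(fold_scores))
        except Exception as exc:  # noqa: BLE001 — record, score worst, move on
            error = f"{type(exc).__name__}: {exc}"
            mean_score = -np.inf
        results.append(
            {
                "combination": combo,
                "mean_score": mean_score,
                "fold_scores": fold_scores,
                "error": error,
            }
        )
        if mean_score > best_score:
            best_score = mean_score
            best_combo = combo
    if best_combo is None:
        raise RuntimeError("every grid combination failed to fit")
    return SearchResult(
        results=results,
        best=ModelSpec(family, best_combo, random_seed=seed),
        best_score=best_score,
    )


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def save_model(classifier: TrainedClassifier, path: str | Path) -> None:
    """Persist a trained classifier to a directory.

    Layout: ``manifest.json`` (format version, spec, class order, history),
    plus ``model.joblib`` for conventional models or ``weights.npz`` for the
    deep models; the standardizer is stored beside as ``standardizer.json``.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": _MODEL_FORMAT_VERSION,
        "family": classifier.spec.family,
        "hyperparameters": {
            k: list(v) if isinstance(v, tuple) else v
            for k, v in classifier.spec.hyperparameters.items()
        },
        "random_seed": classifier.spec.random_seed,
        "class_names": classifier.class_names,
        "kind": classifier.kind,
        "training_history": classifier.training_history,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
    if classifier.kind == "kmer":
        joblib.dump(classifier.model, path / "model.joblib")
        if classifier.standardizer is not None:
            classifier.standardizer.save(path / "standardizer.json")
    else:
        np.savez(path / "weights.npz", **classifier.model.get_weights())


def load_model(path: str | Path) -> TrainedClassifier:
    """Load a classifier saved by :func:`save_model`.

    Raises a clear error on a missing/corrupted file or a format-version
    mismatch instead of returning silent garbage.
    """
    path = Path(path)
    manifest_file = path / "manifest.json"
    if not manifest_file.exists():
        raise FileNotFoundError(f"{path} does not contain a model manifest")
    try:
        manifest = json.loads(manifest_file.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{manifest_file}: corrupted model manifest") from exc
    version = manifest.get("format_version")
    if version != _MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model format version {version} is not supported "
            f"(expected {_MODEL_FORMAT_VERSION})"
        )
    hp = {
        k: tuple(v) if isinstance(v, list) else v
        for k, v in manifest["hyperparameters"].items()
    }
    spec = ModelSpec(manifest["family"], hp, random_seed=manifest["random_seed"])
    class_names = list(manifest["class_names"])
    if manifest["kind"] == "kmer":
        try:
            est = joblib.load(path / "model.joblib")
        except Exception as exc:
            raise ValueError(f"{path}: corrupted model file") from exc
        std_path = path / "standardizer.json"
        std = Standardizer.load(std_path) if std_path.exists() else None
        return TrainedClassifier(
            spec=spec,
            class_names=class_names,
            kind="kmer",
            model=est,
            standardizer=std,
        )
    try:
        with np.load(path / "weights.npz") as archive:
            weights = {k: archive[k] for k in archive.files}
    except Exception as exc:
        raise ValueError(f"{path}: corrupted weights file") from exc
    net = _build_network(spec, len(class_names), seed=0)
    net.set_weights(weights)
    return TrainedClassifier(
        spec=spec,
        class_names=class_names,
        kind="sequence",
        model=net,
        training_history=manifest.get("training_history"),
    )
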