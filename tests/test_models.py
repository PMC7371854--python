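import numpy as np
import pytest

from riboclass.evaluation import evaluate_classifier
from riboclass.featurize import Standardizer, encode_sequences, kmer_feature_matrix
from riboclass.models import (
    ModelSpec,
    architecture_summary,
    build_cnn,
    build_rnn,
    grid_search_cv,
    load_model,
    save_model,
    stratified_split,
    train_base,
    train_deep,
    train_on_dataset,
)
from riboclass.synthetic_data import SyntheticSpec, generate_dataset

# small deep configs keep unit-test fits to seconds
CNN_SMALL = {
    "filters": (16, 16),
    "kernel_size": 5,
    "pool_size": 52,  # covers the conv output: global max pooling
    "dropout": 0.2,
    "epochs": 10,
    "learning_rate": 2e-3,
    "encoding_length": 60,
}
RNN_SMALL = {
    "lstm_units": 8,
    "dropout": 0.1,
    "epochs": 10,
    "learning_rate": 3e-3,
    "encoding_length": 60,
}


class TestModelSpec:
    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="unknown family"):
            ModelSpec("svm")

    def test_illegal_hyperparameter_rejected(self):
        with pytest.raises(ValueError, match="not legal"):
            ModelSpec("knn", {"max_depth": 3})

    def test_deep_builders_validate(self):
        with pytest.raises(ValueError):
            build_cnn({"filters": (0, 8)})
        with pytest.raises(ValueError):
            build_rnn({"lstm_units": -1})
        with pytest.raises(ValueError):
            build_rnn({"n_bidirectional_layers": 3})

    def test_architecture_topology(self):
        cnn_layers = architecture_summary(build_cnn(), n_classes=5)
        assert cnn_layers.count("Conv1D") == 2
        rnn_layers = architecture_summary(build_rnn(), n_classes=5)
        assert rnn_layers.count("BiLSTM") == 2
        assert rnn_layers.count("Dropout") >= 2


class TestStratifiedSplit:
    def test_divisible_case_is_exact(self):
        labels = np.repeat([f"c{i}" for i in range(10)], 100)
        split = stratified_split(labels, test_fraction=0.1, seed=0)
        test_labels = labels[split.test]
        for c in np.unique(labels):
            assert (test_labels == c).sum() == 10

    def test_uneven_classes_round_within_one(self):
        labels = np.array(["a"] * 100 + ["b"] * 50)
        split = stratified_split(labels, test_fraction=0.1, seed=0)
        test_labels = labels[split.test]
        assert (test_labels == "a").sum() == 10
        assert (test_labels == "b").sum() == 5

    def test_deterministic_given_seed(self):
        labels = np.repeat(["x", "y", "z"], 30)
        a = stratified_split(labels, seed=5)
        b = stratified_split(labels, seed=5)
        np.testing.assert_array_equal(a.test, b.test)
        np.testing.assert_array_equal(a.train, b.train)

    def test_singleton_class_error_names_class(self):
        labels = np.array(["a", "a", "lonely"])
        with pytest.raises(ValueError, match="lonely"):
            stratified_split(labels)

    def test_partition_covers_dataset(self):
        labels = np.repeat(["a", "b"], 25)
        s = stratified_split(labels, 0.2, 0.1, seed=1)
        combined = np.concatenate([s.train, s.validation, s.test])
        assert sorted(combined) == list(range(50))

    def test_deviation_at_most_one_over_random_class_sizes(self, rng):
        """Per-class test counts stay within one instance of the 10% target
        across many random class-size vectors."""
        for _ in range(100):
            sizes = rng.integers(2, 80, size=int(rng.integers(2, 12)))
            labels = np.concatenate(
                [np.repeat(f"c{i}", n) for i, n in enumerate(sizes)]
            )
            split = stratified_split(labels, test_fraction=0.1, seed=0)
            test_labels = labels[split.test]
            for i, n in enumerate(sizes):
                got = (test_labels == f"c{i}").sum()
                assert abs(got - n * 0.1) <= 1


def _separable_features(rng, n=100):
    """Two classes split cleanly along the first feature."""
    x = rng.normal(size=(n, 20)) * 0.1
    y = np.array(["pos"] * (n // 2) + ["neg"] * (n - n // 2))
    x[: n // 2, 0] += 3.0
    return x, y


class TestBaseModels:
    def test_decision_tree_fits_separable_data(self, rng):
        x, y = _separable_features(rng)
        clf = train_base(ModelSpec("decision_tree"), x, y, ["pos", "neg"])
        assert (clf.predict(x) == y).mean() == 1.0

    def test_gaussian_nb_on_uninformative_features(self, rng):
        # identical feature distribution for both classes: accuracy falls to
        # the majority-class rate
        x = np.zeros((90, 20))
        y = np.array(["a"] * 60 + ["b"] * 30)
        clf = train_base(ModelSpec("gaussian_nb"), x, y, ["a", "b"])
        assert (clf.predict(x) == "a").all()

    def test_refit_same_seed_identical(self, rng):
        x, y = _separable_features(rng, n=60)
        preds = []
        for _ in range(2):
            clf = train_base(
                ModelSpec("random_forest", {"n_estimators": 10}, random_seed=3),
                x,
                y,
                ["pos", "neg"],
            )
            preds.append(clf.predict_proba(x))
        np.testing.assert_array_equal(preds[0], preds[1])

    def test_wrong_feature_width_rejected(self, rng):
        with pytest.raises(ValueError, match="20"):
            train_base(
                ModelSpec("knn"), rng.normal(size=(10, 5)), ["a", "b"] * 5, ["a", "b"]
            )

    def test_proba_rows_sum_to_one_and_argmax_consistent(self, rng):
        x, y = _separable_features(rng)
        clf = train_base(ModelSpec("mlp", {"max_iter": 200}), x, y, ["pos", "neg"])
        proba = clf.predict_proba(x)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        labels = np.asarray(clf.class_names)[proba.argmax(axis=1)]
        np.testing.assert_array_equal(labels, clf.predict(x))


class TestGridSearch:
    def test_product_of_grid_evaluated(self, rng):
        x, y = _separable_features(rng, n=60)
        result = grid_search_cv(
            "decision_tree",
            {"max_depth": [1, 3], "min_samples_leaf": [1, 2]},
            x,
            y,
            ["pos", "neg"],
            folds=3,
        )
        assert len(result.results) == 4

    def test_single_combination_is_best(self, rng):
        x, y = _separable_features(rng, n=60)
        result = grid_search_cv(
            "knn", {"n_neighbors": [3]}, x, y, ["pos", "neg"], folds=3
        )
        assert result.best.hyperparameters == {"n_neighbors": 3}

    def test_known_best_configuration_selected(self, rng):
        """A planted case where only a deep-enough tree can separate:
        class = XOR of two binary features needs depth 2, so max_depth=2
        must beat max_depth=1."""
        n = 200
        a = rng.integers(0, 2, n)
        b = rng.integers(0, 2, n)
        x = np.zeros((n, 20))
        x[:, 0] = a
        x[:, 1] = b
        y = np.where(a ^ b, "odd", "even")
        result = grid_search_cv(
            "decision_tree",
            {"max_depth": [1, 2]},
            x,
            y,
            ["even", "odd"],
            folds=4,
        )
        assert result.best.hyperparameters["max_depth"] == 2

    def test_failing_combination_recorded_not_fatal(self, rng):
        x, y = _separable_features(rng, n=60)
        result = grid_search_cv(
            "adaboost",
            {"learning_rate": [-1.0, 0.5], "n_estimators": [5]},
            x,
            y,
            ["pos", "neg"],
            folds=3,
        )
        failed = [r for r in result.results if r["error"] is not None]
        assert len(failed) == 1
        assert result.best.hyperparameters["learning_rate"] == 0.5

    def test_empty_grid_rejected(self, rng):
        x, y = _separable_features(rng, n=40)
        with pytest.raises(ValueError):
            grid_search_cv("knn", {}, x, y, ["pos", "neg"])


class TestDeepModels:
    def test_output_width_and_softmax(self, small_generated, rng):
        ds = small_generated.dataset
        encoded = encode_sequences(ds.sequences, 60)
        labels = np.asarray(ds.labels)
        clf = train_deep(
            ModelSpec("cnn", CNN_SMALL, random_seed=1),
            encoded,
            labels,
            ds.class_names,
            epochs=2,
        )
        proba = clf.predict_proba(encoded[:10])
        assert proba.shape == (10, 4)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-5)

    def test_history_matches_epochs_run(self, small_generated):
        ds = small_generated.dataset
        encoded = encode_sequences(ds.sequences, 60)
        clf = train_deep(
            ModelSpec("rnn", RNN_SMALL, random_seed=1),
            encoded,
            np.asarray(ds.labels),
            ds.class_names,
            epochs=3,
        )
        assert len(clf.training_history["loss"]) == 3
        assert len(clf.training_history["val_loss"]) == 3

    def test_training_reduces_loss_on_planted_motifs(self, small_generated):
        ds = small_generated.dataset
        encoded = encode_sequences(ds.sequences, 60)
        clf = train_deep(
            ModelSpec("cnn", CNN_SMALL, random_seed=1),
            encoded,
            np.asarray(ds.labels),
            ds.class_names,
        )
        history = clf.training_history
        assert history["loss"][-1] < history["loss"][0]

    def test_cnn_learns_planted_motifs(self, small_generated):
        """Strongly planted distinct motifs are learnable to >= 0.9
        validation accuracy within a handful of epochs."""
        ds = small_generated.dataset
        encoded = encode_sequences(ds.sequences, 60)
        clf = train_deep(
            ModelSpec("cnn", CNN_SMALL, random_seed=1),
            encoded,
            np.asarray(ds.labels),
            ds.class_names,
            epochs=15,
        )
        assert clf.training_history["val_accuracy"][-1] >= 0.9

    def test_bad_validation_fraction_rejected(self, small_generated):
        ds = small_generated.dataset
        encoded = encode_sequences(ds.sequences, 60)
        with pytest.raises(ValueError):
            train_deep(
                ModelSpec("rnn", RNN_SMALL),
                encoded,
                np.asarray(ds.labels),
                ds.class_names,
                validation_fraction=1.5,
            )

    def test_wrong_encoding_width_rejected(self, small_generated):
        ds = small_generated.dataset
        encoded = encode_sequences(ds.sequences, 80)
        with pytest.raises(ValueError, match="60"):
            train_deep(
                ModelSpec("cnn", CNN_SMALL),
                encoded,
                np.asarray(ds.labels),
                ds.class_names,
            )


class TestPersistence:
    def test_base_model_round_trip(self, tmp_path, rng):
        x, y = _separable_features(rng, n=60)
        std = Standardizer.fit(x)
        clf = train_base(
            ModelSpec("random_forest", {"n_estimators": 8}, random_seed=0),
            std.transform(x),
            y,
            ["pos", "neg"],
            standardizer=std,
        )
        save_model(clf, tmp_path / "m")
        back = load_model(tmp_path / "m")
        probes = std.transform(rng.normal(size=(10, 20)))
        np.testing.assert_allclose(
            clf.predict_proba(probes), back.predict_proba(probes)
        )
        assert back.class_names == clf.class_names
        assert back.standardizer is not None

    def test_deep_model_round_trip(self, tmp_path, small_generated):
        ds = small_generated.dataset
        encoded = encode_sequences(ds.sequences, 60)
        clf = train_deep(
            ModelSpec("rnn", RNN_SMALL, random_seed=2),
            encoded,
            np.asarray(ds.labels),
            ds.class_names,
            epochs=2,
        )
        save_model(clf, tmp_path / "m")
        back = load_model(tmp_path / "m")
        np.testing.assert_allclose(
            clf.predict_proba(encoded[:10]),
            back.predict_proba(encoded[:10]),
            rtol=1e-6,
        )
        assert back.class_names == clf.class_names
        assert back.training_history == clf.training_history

    def test_corrupted_model_errors(self, tmp_path):
        d = tmp_path / "m"
        d.mkdir()
        (d / "manifest.json").write_text("{not json")
        with pytest.raises(ValueError, match="corrupted"):
            load_model(d)

    def test_missing_manifest_errors(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_model(tmp_path)

    def test_version_mismatch_errors(self, tmp_path):
        d = tmp_path / "m"
        d.mkdir()
        (d / "manifest.json").write_text('{"format_version": 99}')
        with pytest.raises(ValueError, match="version"):
            load_model(d)


class TestPipelineGuards:
    def test_separable_two_class_data_learned_by_base_and_deep(self):
        """Both model tiers reach >= 0.95 held-out accuracy on cleanly
        separated synthetic families."""
        gen = generate_dataset(
            SyntheticSpec(
                n_classes=2,
                n_per_class=100,
                length_range=(50, 60),
                motif_length=14,
                motif_mutation_rate=0.0,
                background_composition=np.array(
                    [[0.40, 0.10, 0.40, 0.10], [0.10, 0.40, 0.10, 0.40]]
                ),
                seed=13,
            )
        )
        ds = gen.dataset
        split = stratified_split(ds, seed=1)
        test = ds.subset(split.test)
        for spec in (
            ModelSpec("mlp", {"max_iter": 400}, random_seed=1),
            ModelSpec("cnn", CNN_SMALL, random_seed=1),
        ):
            clf, _ = train_on_dataset(ds, spec, split=split, seed=1)
            rep = evaluate_classifier(
                clf.predict_proba_sequences(test.sequences),
                test.labels,
                clf.class_names,
            )
            assert rep.accuracy >= 0.95, spec.family

    def test_permuted_labels_score_at_chance(self, small_generated, rng):
        """With labels randomly permuted no model should beat the 1/k
        baseline by more than noise — the overfitting guard."""
        ds = small_generated.dataset
        feats = kmer_feature_matrix(ds.sequences)
        labels = rng.permutation(np.asarray(ds.labels))
        split = stratified_split(list(labels), seed=2)
        std = Standardizer.fit(feats[split.train])
        for family in ("decision_tree", "gaussian_nb", "mlp"):
            clf = train_base(
                ModelSpec(family, random_seed=2),
                std.transform(feats[split.train]),
                labels[split.train],
                ds.class_names,
                standardizer=std,
            )
            rep = evaluate_classifier(
                clf.predict_proba(std.transform(feats[split.test])),
                labels[split.test],
                ds.class_names,
            )
            assert rep.macro_f < 0.25 + 0.1 + 0.1, family  # 1/4 chance + slack
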