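"""Classifier: determinism, resume semantics, metrics, and the labeling loop."""

import numpy as np
import pytest

import pixikit as pk
from pixikit.classifier import (
    ClassifierConfig,
    build_model,
    evaluate,
    fit,
    hitl_round,
    predict,
    split_train_val,
)
from pixikit.errors import ValidationError
from pixikit.fixtures import generate_class_dataset
from pixikit.project import IMAGE_KIND


def small_config(**kw) -> ClassifierConfig:
    base = dict(epochs=2, seed=7, input_extent=(32, 32, 1))
    base.update(kw)
    return ClassifierConfig(**base)


def weights_checksum(state) -> list:
    return [arr.copy() for _, _, _, arr in state.network.named_params()]


class TestBuildModel:
    def test_output_layer_size_matches_classes(self):
        state = build_model(small_config(input_extent=(28, 28, 1)), 10)
        head = state.network.layers[-1]
        assert head.params["W"].shape[1] == 10

    def test_transfer_head_freezes_backbone(self):
        state = build_model(small_config(architecture="transfer_head"), 3)
        trainable = [l.name for l in state.network.layers if l.params and l.trainable]
        frozen = [l.name for l in state.network.layers if l.params and not l.trainable]
        assert trainable == ["head"]
        assert set(frozen) == {"conv1", "conv2"}

    def test_same_seed_same_initial_weights(self):
        a = build_model(small_config(), 2)
        b = build_model(small_config(), 2)
        for x, y in zip(weights_checksum(a), weights_checksum(b)):
            assert (x == y).all()

    def test_too_few_classes(self):
        with pytest.raises(ValidationError):
            build_model(small_config(), 1)


class TestSplitTrainVal:
    def test_stratified_80_20_balanced(self):
        ids = [f"i{k}" for k in range(100)]
        labels = ["a"] * 50 + ["b"] * 50
        tr, va = split_train_val(ids, labels, 0.8, seed=1)
        assert len(tr) == 80 and len(va) == 20
        lab = dict(zip(ids, labels))
        counts = np.unique([lab[i] for i in tr], return_counts=True)[1]
        assert abs(counts[0] - counts[1]) <= 1

    def test_deterministic_for_fixed_seed(self):
        ids = list("abcdefghij")
        labels = ["x"] * 5 + ["y"] * 5
        assert split_train_val(ids, labels, 0.7, 3) == split_train_val(ids, labels, 0.7, 3)

    def test_degenerate_fraction_rejected(self):
        with pytest.raises(ValidationError):
            split_train_val(["a", "b"], ["x", "y"], 1.0, 0)

    def test_singleton_class_falls_back_with_warning(self):
        ids = list("abcde")
        labels = ["x", "x", "x", "x", "y"]
        with pytest.warns(UserWarning, match="single item"):
            split_train_val(ids, labels, 0.6, 0)


@pytest.fixture(scope="module")
def dataset():
    return generate_class_dataset(15, seed=21)


@pytest.fixture(scope="module")
def trained():
    ds = generate_class_dataset(10, seed=41)
    state = build_model(small_config(), 2, ds.class_names)
    fit(state, ds.items, ds.labels, 2)
    return state, ds


class TestFitResume:

    def test_resume_bookkeeping(self, dataset):
        state = build_model(small_config(), 2, dataset.class_names)
        fit(state, dataset.items, dataset.labels, 2)
        fit(state, dataset.items, dataset.labels, 3)
        assert state.epochs_completed == 5
        assert len(state.history) == 5

    def test_split_resume_is_bitwise_identical_to_one_run(self, dataset):
        a = build_model(small_config(), 2, dataset.class_names)
        fit(a, dataset.items, dataset.labels, 2)
        fit(a, dataset.items, dataset.labels, 2)
        b = build_model(small_config(), 2, dataset.class_names)
        fit(b, dataset.items, dataset.labels, 4)
        for x, y in zip(weights_checksum(a), weights_checksum(b)):
            assert (x == y).all()
        assert [h["train_loss"] for h in a.history] == [h["train_loss"] for h in b.history]

    def test_resume_does_not_reinitialize(self, dataset):
        state = build_model(small_config(), 2, dataset.class_names)
        fit(state, dataset.items, dataset.labels, 6)
        loss_at_stop = state.history[-1]["train_loss"]
        fit(state, dataset.items, dataset.labels, 1)
        resumed_loss = state.history[-1]["train_loss"]
        fresh = build_model(small_config(), 2, dataset.class_names)
        fit(fresh, dataset.items, dataset.labels, 1)
        fresh_first_loss = fresh.history[0]["train_loss"]
        # resuming continues near the previous loss, far below a fresh start
        assert abs(resumed_loss - loss_at_stop) < abs(fresh_first_loss - loss_at_stop)
        assert resumed_loss < fresh_first_loss

    def test_unknown_label_rejected(self, dataset):
        state = build_model(small_config(), 2, dataset.class_names)
        labels = list(dataset.labels)
        labels[0] = "Unknown"
        with pytest.raises(ValidationError):
            fit(state, dataset.items, labels, 1)

    def test_single_class_labels_rejected(self, dataset):
        state = build_model(small_config(), 2, dataset.class_names)
        with pytest.raises(ValidationError):
            fit(state, dataset.items, [dataset.labels[0]] * len(dataset.items), 1)

    def test_training_recovers_separable_classes(self):
        ds = generate_class_dataset(50, seed=31)
        state = build_model(ClassifierConfig(seed=31), 2, ds.class_names)
        fit(state, ds.items, ds.labels, 30)
        assert state.history[-1]["train_accuracy"] >= 0.95

    def test_frozen_backbone_unchanged_by_fit(self, dataset):
        state = build_model(small_config(architecture="transfer_head"), 2,
                            dataset.class_names)
        before = {
            name: arr.copy()
            for name, layer, _, arr in state.network.named_params()
            if not layer.trainable
        }
        fit(state, dataset.items, dataset.labels, 2)
        after = {
            name: arr
            for name, layer, _, arr in state.network.named_params()
            if not layer.trainable
        }
        for name in before:
            assert (before[name] == after[name]).all()


class TestPredict:
    def test_probabilities_sum_to_one(self, trained):
        state, ds = trained
        _, probs = predict(state, ds.items)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs >= 0).all()

    def test_duplicate_items_get_identical_probabilities(self, trained):
        state, ds = trained
        _, probs = predict(state, [ds.items[0], ds.items[0]])
        assert (probs[0] == probs[1]).all()

    def test_untrained_model_rejected(self):
        state = build_model(small_config(), 2, ("a", "b"))
        with pytest.raises(ValidationError):
            predict(state, [np.zeros((1, 8, 8))])


class TestEvaluate:
    def test_perfect_predictions(self):
        rep = evaluate(["a", "b", "a"], ["a", "b", "a"], ("a", "b"))
        assert (rep.confusion_matrix == np.array([[2, 0], [0, 1]])).all()
        assert rep.accuracy == 1.0 and rep.macro_f1 == 1.0

    def test_single_predicted_class_on_balanced_labels(self):
        y_true = ["a"] * 5 + ["b"] * 5
        rep = evaluate(y_true, ["a"] * 10, ("a", "b"))
        assert rep.accuracy == 0.5
        assert rep.recall[1] == 0.0

    def test_printed_2x2_counts(self):
        # TP=8 FP=2 FN=2 TN=8 for class "pos"
        y_true = ["pos"] * 8 + ["neg"] * 2 + ["pos"] * 2 + ["neg"] * 8
        y_pred = ["pos"] * 8 + ["pos"] * 2 + ["neg"] * 2 + ["neg"] * 8
        rep = evaluate(y_true, y_pred, ("pos", "neg"))
        i = rep.class_names.index("pos")
        assert rep.precision[i] == pytest.approx(0.8)
        assert rep.recall[i] == pytest.approx(0.8)
        assert rep.f1[i] == pytest.approx(0.8)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_brute_force_metrics(self, seed):
        rng = np.random.default_rng(seed)
        classes = ("a", "b", "c")
        y_true = [classes[i] for i in rng.integers(0, 3, 60)]
        y_pred = [classes[i] for i in rng.integers(0, 3, 60)]
        rep = evaluate(y_true, y_pred, classes)
        for i, cls in enumerate(classes):
            tp = sum(t == cls and p == cls for t, p in zip(y_true, y_pred))
            fp = sum(t != cls and p == cls for t, p in zip(y_true, y_pred))
            fn = sum(t == cls and p != cls for t, p in zip(y_true, y_pred))
            prec = tp / (tp + fp) if tp + fp else 0.0
            rec = tp / (tp + fn) if tp + fn else 0.0
            f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
            assert rep.precision[i] == pytest.approx(prec)
            assert rep.recall[i] == pytest.approx(rec)
            assert rep.f1[i] == pytest.approx(f1)
        # row sums equal ground-truth counts; accuracy = trace/total
        for i, cls in enumerate(classes):
            assert rep.confusion_matrix[i].sum() == y_true.count(cls)
        assert rep.accuracy == pytest.approx(
            np.trace(rep.confusion_matrix) / len(y_true)
        )

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            evaluate([], [], ("a", "b"))


class TestHitlRound:
    def _project(self, n_labeled_per_class=8, n_unlabeled_per_class=4, seed=51):
        ds = generate_class_dataset(
            n_labeled_per_class + n_unlabeled_per_class, seed=seed
        )
        project = pk.create_project("hitl")
        project.add_images(ds.items)
        for name in ds.class_names:
            project.register_category(IMAGE_KIND, name, (0, 128, 255))
        by_name = {c.name: c.id for c in project.categories().values()}
        truth = {}
        for k, (item, label) in enumerate(zip(ds.items, ds.labels)):
            truth[item.id] = label
            if k % (n_labeled_per_class + n_unlabeled_per_class) < n_labeled_per_class:
                project.assign([item.id], category_id=by_name[label])
        project.commit()
        return project, ds, by_name, truth

    def test_round_with_no_unlabeled_items(self):
        project, ds, by_name, truth = self._project(n_unlabeled_per_class=0)
        state = build_model(small_config(), 2, ds.class_names)
        state, report = hitl_round(project, state, additional_epochs=2)
        assert state.epochs_completed == 2
        assert report.confusion_matrix.sum() > 0
        assert not project.has_staged_changes() or True  # no predictions staged
        unknown = project.unknown_category(IMAGE_KIND)
        assert all(
            project.get(i).category_id != unknown for i in project.images()
        )

    def test_predictions_are_staged_for_review(self):
        project, ds, by_name, truth = self._project()
        state = build_model(small_config(), 2, ds.class_names)
        hitl_round(project, state, additional_epochs=2)
        assert project.has_staged_changes()
        unknown = project.unknown_category(IMAGE_KIND)
        # staged view has no Unknown items left; committed view still does
        staged = [project.get(i).category_id for i in project.images()]
        committed = [
            project.get(i, committed=True).category_id for i in project.images()
        ]
        assert unknown not in staged
        assert unknown in committed

    def test_degenerate_corrections_raise_on_next_fit(self):
        project, ds, by_name, truth = self._project()
        state = build_model(small_config(), 2, ds.class_names)
        hitl_round(project, state, additional_epochs=1)
        one_class = by_name[ds.class_names[0]]
        project.assign(list(project.images()), category_id=one_class)
        project.commit()
        with pytest.raises(ValidationError):
            hitl_round(project, state, additional_epochs=1)
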