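"""Dataset assembly, head-only fine-tuning, evaluation and embedding."""

import numpy as np
import pytest
from sklearn.metrics import silhouette_score

from suturemap.datatypes import ProjectedImage
from suturemap.errors import DegenerateDataError, InsufficientDataError, ValidationError
from suturemap.phantom import SUBTYPES
from suturemap.training import (
    DatasetSplit,
    SutureClassifier,
    TinyConvBackbone,
    TrainingConfig,
    assemble_dataset,
    embed_2d,
    evaluate,
    extract_features,
    repeated_train,
    shuffle_split_labels,
    train_classifier,
)


def random_cases(rng, n_per_class, side=32):
    """Distinct random binary images, n_per_class per subtype."""
    images, labels = {}, {}
    i = 0
    for cls in SUBTYPES:
        for _ in range(n_per_class):
            cid = f"case{i:03d}"
            images[cid] = ProjectedImage((rng.random((side, side)) < 0.3).astype(np.uint8))
            labels[cid] = cls
            i += 1
    return images, labels


def class_prototypes(side=32):
    """Four fixed, well-separated images: one quadrant of ones per class."""
    protos = {}
    h = side // 2
    corners = [(0, 0), (0, h), (h, 0), (h, h)]
    for cls, (r, c) in zip(SUBTYPES, corners):
        px = np.zeros((side, side), dtype=np.uint8)
        px[r: r + h, c: c + h] = 1
        protos[cls] = px
    return protos


def separable_split(n_train=40, n_eval=12, seed=0):
    protos = class_prototypes()
    rng = np.random.default_rng(seed)

    def draw(n):
        labs = np.array([SUBTYPES[i % 4] for i in range(n)])
        rng.shuffle(labs)
        imgs = np.stack([protos[l] for l in labs])
        return imgs, labs

    tr = draw(n_train)
    va = draw(n_eval)
    te = draw(n_eval)
    bl = draw(8)
    return DatasetSplit(
        train_images=tr[0], train_labels=tr[1],
        val_images=va[0], val_labels=va[1],
        test_images=te[0], test_labels=te[1],
        blind_images=bl[0], blind_labels=bl[1],
    )


FAST = TrainingConfig(learning_rate=0.1, steps=300, seed=0)


class TestAssemble:
    def test_blind_holdout_is_two_per_class(self, rng):
        images, labels = random_cases(rng, 4)
        split = assemble_dataset(images, labels, holdout_per_class=2, seed=0)
        assert len(split.blind_labels) == 8
        assert all(list(split.blind_labels).count(c) == 2 for c in SUBTYPES)
        # blind cases appear in no partition
        used = set(split.train_case_ids) | set(split.val_case_ids) | set(split.test_case_ids)
        assert used.isdisjoint(split.blind_case_ids)

    def test_61_images_per_case_before_splitting(self, rng):
        """10 labeled cases with the default recipe -> 610 augmented images."""
        images, labels = random_cases(rng, 3)
        images = dict(list(images.items())[:10])
        labels = {k: labels[k] for k in images}
        split = assemble_dataset(images, labels, holdout_per_class=0, seed=0)
        assert sum(split.sizes) == 610

    def test_split_sizes_within_one_of_exact_ratio(self, rng):
        images, labels = random_cases(rng, 3)
        images = dict(list(images.items())[:10])
        labels = {k: labels[k] for k in images}
        split = assemble_dataset(images, labels, holdout_per_class=0, seed=0)
        exact = np.array([610 * 3 / 5, 610 / 5, 610 / 5])
        assert np.all(np.abs(np.array(split.sizes) - exact) <= 1)

    def test_partitions_disjoint_and_exhaustive(self, rng):
        images, labels = random_cases(rng, 3)
        split = assemble_dataset(images, labels, holdout_per_class=1, seed=3)
        assert sum(split.sizes) == 8 * 61

    def test_unlabeled_cases_removed(self, rng):
        images, labels = random_cases(rng, 3)
        victim = next(iter(labels))
        labels[victim] = "unlabeled"
        split = assemble_dataset(images, labels, holdout_per_class=0, seed=0)
        assert victim not in set(split.train_case_ids) | set(split.val_case_ids) | set(split.test_case_ids)

    def test_too_few_cases_raises(self, rng):
        images, labels = random_cases(rng, 2)
        with pytest.raises(InsufficientDataError):
            assemble_dataset(images, labels, holdout_per_class=2, seed=0)

    def test_grouped_split_keeps_cases_together(self, rng):
        images, labels = random_cases(rng, 4)
        split = assemble_dataset(images, labels, holdout_per_class=1, seed=0, grouped=True)
        parts = [set(split.train_case_ids), set(split.val_case_ids), set(split.test_case_ids)]
        for a in range(3):
            for b in range(a + 1, 3):
                assert parts[a].isdisjoint(parts[b])

    def test_image_level_split_leaks_cases(self, rng):
        """The default split places augments of one case in several partitions."""
        images, labels = random_cases(rng, 4)
        split = assemble_dataset(images, labels, holdout_per_class=1, seed=0, grouped=False)
        assert set(split.train_case_ids) & set(split.test_case_ids)


class TestTraining:
    def test_backbone_untouched_by_head_training(self):
        backbone = TinyConvBackbone(seed=0)
        before = backbone.checksum()
        _, report = train_classifier(separable_split(), FAST, backbone)
        assert backbone.checksum() == before

    def test_head_scope_freezes_hidden_layer(self):
        model = SutureClassifier(separable_split(), FAST)
        model.fit()
        w1_after_first = model._w1.copy()
        rng_clone = np.random.default_rng(FAST.seed)
        d, h = model._w1.shape
        expected = rng_clone.normal(0.0, np.sqrt(2.0 / d), size=(d, h))
        np.testing.assert_array_equal(w1_after_first, expected)

    def test_all_scope_trains_hidden_layer(self):
        cfg = TrainingConfig(learning_rate=0.1, steps=100, trainable_scope="all", seed=0)
        model = SutureClassifier(separable_split(), cfg)
        rng_clone = np.random.default_rng(cfg.seed)
        model.fit()
        d, h = model._w1.shape
        init = rng_clone.normal(0.0, np.sqrt(2.0 / d), size=(d, h))
        assert not np.array_equal(model._w1, init)

    def test_separable_classes_reach_full_training_accuracy(self):
        """Four fixed, distinct class images are linearly separable, so the
        head fits them perfectly."""
        _, report = train_classifier(separable_split(), FAST)
        assert report.final_train_accuracy == 100.0
        assert report.final_test_accuracy == 100.0

    def test_same_seed_same_result(self):
        _, r1 = train_classifier(separable_split(), FAST)
        _, r2 = train_classifier(separable_split(), FAST)
        assert r1.final_test_accuracy == r2.final_test_accuracy
        np.testing.assert_array_equal(r1.cross_entropy, r2.cross_entropy)

    def test_curves_recorded_at_stated_cadence(self):
        cfg = TrainingConfig(learning_rate=0.1, steps=100, validation_every=10, seed=0)
        _, report = train_classifier(separable_split(), cfg)
        assert len(report.train_accuracy) == 100
        assert len(report.cross_entropy) == 100
        assert [s for s, _ in report.validation_accuracy] == list(range(10, 101, 10))
        assert np.all(report.cross_entropy >= 0)

    def test_single_class_training_set_raises(self):
        split = separable_split()
        split.train_labels = np.array(["anterior"] * len(split.train_labels))
        with pytest.raises(DegenerateDataError):
            SutureClassifier(split, FAST)

    def test_summary_mentions_all_rows(self):
        _, report = train_classifier(separable_split(), FAST)
        text = report.summary()
        for key in ("Training", "Validation", "Test (generated)", "blind"):
            assert key in text

    def test_label_shuffle_breaks_learning(self):
        split = shuffle_split_labels(separable_split(n_train=400), seed=1)
        _, report = train_classifier(split, FAST)
        assert report.final_test_accuracy < 60.0


class TestRepeatedTrain:
    def test_single_run_mean_is_that_run(self):
        out = repeated_train(lambda s: separable_split(seed=s), FAST, n_runs=1)
        assert out["mean"] == out["accuracies"][0]
        assert out["sd"] == 0.0

    def test_constant_accuracy_has_zero_sd(self):
        out = repeated_train(lambda s: separable_split(seed=s), FAST, n_runs=3)
        assert out["accuracies"] == [100.0] * 3
        assert out["sd"] == 0.0

    def test_mean_recomputed_from_returned_values(self):
        out = repeated_train(lambda s: separable_split(seed=s), FAST, n_runs=3)
        assert out["mean"] == pytest.approx(np.mean(out["accuracies"]))


class TestEvaluate:
    def test_six_of_eight_is_75_percent(self):
        """6 correct of 8: the evaluation arithmetic gives exactly 75.00%."""
        model, _ = train_classifier(separable_split(), FAST)
        protos = class_prototypes()
        images = np.stack([protos["anterior"]] * 8)
        labels = np.array(["anterior"] * 6 + ["central", "posterior"])
        acc, conf = evaluate(model, images, labels)
        assert acc == 75.00
        assert conf.loc["anterior", "anterior"] == 6
        assert conf.loc["central", "anterior"] == 1

    def test_all_and_none_correct(self):
        model, _ = train_classifier(separable_split(), FAST)
        protos = class_prototypes()
        images = np.stack([protos[c] for c in SUBTYPES])
        acc, conf = evaluate(model, images, np.array(list(SUBTYPES)))
        assert acc == 100.0
        wrong = np.array(list(SUBTYPES))[[1, 2, 3, 0]]
        acc0, conf0 = evaluate(model, images, wrong)
        assert acc0 == 0.0
        assert np.trace(conf0.values) == 0

    def test_empty_set_raises(self):
        model, _ = train_classifier(separable_split(), FAST)
        with pytest.raises(ValidationError):
            evaluate(model, np.zeros((0, 32, 32)), np.array([]))


class TestEmbedding:
    def test_row_count_preserved(self, rng):
        model, _ = train_classifier(separable_split(), FAST)
        protos = class_prototypes()
        images = np.stack([protos[c] for c in SUBTYPES] * 3)
        feats = extract_features(model, images)
        emb = embed_2d(feats, seed=0)
        assert emb.shape == (12, 2)

    def test_identical_vectors_coincide(self):
        emb = embed_2d(np.ones((6, 8)), seed=0)
        assert np.ptp(emb) == 0.0

    def test_separated_clusters_have_positive_silhouette(self, rng):
        a = rng.normal(0, 0.1, size=(15, 8))
        b = rng.normal(5, 0.1, size=(15, 8))
        emb = embed_2d(np.vstack([a, b]), seed=0)
        labels = np.array([0] * 15 + [1] * 15)
        assert silhouette_score(emb, labels) > 0

    def test_single_vector_rejected(self):
        with pytest.raises(ValidationError):
            embed_2d(np.ones((1, 4)))
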