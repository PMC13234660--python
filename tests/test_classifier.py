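"""Cosine similarity, centroid fitting, classification, and evaluation."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from plasmavoc.classifier import (
    CategoryModel,
    category_similarity_stats,
    classify,
    concat_features,
    cosine_similarity,
    evaluate,
    fit_centroids,
    normalize_similarities,
    SimilarityMatrix,
)
from plasmavoc.features import BlockGrid, FeatureVector
from plasmavoc.images import enumerate_categories


def fv(values, label=None, source_id="", region=""):
    return FeatureVector(np.asarray(values, dtype=float), grid=None,
                         region_name=region, source_id=source_id, label=label)


def naive_cosine(x, y):
    num = sum(a * b for a, b in zip(x, y))
    nx = math.sqrt(sum(a * a for a in x))
    ny = math.sqrt(sum(b * b for b in y))
    return num / (nx * ny)


finite_vec = hnp.arrays(
    np.float64, st.integers(2, 12),
    elements=st.floats(0.0, 255.0, allow_nan=False)
).filter(lambda v: np.linalg.norm(v) > 1e-6)


class TestCosine:
    def test_identical_vectors_give_one(self, rng):
        x = rng.uniform(1, 255, 12)
        assert cosine_similarity(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_vectors_give_zero(self):
        assert cosine_similarity([1.0, 0.0], [0.0, 1.0]) == 0.0

    def test_cos_45_degrees(self):
        assert cosine_similarity([1.0, 0.0], [1.0, 1.0]) == pytest.approx(
            math.sqrt(2) / 2, abs=1e-12)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="nonzero"):
            cosine_similarity([0.0, 0.0], [1.0, 1.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            cosine_similarity([1.0, 2.0], [1.0, 2.0, 3.0])

    @given(finite_vec, st.data())
    def test_bounds_symmetry_scale_invariance(self, x, data):
        y = data.draw(
            hnp.arrays(np.float64, len(x),
                       elements=st.floats(0.0, 255.0, allow_nan=False))
            .filter(lambda v: np.linalg.norm(v) > 1e-6)
        )
        s = cosine_similarity(x, y)
        assert -1.0 - 1e-12 <= s <= 1.0 + 1e-12
        # nonnegative entries confine the similarity to [0, 1]
        assert s >= -1e-12
        assert cosine_similarity(y, x) == pytest.approx(s, abs=1e-12)
        alpha = data.draw(st.floats(0.01, 1.0))
        assert cosine_similarity(alpha * x, y) == pytest.approx(s, abs=1e-9)

    def test_against_sklearn(self, rng):
        from sklearn.metrics.pairwise import cosine_similarity as sk_cos

        for _ in range(20):
            x = rng.uniform(0, 255, 9)
            y = rng.uniform(0.1, 255, 9)
            assert cosine_similarity(x, y) == pytest.approx(
                float(sk_cos(x[None], y[None])[0, 0]), abs=1e-12)


class TestFitCentroids:
    def test_single_vector_per_label(self, rng):
        vecs = [fv(rng.uniform(1, 255, 6), label=l) for l in ["C-17", "B-17"]]
        model = fit_centroids(vecs)
        assert model.labels == ["C-17", "B-17"]
        for v in vecs:
            assert np.allclose(model.centroid(v.label), v.values)

    def test_two_point_mean(self):
        model = fit_centroids([
            fv([0.0, 0.0, 0.0], label="C-17"),
            fv([2.0, 4.0, 6.0], label="C-17"),
        ])
        assert np.allclose(model.centroid("C-17"), [1.0, 2.0, 3.0])
        assert model.train_counts == {"C-17": 2}

    def test_matches_column_loop_oracle(self, rng):
        labels = ["C-17", "B-20", "A-24"]
        training = [
            (fv(rng.uniform(0, 255, 8)), lab) for lab in labels for _ in range(5)
        ]
        model = fit_centroids(training)
        for lab in labels:
            vecs = [v.values for v, l in training if l == lab]
            expected = [sum(v[i] for v in vecs) / len(vecs) for i in range(8)]
            assert np.allclose(model.centroid(lab), expected, atol=1e-12)

    def test_inconsistent_lengths_rejected(self):
        with pytest.raises(ValueError, match="length"):
            fit_centroids([fv([1.0, 2.0], label="C-17"),
                           fv([1.0, 2.0, 3.0], label="B-17")])

    def test_empty_training_rejected(self):
        with pytest.raises(ValueError):
            fit_centroids([])

    def test_unlabeled_vector_rejected(self):
        with pytest.raises(ValueError, match="label"):
            fit_centroids([fv([1.0, 2.0])])

    def test_labels_in_canonical_order(self, rng):
        labels = [l.render() for l in enumerate_categories()]
        training = [fv(rng.uniform(1, 255, 4), label=l) for l in reversed(labels)]
        model = fit_centroids(training)
        assert model.labels == labels


class TestClassify:
    def make_model(self, rng, n_labels=24, n=12):
        labels = [l.render() for l in enumerate_categories()][:n_labels]
        centroids = rng.uniform(1, 255, (n_labels, n))
        return CategoryModel(labels=labels, centroids=centroids)

    def test_centroid_classifies_to_itself(self, rng):
        model = self.make_model(rng)
        label = model.labels[5]
        pred, row = classify(model.centroid(label), model)
        assert pred == label
        assert row[label] == pytest.approx(1.0, abs=1e-12)

    def test_singleton_model(self, rng):
        model = CategoryModel(labels=["A-27"],
                              centroids=rng.uniform(1, 255, (1, 6)))
        pred, _ = classify(rng.uniform(1, 255, 6), model)
        assert pred == "A-27"

    def test_perturbed_centroid_recovers_label(self, rng):
        model = self.make_model(rng)
        for k in [0, 7, 23]:
            test = model.centroids[k] + rng.normal(0, 1e-6, model.n_entries)
            pred, row = classify(test, model)
            # exhaustive comparison oracle
            sims = [naive_cosine(test, c) for c in model.centroids]
            assert pred == model.labels[int(np.argmax(sims))]
            assert pred == model.labels[k]

    def test_matches_sklearn_argmax(self, rng):
        from sklearn.metrics.pairwise import cosine_similarity as sk_cos

        model = self.make_model(rng)
        tests = rng.uniform(1, 255, (10, model.n_entries))
        sk = sk_cos(tests, model.centroids)
        for t, sims in zip(tests, sk):
            pred, row = classify(t, model)
            assert pred == model.labels[int(np.argmax(sims))]
            assert np.allclose(row.to_numpy(), sims, atol=1e-12)

    def test_tie_breaks_to_first_canonical_label(self, rng):
        c = rng.uniform(1, 255, 6)
        model = CategoryModel(labels=["C-17", "B-17"],
                              centroids=np.stack([c, 2 * c]))
        pred, row = classify(3 * c, model)
        assert row["C-17"] == row["B-17"]
        assert pred == "C-17"

    def test_permutation_invariance(self, rng):
        model = self.make_model(rng)
        test = rng.uniform(1, 255, model.n_entries)
        perm = rng.permutation(model.n_entries)
        permuted = CategoryModel(labels=model.labels,
                                 centroids=model.centroids[:, perm])
        assert classify(test, model)[0] == classify(test[perm], permuted)[0]

    def test_length_mismatch_rejected(self, rng):
        model = self.make_model(rng)
        with pytest.raises(ValueError, match="length"):
            classify(rng.uniform(1, 255, model.n_entries + 1), model)


class TestNormalization:
    def matrix(self, values):
        values = np.asarray(values, dtype=float)
        return SimilarityMatrix(
            row_ids=[f"t{i}" for i in range(values.shape[0])],
            labels=[f"c{j}" for j in range(values.shape[1])],
            values=values,
        )

    def test_direct_arithmetic(self):
        norm = normalize_similarities(self.matrix([[0.99, 0.95]]))
        assert np.allclose(norm.values, [[0.8, 0.0]])

    def test_minimum_maps_to_zero_and_one_is_fixed(self, rng):
        raw = rng.uniform(0.9, 0.999, (5, 4))
        raw[2, 1] = 1.0
        norm = normalize_similarities(self.matrix(raw))
        assert norm.values.min() == 0.0
        assert norm.values[2, 1] == pytest.approx(1.0, abs=1e-12)
        assert norm.values.max() <= 1.0

    def test_minimum_is_global_not_per_row(self):
        raw = np.array([[0.99, 0.98], [0.95, 0.97]])
        norm = normalize_similarities(self.matrix(raw))
        # row 0 minimum does not map to 0; only the global minimum does
        assert norm.values[0].min() > 0.0
        assert norm.values[1, 0] == 0.0

    def test_rank_order_preserved(self, rng):
        raw = rng.uniform(0.5, 0.9999, (6, 5))
        norm = normalize_similarities(self.matrix(raw))
        assert np.array_equal(np.argsort(raw, axis=None),
                              np.argsort(norm.values, axis=None))

    def test_degenerate_all_ones_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            normalize_similarities(self.matrix([[1.0, 1.0]]))


class TestEvaluate:
    def make_model(self, rng, n=12):
        labels = [l.render() for l in enumerate_categories()]
        centroids = rng.uniform(1, 255, (24, n))
        return CategoryModel(labels=labels, centroids=centroids)

    def test_self_classification_is_perfect(self, rng):
        model = self.make_model(rng)
        test = [(fv(c, source_id=f"{l}_t.png"), l)
                for l, c in zip(model.labels, model.centroids)]
        report = evaluate(test, model)
        assert report.accuracy == 1.0
        assert report.misclassified == []
        assert report.wall_time_s >= 0.0

    def test_23_of_24_rounds_to_95_8(self, rng):
        model = self.make_model(rng)
        test = [(fv(c), l) for l, c in zip(model.labels, model.centroids)]
        # corrupt one test item: feed another category's centroid
        test[3] = (fv(model.centroids[4]), model.labels[3])
        report = evaluate(test, model)
        assert report.accuracy == pytest.approx(23 / 24)
        assert report.accuracy_percent == 95.8
        assert len(report.misclassified) == 1
        assert report.misclassified[0].true_label == model.labels[3]
        assert report.misclassified[0].predicted_label == model.labels[4]

    def test_matrices_shape_and_normalized_twin(self, rng):
        model = self.make_model(rng)
        test = [(fv(c + rng.normal(0, 1, len(c)).clip(-1, 1) + 1), l)
                for l, c in zip(model.labels, model.centroids)]
        report = evaluate(test, model)
        assert report.similarities.values.shape == (24, 24)
        assert report.normalized is not None
        assert report.normalized.values.min() == 0.0
        assert report.normalized.values.max() <= 1.0

    def test_empty_test_set_rejected(self, rng):
        with pytest.raises(ValueError):
            evaluate([], self.make_model(rng))


class TestCategoryStats:
    def test_degenerate_set(self, rng):
        model = CategoryModel(labels=["C-17"],
                              centroids=rng.uniform(1, 255, (1, 6)))
        imgs = [(fv(model.centroids[0]), "C-17")] * 3
        stats = category_similarity_stats(imgs, model)
        assert stats.loc["C-17", "mean"] == pytest.approx(1.0, abs=1e-12)
        assert stats.loc["C-17", "difference"] == pytest.approx(0.0, abs=1e-12)

    def test_two_point_statistics(self):
        # construct two vectors with cosines 0.90 and 1.00 to the centroid
        c = np.array([1.0, 0.0])
        theta = math.acos(0.90)
        v = np.array([math.cos(theta), math.sin(theta)])
        model = CategoryModel(labels=["C-17"], centroids=c[None])
        stats = category_similarity_stats(
            [(fv(c), "C-17"), (fv(v), "C-17")], model)
        assert stats.loc["C-17", "mean"] == pytest.approx(0.95, abs=1e-12)
        assert stats.loc["C-17", "max"] == pytest.approx(1.0, abs=1e-12)
        assert stats.loc["C-17", "difference"] == pytest.approx(0.05, abs=1e-12)

    def test_unknown_label_rejected(self, rng):
        model = CategoryModel(labels=["C-17"],
                              centroids=rng.uniform(1, 255, (1, 4)))
        with pytest.raises(KeyError, match="B-17"):
            category_similarity_stats([(fv(rng.uniform(1, 255, 4)), "B-17")],
                                      model)


class TestConcat:
    def test_region2_plus_region3_lengths(self, rng):
        a = fv(rng.uniform(0, 255, 270), source_id="x.png", region="region2")
        b = fv(rng.uniform(0, 255, 1620), source_id="x.png", region="region3")
        out = concat_features(a, b)
        assert len(out) == 1890
        assert out.region_name == "region2+region3"

    def test_empty_operand_rejected(self, rng):
        a = fv(rng.uniform(0, 255, 6), source_id="x.png")
        with pytest.raises(ValueError, match="empty"):
            concat_features(a, fv([], source_id="x.png"))

    def test_source_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="source id"):
            concat_features(fv(rng.uniform(0, 255, 6), source_id="x.png"),
                            fv(rng.uniform(0, 255, 6), source_id="y.png"))

    def test_self_concatenation_preserves_classification(self, rng):
        # cos(x||x, y||y) == cos(x, y), so duplicated features cannot
        # change the argmax
        labels = [l.render() for l in enumerate_categories()][:6]
        training = [fv(rng.uniform(1, 255, 8), label=l, source_id=f"{l}.png")
                    for l in labels for _ in range(3)]
        single = fit_centroids(training)
        doubled = fit_centroids(
            [concat_features(v, v) for v in training])
        for _ in range(10):
            t = fv(rng.uniform(1, 255, 8), source_id="t.png")
            assert classify(t, single)[0] == \
                classify(concat_features(t, t), doubled)[0]


class TestModelIO:
    def test_json_roundtrip(self, rng, tmp_path):
        model = CategoryModel(
            labels=["C-17", "B-20"],
            centroids=rng.uniform(1, 255, (2, 6)),
            grid=BlockGrid(1, 2),
            region_name="region1",
            train_counts={"C-17": 5, "B-20": 5},
        )
        path = model.save(tmp_path / "model.json")
        back = CategoryModel.load(path)
        assert back.labels == model.labels
        assert np.allclose(back.centroids, model.centroids)
        assert back.grid == model.grid
        assert back.region_name == "region1"
        assert back.train_counts == model.train_counts

    def test_zero_centroid_rejected(self):
        with pytest.raises(ValueError, match="zero centroid"):
            CategoryModel(labels=["C-17"], centroids=np.zeros((1, 4)))
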