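"""Chi-square distance, similarity, retrieval, k-NN, PR evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from florashape import (
    DescriptorIndex,
    RunConfig,
    ScalarScaling,
    chi2_distance,
    classify_nn,
    descriptor_distance,
    exponential_weights,
    extract_descriptor,
    precision_recall,
    retrieve,
    similarity,
    uniform_weights,
)
from florashape.synthetic import FlowerSpec, generate_collection, generate_flower

RANKED_10 = ["C9", "Cp", "P8", "C1", "A3", "S7", "D1", "D2", "D4", "D3"]
W_EXP = exponential_weights(RANKED_10)
FAST = RunConfig(n_samples=400, bins=40)


class TestChi2:
    def test_identity(self):
        v = np.array([0.2, 0.3, 0.5])
        assert chi2_distance(v, v) == 0.0

    def test_disjoint_unit_masses(self):
        assert chi2_distance([1, 0], [0, 1]) == pytest.approx(2.0)

    def test_zero_denominator_terms_ignored(self):
        assert chi2_distance([0.5, 0.5, 0], [0.5, 0.5, 0]) == 0.0
        assert chi2_distance([1, 0, 0], [0, 1, 0]) == pytest.approx(2.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            chi2_distance([1, 0], [1, 0, 0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=3, max_size=3),
           st.lists(st.floats(0, 1), min_size=3, max_size=3))
    def test_symmetric_and_nonnegative(self, a, b):
        assert chi2_distance(a, b) == pytest.approx(chi2_distance(b, a))
        assert chi2_distance(a, b) >= 0.0


class TestSimilarity:
    def test_endpoints_and_midpoint(self):
        assert similarity(1.0, max_dis=5.0, min_dis=1.0) == 1.0
        assert similarity(5.0, max_dis=5.0, min_dis=1.0) == 0.0
        assert similarity(3.0, max_dis=5.0, min_dis=1.0) == 0.5

    def test_out_of_range_clipped_with_warning(self):
        with pytest.warns(UserWarning):
            assert similarity(9.0, max_dis=5.0, min_dis=1.0) == 0.0

    def test_degenerate_range(self):
        with pytest.raises(ValueError):
            similarity(1.0, max_dis=2.0, min_dis=2.0)


@pytest.fixture(scope="module")
def small_collection():
    coll = generate_collection(
        n_classes=3, per_class=6,
        base_specs=[
            FlowerSpec(color=1, openness=0.2, n_petals=5, seed=0),
            FlowerSpec(color=5, openness=0.6, n_petals=9, seed=1),
            FlowerSpec(color=2, openness=0.9, n_petals=7, fullness=0.4, seed=2),
        ],
        seed=10, jitter=0.03,
    )
    descs = [
        extract_descriptor(m, RunConfig(n_samples=400, bins=40, seed=100 + i))
        for i, m in enumerate(coll.meshes)
    ]
    return descs, coll.labels


class TestDescriptorDistance:
    def test_zero_on_identical(self, small_collection):
        descs, _ = small_collection
        assert descriptor_distance(descs[0], descs[0], W_EXP) == 0.0

    def test_color_mismatch_forced_value(self, small_collection):
        """Identical shape, different C9: the one-hot chi-square of 2
        weighted by 0.28 contributes exactly 0.56."""
        import copy
        from dataclasses import replace

        descs, _ = small_collection
        a = descs[0]
        b = copy.deepcopy(a)
        b.color = replace(b.color, c9=a.color.c9 % 8 + 1)
        scaling = ScalarScaling.from_descriptors([a, b])
        assert descriptor_distance(a, b, W_EXP, scaling) == pytest.approx(0.56)

    def test_pseudometric_properties(self, small_collection):
        descs, _ = small_collection
        scaling = ScalarScaling.from_descriptors(descs)
        d_ab = descriptor_distance(descs[0], descs[7], W_EXP, scaling)
        d_ba = descriptor_distance(descs[7], descs[0], W_EXP, scaling)
        assert d_ab == pytest.approx(d_ba)
        assert d_ab >= 0.0

    def test_lower_bounded_by_largest_weighted_term(self, small_collection):
        descs, _ = small_collection
        scaling = ScalarScaling.from_descriptors(descs)
        a, b = descs[0], descs[10]
        total = descriptor_distance(a, b, W_EXP, scaling)
        color_term = W_EXP["C9"] * (2.0 if a.color.c9 != b.color.c9 else 0.0)
        assert total >= color_term - 1e-12


class TestRetrieve:
    def test_self_match_ranks_first_with_similarity_one(self, small_collection):
        descs, _ = small_collection
        res = retrieve(descs[4], descs, W_EXP, k=6)
        assert res.entries[0][0] == "4"
        assert res.entries[0][1] == 0.0
        assert res.entries[0][2] == 1.0
        dists = [e[1] for e in res.entries]
        assert dists == sorted(dists)

    def test_k_larger_than_collection_clamps(self, small_collection):
        descs, _ = small_collection
        res = retrieve(descs[0], descs, W_EXP, k=999)
        assert len(res.entries) == len(descs)

    def test_top_neighbors_share_class(self, small_collection):
        descs, labels = small_collection
        hits = 0
        for i, d in enumerate(descs):
            others = [x for j, x in enumerate(descs) if j != i]
            other_labels = [x for j, x in enumerate(labels) if j != i]
            res = retrieve(d, others, W_EXP, k=3,
                           ids=[str(j) for j in range(len(others))])
            top = [other_labels[int(t)] for t, _, _ in res.entries]
            hits += all(t == labels[i] for t in top)
        assert hits / len(descs) >= 0.9

    def test_invalid_k(self, small_collection):
        descs, _ = small_collection
        with pytest.raises(ValueError):
            retrieve(descs[0], descs, W_EXP, k=0)


class TestClassifyNN:
    def test_exact_training_match(self, small_collection):
        descs, labels = small_collection
        assert classify_nn(descs[3], descs, labels, W_EXP, k=1) == labels[3]

    def test_tie_broken_by_mean_distance(self):
        """Two-neighbor tie: the class with the smaller mean distance
        among the voters wins."""
        from florashape.retrieval import _vote

        distances = np.array([0.1, 0.4, 9.0])
        labels = np.array(["a", "b", "b"], dtype=object)
        assert _vote(distances, labels, k=2) == "a"

    def test_empty_training_set(self, small_collection):
        descs, _ = small_collection
        with pytest.raises(ValueError):
            classify_nn(descs[0], [], [], W_EXP)


class TestPrecisionRecall:
    def test_perfect_ranking_gives_unit_curve(self):
        ranked = [np.array(["a", "a", "b", "b"], dtype=object)] * 2
        curve = precision_recall(ranked, ["a", "a"])
        assert np.allclose(curve.precision, 1.0)
        assert curve.auc() == pytest.approx(1.0)

    def test_random_ranking_approaches_class_prior(self, rng):
        # balanced two-class pool: precision ~ prior 0.5.  The
        # max-over-suffix interpolation biases the lowest recall points
        # upward, so the prior comparison uses recalls >= 0.3.
        pool = np.array(["a"] * 50 + ["b"] * 50, dtype=object)
        ranked = [pool[rng.permutation(100)] for _ in range(200)]
        curve = precision_recall(ranked, ["a"] * 200)
        assert np.all(np.abs(curve.precision[3:] - 0.5) < 0.1)
        assert np.all(curve.precision >= 0.5 - 0.05)

    def test_singleton_class_excluded_with_warning(self):
        ranked = [np.array(["b", "b"], dtype=object),
                  np.array(["a", "b"], dtype=object)]
        with pytest.warns(UserWarning, match="singleton"):
            curve = precision_recall(ranked, ["lonely", "b"])
        assert curve.precision.shape == (11,)

    def test_recall_grid_is_canonical(self):
        ranked = [np.array(["a", "b"], dtype=object)]
        curve = precision_recall(ranked, ["a"])
        assert np.allclose(curve.recall, np.linspace(0, 1, 11))


class TestIndex:
    def test_save_load_roundtrip(self, small_collection, tmp_path):
        descs, labels = small_collection
        idx = DescriptorIndex(
            descriptors=descs, ids=[f"m{i}" for i in range(len(descs))],
            labels=list(labels),
        )
        idx.save(tmp_path / "index.jsonl")
        back = DescriptorIndex.load(tmp_path / "index.jsonl")
        assert back.ids == idx.ids
        assert back.labels == idx.labels
        assert back.scaling.bounds == idx.scaling.bounds
        res_a = idx.retrieve(descs[0], W_EXP, k=3)
        res_b = back.retrieve(descs[0], W_EXP, k=3)
        assert [e[0] for e in res_a.entries] == [e[0] for e in res_b.entries]

    def test_classify_through_index(self, small_collection):
        descs, labels = small_collection
        idx = DescriptorIndex(
            descriptors=descs, ids=[str(i) for i in range(len(descs))],
            labels=list(labels),
        )
        assert idx.classify(descs[5], W_EXP) == labels[5]


class TestWeightVariants:
    def test_uniform_close_to_exponential_on_easy_problem(self, small_collection):
        from florashape.retrieval import evaluate_classification

        descs, labels = small_collection
        acc_exp = evaluate_classification(descs, labels, W_EXP, seed=0)["mean"]
        acc_uni = evaluate_classification(
            descs, labels, uniform_weights(list(W_EXP.weights)), seed=0
        )["mean"]
        assert acc_exp >= acc_uni - 0.01
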