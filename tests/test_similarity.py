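"""Activity vectors, cosine similarity, and significant clustering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster.hierarchy import fcluster

from abnremap import (
    ActivityVector,
    build_activity_vector,
    cluster_significance,
    cosine_similarity,
    hierarchical_clustering,
    similarity_matrix,
)
from abnremap.similarity import truncate_percentile
from conftest import build_experiment, make_train


def _one_event_experiment(activities, mice=None):
    """One neuron per activity value: a single event of that amplitude in a
    one-minute preC window makes mean activity equal the value."""
    mice = mice or ["m1"] * len(activities)
    trains = [
        make_train([1.0], [v], neuron=f"n{i:02d}", mouse=m, session="preC")
        for i, (v, m) in enumerate(zip(activities, mice))
    ]
    durations = {"preC": 60.0}
    return build_experiment(trains, durations=durations)


class TestBuildActivityVector:
    def test_truncation_and_rescale_hand_example(self):
        """[1,2,3,4,100]: p95 by linear interpolation is 80.8, then min-max."""
        exp = _one_event_experiment([1.0, 2.0, 3.0, 4.0, 100.0])
        vec = build_activity_vector(exp, "preC")
        expected = (np.array([1, 2, 3, 4, 80.8]) - 1.0) / 79.8
        np.testing.assert_allclose(vec.values, expected, rtol=1e-12)

    def test_constant_vector_degenerate(self):
        exp = _one_event_experiment([2.0, 2.0, 2.0])
        vec = build_activity_vector(exp, "preC")
        assert vec.degenerate
        np.testing.assert_array_equal(vec.values, 0.0)

    def test_truncation_is_per_mouse(self):
        """A huge outlier in mouse 1 must not alter mouse 2's values."""
        exp = _one_event_experiment(
            [1.0, 2.0, 3.0, 4.0, 100.0, 5.0, 6.0, 7.0],
            mice=["m1"] * 5 + ["m2"] * 3,
        )
        vec = build_activity_vector(exp, "preC")
        raw = np.array([1, 2, 3, 4, 80.8, 5, 6, 6.9])  # m2 p95 of [5,6,7] = 6.9
        np.testing.assert_allclose(
            vec.values, (raw - raw.min()) / (raw.max() - raw.min()), rtol=1e-12
        )

    def test_truncation_idempotent_for_fixed_threshold(self):
        values = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
        mice = ["m1"] * 5
        once = truncate_percentile(values, mice)
        thresholds = {"m1": once.max()}
        twice = truncate_percentile(once, mice, thresholds=thresholds)
        np.testing.assert_array_equal(once, twice)


class TestCosineSimilarity:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ([1, 0], [0, 1], 0.0),
            ([2, 2], [1, 1], 1.0),
            ([1, 2, 3], [3, 2, 1], 10 / 14),
        ],
    )
    def test_examples(self, a, b, expected):
        assert cosine_similarity(np.array(a, float), np.array(b, float)) == (
            pytest.approx(expected)
        )

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero vector"):
            cosine_similarity(np.zeros(3), np.ones(3))

    @given(
        st.lists(st.floats(0.0, 100.0), min_size=2, max_size=20),
        st.floats(0.1, 50.0),
    )
    @settings(max_examples=100, derandomize=True)
    def test_matches_naive_formula_and_scale_invariance(self, values, k):
        a = np.asarray(values) + 0.01  # keep nonzero
        rng = np.random.default_rng(0)
        b = rng.uniform(0.01, 1.0, a.size)
        naive = sum(x * y for x, y in zip(a, b)) / (
            np.sqrt(sum(x * x for x in a)) * np.sqrt(sum(y * y for y in b))
        )
        assert cosine_similarity(a, b) == pytest.approx(naive, abs=1e-12)
        assert cosine_similarity(k * a, b) == pytest.approx(
            cosine_similarity(a, b), abs=1e-12
        )


class TestSimilarityMatrix:
    def test_identical_vectors(self):
        sim = similarity_matrix([np.ones(3), np.ones(3)])
        np.testing.assert_allclose(sim.values, 1.0)

    def test_orthogonal_basis(self):
        sim = similarity_matrix([np.eye(3)[i] for i in range(3)])
        np.testing.assert_allclose(sim.values, np.eye(3))

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(1)
        vectors = [rng.uniform(0.1, 1.0, 12) for _ in range(4)]
        sim = similarity_matrix(vectors)
        for i in range(4):
            for j in range(4):
                assert sim.values[i, j] == pytest.approx(
                    cosine_similarity(vectors[i], vectors[j]), abs=1e-12
                )
        np.testing.assert_allclose(sim.values, sim.values.T)
        np.testing.assert_allclose(np.diag(sim.values), 1.0)


def _noisy_direction(direction, n, rng, scale=0.02):
    return [
        np.clip(direction + rng.normal(0, scale, direction.size), 0.0, None)
        for _ in range(n)
    ]


class TestHierarchicalClustering:
    def test_duplicate_pairs_merge_first(self):
        rng = np.random.default_rng(2)
        d1 = np.array([1.0, 0.0, 0.2, 0.1])
        d2 = np.array([0.0, 1.0, 0.1, 0.9])
        vectors = _noisy_direction(d1, 2, rng) + _noisy_direction(d2, 2, rng)
        z = hierarchical_clustering(similarity_matrix(vectors))
        first_two = {frozenset(map(int, row[:2])) for row in z[:2]}
        assert first_two == {frozenset({0, 1}), frozenset({2, 3})}

    def test_identical_vectors_merge_at_zero(self):
        z = hierarchical_clustering(similarity_matrix([np.ones(4)] * 3))
        np.testing.assert_allclose(z[:, 2], 0.0, atol=1e-12)

    def test_planted_two_direction_recovery(self):
        rng = np.random.default_rng(3)
        d1 = np.array([1.0, 0.1, 0.0, 0.5, 0.0])
        d2 = np.array([0.0, 0.8, 1.0, 0.0, 0.3])
        vectors = _noisy_direction(d1, 3, rng) + _noisy_direction(d2, 3, rng)
        z = hierarchical_clustering(similarity_matrix(vectors))
        heights = np.concatenate([[0.0], z[:, 2]])
        gap = int(np.argmax(np.diff(heights)))
        flat = fcluster(
            z, t=(heights[gap] + heights[gap + 1]) / 2, criterion="distance"
        )
        assert len(set(flat[:3])) == 1 and len(set(flat[3:])) == 1
        assert flat[0] != flat[3]

    def test_invariant_to_common_positive_rescaling(self):
        rng = np.random.default_rng(4)
        vectors = [rng.uniform(0.0, 1.0, 10) for _ in range(5)]
        z1 = hierarchical_clustering(similarity_matrix(vectors))
        z2 = hierarchical_clustering(similarity_matrix([7.3 * v for v in vectors]))
        np.testing.assert_allclose(z1, z2, atol=1e-12)


class TestClusterSignificance:
    def test_two_planted_groups_both_significant(self):
        rng = np.random.default_rng(5)
        d1 = np.zeros(60)
        d1[:20] = 1.0
        d2 = np.zeros(60)
        d2[40:] = 1.0
        base = rng.uniform(0.05, 0.2, 60)
        vectors = [
            ActivityVector(f"a{i}", np.clip(base + d1 + rng.normal(0, 0.05, 60), 0, None))
            for i in range(3)
        ] + [
            ActivityVector(f"b{i}", np.clip(base + d2 + rng.normal(0, 0.05, 60), 0, None))
            for i in range(3)
        ]
        result = cluster_significance(vectors, n_replicates=1000, seed=0)
        members = result.cluster_members()
        assert frozenset({"a0", "a1", "a2"}) in members
        assert frozenset({"b0", "b1", "b2"}) in members

    def test_duplicated_pair_among_noise(self):
        rng = np.random.default_rng(6)
        twin = rng.uniform(0.0, 1.0, 80)
        vectors = [
            ActivityVector("t1", twin),
            ActivityVector("t2", twin + rng.normal(0, 0.01, 80).clip(-twin)),
        ] + [
            ActivityVector(f"noise{i}", rng.uniform(0.0, 1.0, 80)) for i in range(3)
        ]
        result = cluster_significance(vectors, n_replicates=1000, seed=1)
        assert any({"t1", "t2"} <= set(c) for c in result.cluster_members())

    def test_iid_noise_false_positive_rate(self):
        """Vectors of i.i.d. noise yield significant clusters at about the
        nominal rate."""
        rng = np.random.default_rng(7)
        n_seeds, hits = 60, 0
        for s in range(n_seeds):
            vectors = [rng.uniform(0.0, 1.0, 50) for _ in range(4)]
            result = cluster_significance(
                [ActivityVector(f"v{i}", v) for i, v in enumerate(vectors)],
                n_replicates=500,
                seed=s,
            )
            hits += result.n_significant_clusters > 0
        assert hits / n_seeds <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_seeds)

    def test_too_few_vectors_rejected(self):
        with pytest.raises(ValueError):
            cluster_significance([np.ones(5), np.ones(5)], n_replicates=1000)
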