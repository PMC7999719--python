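"""Remapping index, consolidation traces, neuron classification, group
profiles and subgroup clustering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from abnremap import (
    GeneratorConfig,
    Hypnogram,
    classify_remapping_neurons,
    consolidation_activity_matrix,
    group_activity_profile,
    remap_fractions,
    remapping_index,
    remapping_trace,
    subgroup_similarity,
)
from abnremap.remapping import RemapLabel, ri_trend
from abnremap.similarity import session_vectors, similarity_matrix
from abnremap.synthetic import generate_experiment, generate_null_experiment
from conftest import build_experiment, make_train

A = np.array([1.0, 0.0])
C = np.array([0.0, 1.0])


class TestRemappingIndex:
    @pytest.mark.parametrize(
        "current, expected",
        [
            (np.array([1.0, 0.0]), 1.0),   # perfect match to the first bin
            (np.array([0.0, 1.0]), -1.0),  # perfect match to the last bin
            (np.array([1.0, 1.0]), 0.0),   # equidistant bisector
        ],
    )
    def test_anchor_values(self, current, expected):
        assert remapping_index(A, C, current) == expected

    def test_hand_computed_intermediate(self):
        # AD(A,Bt)=1-2/sqrt(5), AD(C,Bt)=1-1/sqrt(5)
        assert remapping_index(A, C, np.array([2.0, 1.0])) == pytest.approx(
            0.6793, abs=1e-4
        )

    def test_printed_convention_negates(self):
        bt = np.array([2.0, 1.0])
        assert remapping_index(A, C, bt, convention="printed") == pytest.approx(
            -remapping_index(A, C, bt)
        )

    def test_degenerate_equidistant_collinear(self):
        # first == last: both distances identical for any current vector
        v = np.array([1.0, 1.0])
        assert remapping_index(v, 2.0 * v, v) == 0.0

    @given(st.integers(0, 1000))
    @settings(max_examples=50, derandomize=True)
    def test_swap_antisymmetry_and_scale_invariance(self, seed):
        rng = np.random.default_rng(seed)
        first, last, current = (rng.uniform(0.01, 1.0, 6) for _ in range(3))
        ri = remapping_index(first, last, current)
        assert remapping_index(last, first, current) == pytest.approx(-ri)
        assert remapping_index(3.0 * first, last, 0.5 * current) == pytest.approx(ri)
        assert -1.0 <= ri <= 1.0


def _linear_neuron_experiment():
    """10 neurons over a 150-min consolidation recording; neuron n00 has
    strictly linearly increasing per-bin activity, the rest are constant."""
    trains = []
    for j in range(10):
        times = []
        for b in range(10):
            count = b + 1 if j == 0 else 3
            times.extend(b * 900.0 + 10.0 * np.arange(count))
        trains.append(
            make_train(sorted(times), neuron=f"n{j:02d}", session="consolidation")
        )
    return build_experiment(trains)


class TestConsolidationActivityMatrix:
    def test_150_minutes_gives_10_bins(self, crossfade_experiment):
        exp, _ = crossfade_experiment
        mat = consolidation_activity_matrix(exp)
        assert mat.raw.shape[0] == 10
        np.testing.assert_allclose(mat.bin_centers_min, 7.5 + 15.0 * np.arange(10))

    def test_peak_bin_scaled_to_one(self):
        mat = consolidation_activity_matrix(_linear_neuron_experiment())
        np.testing.assert_allclose(mat.scaled.max(axis=0), 1.0)
        assert mat.scaled[-1, 0] == 1.0  # the increasing neuron peaks last

    def test_sleep_filter_drops_wake_only_bins(self):
        exp = _linear_neuron_experiment()
        # first 1800 s purely wake, then alternating NREM/wake
        intervals = [(0.0, 1800.0, "wake")]
        t = 1800.0
        state = "NREM"
        while t < 9000.0:
            intervals.append((t, min(t + 450.0, 9000.0), state))
            t += 450.0
            state = "wake" if state == "NREM" else "NREM"
        exp.hypnogram = Hypnogram(tuple(intervals))
        mat = consolidation_activity_matrix(exp, state_filter="sleep")
        assert mat.bin_centers_min.min() > 30.0  # bins 0-1 have no sleep dwell

    def test_rem_only_refused_by_default(self, crossfade_experiment):
        exp, _ = crossfade_experiment
        with pytest.raises(ValueError, match="REM"):
            consolidation_activity_matrix(exp, state_filter="REM")


class TestRemappingTrace:
    def test_crossfade_trace_is_strongly_negative(self, crossfade_experiment):
        exp, _ = crossfade_experiment
        trace = remapping_trace(exp, "all")
        assert trace.ri[0] == pytest.approx(1.0)
        assert trace.ri[-1] == pytest.approx(-1.0)
        assert trace.pearson_r <= -0.8
        assert trace.slope < 0
        assert trace.pearson_p < 0.01

    def test_state_filtered_traces_share_the_trend(self, crossfade_experiment):
        exp, _ = crossfade_experiment
        for state in ("sleep", "wake"):
            trace = remapping_trace(exp, state)
            assert trace.pearson_r < -0.5
            assert np.all((-1.0 <= trace.ri) & (trace.ri <= 1.0))

    def test_trend_flips_under_time_reversal(self):
        rng = np.random.default_rng(0)
        t = 7.5 + 15.0 * np.arange(10)
        ri = np.linspace(1, -1, 10) + rng.normal(0, 0.05, 10)
        r, p, slope = ri_trend(t, ri)
        r_rev, _, slope_rev = ri_trend(t, ri[::-1])
        assert r_rev == pytest.approx(-r)
        assert slope_rev == pytest.approx(-slope)

    def test_null_trace_trend_is_weak(self, null_experiment):
        exp, _ = null_experiment
        trace = remapping_trace(exp, "all")
        # endpoints are pinned to +-1 by construction; interior bins carry
        # no planted order, so the fit is far from the crossfade regime
        assert trace.pearson_p > 1e-4 or abs(trace.slope) < 0.008


class TestClassifyRemappingNeurons:
    def test_linear_neuron_labelled_increasing(self):
        labels = classify_remapping_neurons(_linear_neuron_experiment())
        by_id = {lab.neuron_id: lab for lab in labels}
        assert by_id["n00"].label == "increasing"
        assert by_id["n00"].pearson_r == pytest.approx(1.0)
        assert all(
            by_id[f"n{j:02d}"].label == "non_remapping" for j in range(1, 10)
        )

    def test_null_population_discovery_rate(self):
        counts = []
        for seed in range(10):
            exp, _ = generate_null_experiment(GeneratorConfig(seed=seed))
            labels = classify_remapping_neurons(exp)
            counts.append(
                sum(1 for lab in labels if lab.label != "non_remapping")
            )
        assert np.mean(counts) <= 5.0

    def test_planted_fractions_recovered(self, crossfade_experiment):
        exp, truth = crossfade_experiment
        fractions = remap_fractions(classify_remapping_neurons(exp))
        assert abs(fractions["decreasing"] - 0.16) <= 0.08
        assert abs(fractions["increasing"] - 0.10) <= 0.08


class TestGroupActivityProfile:
    def test_single_neuron_groups_equal_their_values(self):
        trains = []
        # three neurons; n0 concentrates its activity in the learning windows
        for j in range(3):
            for session in ("preS", "postS", "consolidation", "test"):
                n_events = 20 if (j == 0 and session in ("preS", "postS")) else 5
                duration = {"preS": 600, "postS": 300, "consolidation": 9000,
                            "test": 600}[session]
                times = np.linspace(1.0, duration - 1.0, n_events)
                trains.append(
                    make_train(times, neuron=f"n{j}", session=session)
                )
        exp = build_experiment(trains)
        labels = [
            RemapLabel("n0", "m1", "decreasing", -1.0, 0.0, 0.0),
            RemapLabel("n1", "m1", "increasing", 1.0, 0.0, 0.0),
            RemapLabel("n2", "m1", "non_remapping", 0.0, 1.0, 1.0),
        ]
        profile = group_activity_profile(exp, labels, n_replicates=1000, seed=0)
        assert profile.group_sizes == {
            "decreasing": 1, "increasing": 1, "non_remapping": 1
        }
        # a one-neuron group's mean is that neuron's scaled value
        for group in ("decreasing", "increasing", "non_remapping"):
            for period in ("learning", "consolidation", "test"):
                assert 0.0 <= profile.means[group][period] <= 1.0
        assert (
            profile.means["decreasing"]["learning"]
            > profile.means["decreasing"]["test"]
        )

    def test_crossfade_order_reversal(self, crossfade_experiment):
        """Decreasing neurons dominate learning; increasing dominate test."""
        exp, _ = crossfade_experiment
        labels = classify_remapping_neurons(exp)
        profile = group_activity_profile(exp, labels, n_replicates=2000, seed=3)
        means = profile.means
        assert means["decreasing"]["learning"] > means["increasing"]["learning"]
        assert means["increasing"]["test"] > means["decreasing"]["test"]
        assert profile.comparisons["learning"].significant
        assert profile.comparisons["test"].significant

    def test_permuted_labels_rarely_significant(self, crossfade_experiment):
        """Shuffling group labels destroys the contrast almost always.

        The percentile bootstrap is mildly anticonservative at these
        group sizes (about ten neurons), so the clean fraction sits a
        few points below the Bonferroni-nominal level rather than at
        1 - alpha; the bound reflects that known inflation.
        """
        exp, _ = crossfade_experiment
        labels = classify_remapping_neurons(exp)
        rng = np.random.default_rng(4)
        names = [lab.label for lab in labels]
        n_perms, clean = 200, 0
        for i in range(n_perms):
            shuffled = [
                RemapLabel(lab.neuron_id, lab.mouse_id, name, 0.0, 1.0, 1.0)
                for lab, name in zip(labels, rng.permutation(names))
            ]
            profile = group_activity_profile(
                exp, shuffled, n_replicates=1000, seed=1000 + i
            )
            clean += not any(r.significant for r in profile.comparisons.values())
        assert clean / n_perms >= 0.80
        # the true labels, by contrast, always show the planted contrast
        true_profile = group_activity_profile(exp, labels, n_replicates=1000, seed=0)
        assert any(r.significant for r in true_profile.comparisons.values())


class TestSubgroupSimilarity:
    def test_all_neurons_subgroup_matches_full_analysis(self, crossfade_experiment):
        exp, _ = crossfade_experiment
        labels = [
            RemapLabel(n, m, "non_remapping", 0.0, 1.0, 1.0)
            for m, n in exp.neuron_index
        ]
        result = subgroup_similarity(exp, labels, n_replicates=1000, seed=5)
        assert set(result) == {"non_remapping"}
        sim, _ = result["non_remapping"]
        full = similarity_matrix(session_vectors(exp))
        np.testing.assert_allclose(sim.values, full.values, atol=1e-12)

    def test_remapping_subgroup_has_significant_structure(self, crossfade_experiment):
        exp, _ = crossfade_experiment
        labels = classify_remapping_neurons(exp)
        result = subgroup_similarity(exp, labels, n_replicates=2000, seed=6)
        _, clusters = result["remapping"]
        assert clusters.n_significant_clusters >= 1

    def test_null_subgroup_has_no_significant_structure(self, null_experiment):
        exp, _ = null_experiment
        labels = [
            RemapLabel(n, m, "non_remapping", 0.0, 1.0, 1.0)
            for m, n in exp.neuron_index
        ]
        result = subgroup_similarity(exp, labels, n_replicates=2000, seed=7)
        _, clusters = result["non_remapping"]
        assert clusters.n_significant_clusters == 0

    def test_tiny_subgroup_skipped_with_warning(self, crossfade_experiment):
        exp, _ = crossfade_experiment
        labels = [
            RemapLabel(n, m, "non_remapping", 0.0, 1.0, 1.0)
            for m, n in exp.neuron_index
        ]
        with pytest.warns(UserWarning, match="skipped"):
            result = subgroup_similarity(exp, labels, n_replicates=1000, seed=8)
        assert "remapping" not in result
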