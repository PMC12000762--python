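import dataclasses
import itertools

import numpy as np
import pytest

from callcensus import cluster as cl
from callcensus.dsp import compute_spectrogram
from callcensus.synth import render_call, sample_population


def block_matrix(k, per, within, between, noise=0.0, seed=0):
    """Synthetic similarity matrix with k blocks of `per` calls."""
    n = k * per
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(k), per)
    v = np.where(labels[:, None] == labels[None, :], within, between).astype(float)
    if noise:
        jitter = rng.normal(0, noise, size=(n, n))
        v += (jitter + jitter.T) / 2
    np.fill_diagonal(v, 1.0)
    return v, labels


@pytest.fixture(scope="module")
def call_pair():
    rng = np.random.default_rng(2)
    (prof,) = sample_population(1, seed=rng)
    audio, _ = render_call(prof, snr_db=25, seed=3)
    return compute_spectrogram(audio)


class TestSpcc:
    def test_self_similarity_is_one(self, call_pair):
        assert cl.spcc(call_pair, call_pair) == pytest.approx(1.0, abs=1e-9)

    def test_time_shift_absorbed_by_lag_search(self, call_pair):
        shifted = dataclasses.replace(
            call_pair,
            magnitudes=np.pad(call_pair.magnitudes, ((0, 0), (40, 0))),
        )
        assert cl.spcc(call_pair, shifted) == pytest.approx(1.0, abs=1e-6)

    def test_independent_noise_pairs_dissimilar(self):
        rng = np.random.default_rng(0)
        sims = []
        for _ in range(100):
            a = compute_spectrogram(rng.normal(0, 1, 11_025))
            b = compute_spectrogram(rng.normal(0, 1, 11_025))
            sims.append(cl.spcc(a, b))
        assert np.mean(sims) < 0.3

    def test_mismatched_resolution_rejected(self, call_pair):
        other = dataclasses.replace(call_pair, dt=call_pair.dt * 2)
        with pytest.raises(ValueError, match="dt"):
            cl.spcc(call_pair, other)

    def test_amplitude_invariance(self, call_pair):
        scaled = dataclasses.replace(
            call_pair, magnitudes=call_pair.magnitudes * 9.0
        )
        assert cl.spcc(call_pair, scaled) == pytest.approx(1.0, abs=1e-9)


class TestSimilarityMatrix:
    def test_identical_calls_give_all_ones(self, call_pair):
        m = cl.similarity_matrix([call_pair] * 3)
        np.testing.assert_allclose(m.values, 1.0, atol=1e-9)

    def test_symmetric_unit_diagonal(self, small_corpus):
        small_corpus["matrix"].validate()

    def test_each_pair_computed_once(self, call_pair, monkeypatch):
        calls = []
        orig = cl._spcc_pair

        def counting(*args, **kwargs):
            calls.append(1)
            return orig(*args, **kwargs)

        monkeypatch.setattr(cl, "_spcc_pair", counting)
        # a 100 Hz shift bound admits row shifts, forcing the per-pair path
        cl.similarity_matrix([call_pair] * 5, max_freq_shift_hz=100.0)
        assert len(calls) == 5 * 4 // 2

    def test_block_structure_recovered(self, small_corpus):
        m, labels = small_corpus["matrix"], small_corpus["labels"]
        same = labels[:, None] == labels[None, :]
        iu = np.triu_indices(m.n, 1)
        assert m.values[iu][same[iu]].mean() > m.values[iu][~same[iu]].mean()


class TestCompareWithinBetween:
    def test_identical_distributions_give_small_D(self):
        rng = np.random.default_rng(1)
        v = rng.uniform(0, 1, size=(40, 40))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        labels = np.repeat(np.arange(8), 5)
        rng.shuffle(labels)  # labels unrelated to values
        res = cl.compare_within_between(v, labels)
        assert res.ks_D < 0.2

    def test_disjoint_supports_give_D_one(self):
        v, labels = block_matrix(4, 4, within=0.9, between=0.1)
        res = cl.compare_within_between(v, labels)
        assert res.ks_D == pytest.approx(1.0)
        assert res.mean_same == pytest.approx(0.9)
        assert res.mean_diff == pytest.approx(0.1)

    def test_single_group_rejected(self):
        v, _ = block_matrix(1, 5, within=0.9, between=0.1)
        with pytest.raises(ValueError):
            cl.compare_within_between(v, np.zeros(5))


class TestHopkins:
    def test_uniform_embedding_near_half(self):
        """Null behaviour: H ~ 0.5 for unstructured points (mean over 50
        replicates within +/-0.05)."""
        vals = [
            cl.hopkins_statistic(
                np.random.default_rng(s).uniform(0, 1, size=(60, 6)),
                seed=10_000 + s,
            )
            for s in range(50)
        ]
        assert abs(np.mean(vals) - 0.5) <= 0.05

    def test_five_blocks_strongly_clusterable(self):
        v, _ = block_matrix(5, 10, within=0.9, between=0.1, noise=0.02, seed=2)
        h = np.mean([cl.hopkins_statistic(v, seed=s) for s in range(10)])
        assert h > 0.8

    def test_duplicated_points_with_jitter_approach_one(self):
        rng = np.random.default_rng(3)
        X = np.tile(rng.uniform(size=(1, 8)), (50, 1)) + rng.normal(
            0, 1e-4, size=(50, 8)
        )
        # one distant straggler so the bounding box is non-degenerate
        X[0] += 1.0
        assert cl.hopkins_statistic(X, seed=0) > 0.95

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            cl.hopkins_statistic(np.ones((20, 20)), seed=0)


def ap_net_similarity(S, exemplars, pref):
    """Frey-Dueck objective for an exemplar set on similarity matrix S."""
    E = np.asarray(sorted(exemplars))
    assign = E[np.argmax(S[:, E], axis=1)]
    assign[E] = E
    total = sum(S[i, assign[i]] for i in range(len(S)) if i not in set(E))
    return total + pref * len(E)


class TestAPCluster:
    def test_two_blocks_recovered(self):
        v, labels = block_matrix(2, 6, within=0.9, between=0.1, noise=0.01)
        res = cl.ap_cluster(v, seed=0)
        assert res.n_clusters == 2
        got = res.labels()
        for block in (labels == 0, labels == 1):
            assert len(set(got[block])) == 1

    def test_large_preference_forces_singletons(self):
        v, _ = block_matrix(2, 5, within=0.9, between=0.1, noise=0.01)
        res = cl.ap_cluster(v, preference=10.0, seed=0)
        assert res.n_clusters == v.shape[0]

    def test_exemplars_self_assigned(self):
        v, _ = block_matrix(3, 5, within=0.8, between=0.2, noise=0.02)
        res = cl.ap_cluster(v, seed=1)
        for e in res.exemplars:
            assert res.assignment[e] == e

    def test_matches_exhaustive_optimum_on_small_instances(self):
        """On n <= 8 separable instances the exemplar set's net similarity
        matches the brute-force optimum in >= 80% of 50 runs."""
        hits = 0
        for s in range(50):
            rng = np.random.default_rng(s)
            k = rng.integers(2, 4)
            per = rng.integers(2, 5)
            n = int(k * per)
            if n > 8:
                per = 8 // k
                n = int(k * per)
            v, _ = block_matrix(int(k), int(per), within=0.9, between=0.1,
                                noise=0.05, seed=s)
            pref = cl.median_preference(v)
            res = cl.ap_cluster(v, seed=s)
            ours = ap_net_similarity(v, res.exemplars, pref)
            best = max(
                ap_net_similarity(v, E, pref)
                for r in range(1, n + 1)
                for E in itertools.combinations(range(n), r)
            )
            if ours >= best - 1e-9:
                hits += 1
        assert hits >= 40

    def test_cluster_count_monotone_in_preference(self):
        v, _ = block_matrix(4, 5, within=0.8, between=0.2, noise=0.03, seed=5)
        prefs = [-2.0, -0.5, 0.2, 0.6, 2.0]
        counts = [cl.ap_cluster(v, preference=p, seed=0).n_clusters for p in prefs]
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_permutation_equivariance(self):
        v, _ = block_matrix(3, 5, within=0.85, between=0.15, noise=0.02, seed=6)
        res = cl.ap_cluster(v, seed=0)
        rng = np.random.default_rng(7)
        perm = rng.permutation(v.shape[0])
        vp = v[np.ix_(perm, perm)]
        res_p = cl.ap_cluster(vp, seed=0)
        # cluster partitions agree under the permutation
        ours = res.labels()[perm]
        theirs = res_p.labels()
        mapping = {}
        for a, b in zip(ours, theirs):
            mapping.setdefault(a, b)
            assert mapping[a] == b

    def test_all_negative_similarities_fall_back_to_one_cluster(self):
        v = -np.ones((6, 6))
        res = cl.ap_cluster(v, preference=-100.0, seed=0)
        assert res.n_clusters >= 1

    def test_agrees_with_reference_implementation(self):
        """Independent cross-check against sklearn's affinity propagation
        on a well-separated instance."""
        from sklearn.cluster import AffinityPropagation

        v, labels = block_matrix(4, 6, within=0.85, between=0.15, noise=0.02,
                                 seed=9)
        res = cl.ap_cluster(v, damping=0.9, seed=0)
        ref = AffinityPropagation(
            affinity="precomputed", damping=0.9, random_state=0
        ).fit(v)
        assert res.n_clusters == len(ref.cluster_centers_indices_)
        # identical partitions up to relabeling
        ours, theirs = res.labels(), ref.labels_
        mapping = {}
        for a, b in zip(ours, theirs):
            mapping.setdefault(a, b)
            assert mapping[a] == b

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            cl.ap_cluster(np.zeros((3, 4)))
        with pytest.raises(ValueError):
            cl.ap_cluster(np.full((3, 3), np.nan))
        with pytest.raises(ValueError):
            cl.ap_cluster(np.eye(3), damping=0.3)


class TestClusteringAccuracy:
    def test_perfect_blocks(self):
        _, labels = block_matrix(3, 4, 0.9, 0.1)
        correct, rate = cl.clustering_accuracy(labels, labels)
        assert (correct, rate) == (12, 1.0)

    @pytest.mark.parametrize(
        "correct,total,expected", [(169, 170, 99.41), (165, 200, 82.5)]
    )
    def test_field_scale_rates(self, correct, total, expected):
        # singleton clusters except `total - correct` distinct-label calls
        # folded into call 0's cluster, where each is a minority member
        m = total - correct
        assignment = np.arange(total)
        assignment[1 : m + 1] = 0
        labels = np.array([f"bird{i}" for i in range(total)])
        got_correct, rate = cl.clustering_accuracy(assignment, labels)
        assert got_correct == correct
        assert round(100 * rate, 2) == expected


class TestCountAndValidate:
    def test_count_individuals_is_cluster_count(self):
        v, _ = block_matrix(5, 4, 0.9, 0.1, noise=0.02)
        res = cl.ap_cluster(v, seed=0)
        assert cl.count_individuals(res) == res.n_clusters

    def test_single_individual_counts_one(self):
        # preference below the (uniform) within similarity: splitting a
        # single true cluster never pays
        v, _ = block_matrix(1, 6, 0.9, 0.1, noise=0.01)
        res = cl.ap_cluster(v, preference=0.0, seed=0)
        assert cl.count_individuals(res) == 1

    def test_home_range_diameter(self):
        assert cl.home_range_diameter_m(11.0) == pytest.approx(374.2, abs=0.5)

    def test_colocated_clusters_fully_validated(self):
        v, labels = block_matrix(3, 5, within=0.9, between=0.1, noise=0.01)
        res = cl.ap_cluster(v, seed=0)
        coords = np.array([[labels[i] * 1000.0, 0.0] for i in range(len(labels))])
        m = cl.SimilarityMatrix(values=v, call_ids=[str(i) for i in range(15)],
                                coordinates=coords)
        verdicts, acc = cl.validate_wild_clusters(res, m, sample_n=15, seed=0)
        assert acc == 1.0

    def test_distant_same_cluster_calls_fail_spatial_rule(self):
        # one cluster whose members sit 1 km apart: spatial test fails
        v, labels = block_matrix(2, 5, within=0.9, between=0.1, noise=0.01)
        res = cl.ap_cluster(v, seed=0)
        coords = np.zeros((10, 2))
        coords[labels == 0, 0] = np.linspace(0, 1000.0, 5)  # spread 1 km
        m = cl.SimilarityMatrix(values=v, call_ids=[str(i) for i in range(10)],
                                coordinates=coords)
        verdicts, acc = cl.validate_wild_clusters(res, m, sample_n=10, seed=0)
        spread_calls = [v_ for v_, lab in zip(verdicts, labels) if lab == 0]
        assert any(not v_["spatial_ok"] for v_ in spread_calls)

    def test_missing_coordinates_rejected(self):
        v, _ = block_matrix(2, 5, 0.9, 0.1)
        res = cl.ap_cluster(v, seed=0)
        m = cl.SimilarityMatrix(values=v, call_ids=[str(i) for i in range(10)])
        with pytest.raises(ValueError, match="coordinates"):
            cl.validate_wild_clusters(res, m)
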