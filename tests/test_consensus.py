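import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from omicsfuse import (
    SolverConfig,
    ari,
    ccc,
    cluster_network,
    ncut_labels,
    pac,
    run_resampled,
    select_eta,
    select_rank,
    weighted_consensus,
)
from omicsfuse.consensus import RunEnsemble, RunRecord, within_cluster_similarity_score

from conftest import random_network
from oracles import (
    best_bipartition,
    cophenetic_matrix_from_linkage,
    ncut_value,
    weighted_consensus_bruteforce,
)


def make_ensemble(runs, n, r=2):
    return RunEnsemble(
        [RunRecord(np.asarray(i), np.asarray(l), re) for i, l, re in runs],
        n,
        r,
        0.95,
    )


def block_consensus(sizes, within=1.0, between=0.0):
    n = sum(sizes)
    C = np.full((n, n), between)
    start = 0
    for s in sizes:
        C[start : start + s, start : start + s] = within
        start += s
    np.fill_diagonal(C, 1.0)
    return C


class TestRunResampled:
    def test_keep_fraction_one_sees_all(self, two_layer_network):
        ens = run_resampled(
            two_layer_network, SolverConfig(r=2), n_runs=2, keep_fraction=1.0,
            seed=0,
        )
        for rec in ens.runs:
            assert len(rec.indices) == two_layer_network.n

    def test_subset_size_95_percent(self, two_layer_network):
        # floor(0.95 * 24) = 22
        ens = run_resampled(
            two_layer_network, SolverConfig(r=2), n_runs=3, keep_fraction=0.95,
            seed=0,
        )
        for rec in ens.runs:
            assert len(rec.indices) == 22
            assert len(rec.labels) == 22

    def test_default_sixty_runs(self, two_layer_network):
        ens = run_resampled(two_layer_network, SolverConfig(r=2), seed=0)
        assert ens.n_runs == 60

    def test_every_sample_covered(self, two_layer_network):
        ens = run_resampled(
            two_layer_network, SolverConfig(r=2), n_runs=4, keep_fraction=0.8,
            seed=3,
        )
        covered = np.zeros(two_layer_network.n, dtype=bool)
        for rec in ens.runs:
            covered[rec.indices] = True
        assert covered.all()

    def test_runs_differ(self, two_layer_network):
        # same full-sample subset, iteration-capped: the perturbed core
        # initializations must leave a trace in the residual errors
        ens = run_resampled(
            two_layer_network, SolverConfig(r=2, max_iter=10), n_runs=4,
            keep_fraction=1.0, seed=0,
        )
        assert len({rec.RE for rec in ens.runs}) > 1

    def test_ensemble_deterministic_under_seed(self, two_layer_network):
        a = run_resampled(two_layer_network, SolverConfig(r=2), 3, 0.9, seed=5)
        b = run_resampled(two_layer_network, SolverConfig(r=2), 3, 0.9, seed=5)
        for x, y in zip(a.runs, b.runs):
            assert np.array_equal(x.indices, y.indices)
            assert np.array_equal(x.labels, y.labels)
            assert x.RE == y.RE

    def test_invalid_params(self, two_layer_network):
        with pytest.raises(ValueError):
            run_resampled(two_layer_network, SolverConfig(r=2), n_runs=0)
        with pytest.raises(ValueError):
            run_resampled(
                two_layer_network, SolverConfig(r=2), keep_fraction=0.0
            )


class TestWeightedConsensus:
    def test_printed_weight_formula(self):
        # RE = (2, 4, 6) -> weights (1, 0.5, 0)
        idx = np.arange(4)
        lab = np.array([0, 0, 1, 1])
        ens = make_ensemble(
            [(idx, lab, 2.0), (idx, lab, 4.0), (idx, lab, 6.0)], n=4
        )
        C = weighted_consensus(ens)
        # all runs agree -> consensus is the exact co-clustering matrix
        assert np.allclose(C, block_consensus([2, 2]))

    def test_all_agree_gives_one(self):
        idx = np.arange(3)
        ens = make_ensemble(
            [(idx, np.array([0, 0, 1]), 1.0), (idx, np.array([1, 1, 0]), 3.0)],
            n=3,
        )
        C = weighted_consensus(ens)
        assert C[0, 1] == 1.0 and C[0, 2] == 0.0

    def test_mixed_agreement_matches_oracle(self):
        runs = [
            (np.array([0, 1, 2]), np.array([0, 0, 1]), 2.0),
            (np.array([0, 1, 3]), np.array([0, 1, 1]), 4.0),
            (np.array([0, 1, 2, 3]), np.array([0, 0, 0, 1]), 6.0),
        ]
        ens = make_ensemble(runs, n=4)
        C = weighted_consensus(ens)
        expected = weighted_consensus_bruteforce(runs, 4)
        assert np.allclose(C, expected, atol=1e-12)
        # spot check: pair (0,1) co-sampled in all runs with weights 1,.5,0
        assert np.isclose(C[0, 1], (1 * 1 + 0.5 * 0 + 0 * 1) / 1.5)

    def test_equal_re_degenerate_weights(self):
        idx = np.arange(3)
        ens = make_ensemble(
            [(idx, np.array([0, 0, 1]), 5.0), (idx, np.array([0, 1, 1]), 5.0)],
            n=3,
        )
        C = weighted_consensus(ens)
        assert np.isclose(C[0, 1], 0.5)

    def test_never_cosampled_pair_zero(self):
        runs = [
            (np.array([0, 1]), np.array([0, 0]), 1.0),
            (np.array([2, 3]), np.array([0, 0]), 2.0),
        ]
        ens = make_ensemble(runs, n=4)
        C = weighted_consensus(ens)
        assert C[0, 2] == 0.0

    def test_empty_rejected(self):
        ens = make_ensemble([(np.arange(2), np.zeros(2, dtype=int), 1.0)], n=2)
        with pytest.raises(ValueError):
            weighted_consensus(ens, run_subset=[])

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 1000))
    def test_property_entries_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        n = 6
        runs = []
        for _ in range(4):
            idx = np.sort(rng.choice(n, size=5, replace=False))
            runs.append(
                (idx, rng.integers(0, 2, size=5), float(rng.uniform(1, 9)))
            )
        C = weighted_consensus(make_ensemble(runs, n=n))
        assert np.all(C >= 0.0) and np.all(C <= 1.0)
        assert np.allclose(C, C.T)

    def test_increasing_agreement_never_increases_pac(self):
        idx = np.arange(6)
        base = np.array([0, 0, 0, 1, 1, 1])
        noisy = np.array([0, 1, 0, 1, 0, 1])
        mostly = [(idx, base, 1.0)] * 3 + [(idx, noisy, 1.0)] * 3
        all_agree = [(idx, base, 1.0)] * 6
        p_noisy = pac(weighted_consensus(make_ensemble(mostly, 6)))
        p_clean = pac(weighted_consensus(make_ensemble(all_agree, 6)))
        assert p_clean <= p_noisy


class TestNcutLabels:
    def test_exact_two_block(self):
        C = block_consensus([4, 4])
        labels = ncut_labels(C, 2, seed=0)
        assert ari([0] * 4 + [1] * 4, labels) == 1.0

    def test_r_one_single_label(self):
        C = block_consensus([3, 3])
        assert set(ncut_labels(C, 1)) == {0}

    def test_matches_exhaustive_ncut_search(self, rng):
        # noisy 2-block consensus, n=8: exhaustive bipartition oracle
        for seed in range(5):
            g = np.random.default_rng(seed)
            C = block_consensus([4, 4], within=0.9, between=0.1)
            noise = g.uniform(-0.08, 0.08, size=(8, 8))
            C = np.clip(C + (noise + noise.T) / 2, 0, 1)
            np.fill_diagonal(C, 1.0)
            ours = ncut_labels(C, 2, seed=0)
            best_lab, best_val = best_bipartition(C)
            assert np.isclose(ncut_value(C, ours), best_val, atol=1e-9)
            assert ari(ours, best_lab) == 1.0

    def test_asymmetric_rejected(self):
        C = np.array([[1.0, 0.2], [0.8, 1.0]])
        with pytest.raises(ValueError):
            ncut_labels(C, 2)


class TestPac:
    def test_binary_consensus_zero(self):
        assert pac(block_consensus([3, 3])) == 0.0

    def test_all_half_is_one(self):
        C = np.full((5, 5), 0.5)
        np.fill_diagonal(C, 1.0)
        assert pac(C) == 1.0

    def test_counting_inside_open_interval(self):
        # 6 off-diagonal entries: (0.05, 0.5, 0.95, 0.2, 0.5, 0.95)
        # inside (0.1, 0.9): 0.5, 0.2, 0.5 -> PAC = 3/6 = 0.5
        C = np.eye(4)
        vals = [0.05, 0.5, 0.95, 0.2, 0.5, 0.95]
        iu = np.triu_indices(4, k=1)
        C[iu] = vals
        C = C + C.T - np.diag(np.diag(C))
        np.fill_diagonal(C, 1.0)
        assert pac(C) == 0.5

    def test_boundaries_excluded(self):
        C = np.eye(3)
        iu = np.triu_indices(3, k=1)
        C[iu] = [0.1, 0.9, 0.5]
        C = C + C.T - np.diag(np.diag(C))
        np.fill_diagonal(C, 1.0)
        assert pac(C) == pytest.approx(1 / 3)

    def test_too_small(self):
        with pytest.raises(ValueError):
            pac(np.ones((1, 1)))


class TestCcc:
    def test_perfect_two_block_is_one(self):
        C = block_consensus([4, 4])
        assert np.isclose(ccc(C), 1.0)

    def test_constant_returns_nan(self):
        C = np.full((4, 4), 0.5)
        np.fill_diagonal(C, 1.0)
        # dissimilarity 1-C is constant off-diagonal... still two distinct
        # values incl. diagonal 0s; truly constant case:
        C2 = np.ones((4, 4))
        assert np.isnan(ccc(C2))

    def test_matches_tree_traversal_oracle(self, rng):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform
        from scipy.stats import pearsonr

        for seed in range(4):
            g = np.random.default_rng(seed)
            M = g.uniform(0.0, 1.0, size=(6, 6))
            C = (M + M.T) / 2
            np.fill_diagonal(C, 1.0)
            D = 1.0 - C
            np.fill_diagonal(D, 0.0)
            dvec = squareform(D, checks=False)
            Z = linkage(dvec, method="average")
            coph = cophenetic_matrix_from_linkage(Z, 6)
            cvec = squareform(coph, checks=False)
            expected = pearsonr(cvec, dvec).statistic
            assert np.isclose(ccc(C), expected, atol=1e-10)


class TestStableEnsembleInvariant:
    def test_identical_runs_give_pac_zero_ccc_one(self):
        idx = np.arange(9)
        lab = np.array([0] * 3 + [1] * 3 + [2] * 3)
        ens = make_ensemble([(idx, lab, float(i + 1)) for i in range(5)], n=9, r=3)
        C = weighted_consensus(ens)
        assert pac(C) == 0.0
        assert np.isclose(ccc(C), 1.0)


class TestSelectRank:
    def test_three_blob_recommends_three(self):
        # pilot-validated: separable 3-cluster cohort, ranks 2..4 (the full
        # 2..6 sweep lives in the acceptance suite)
        from omicsfuse import build_network, make_blobs, replicate_layer

        c = replicate_layer(make_blobs(45, 30, 3, 0.4, seed=13), 2)
        net = build_network(c.layers)
        sel = select_rank(
            net, range(2, 5), n_runs=12, subset_size=10, n_subsets=4, seed=0
        )
        assert 3 in sel.recommended
        row = sel.table.set_index("rank").loc[3]
        assert row["median_pac"] < 0.1 and row["median_ccc"] > 0.95
        assert ari(c.truth_labels, sel.results[3].labels) == 1.0

    def test_single_rank_report(self, two_layer_network):
        sel = select_rank(
            two_layer_network, [2], n_runs=5, subset_size=4, n_subsets=2, seed=0
        )
        assert list(sel.table["rank"]) == [2]

    def test_rank_ge_n_skipped(self, two_layer_network):
        sel = select_rank(
            two_layer_network, [2, 1000], n_runs=4, subset_size=3,
            n_subsets=2, seed=0,
        )
        assert list(sel.table["rank"]) == [2]

    def test_empty_range_rejected(self, two_layer_network):
        with pytest.raises(ValueError):
            select_rank(two_layer_network, [])


class TestSelectEta:
    def test_single_candidate_returned(self, two_layer_network):
        eta, table = select_eta(
            two_layer_network, [0.37], r=2, n_runs=4, seed=0
        )
        assert eta == 0.37
        assert len(table) == 1

    def test_score_matches_double_loop_oracle(self, rng):
        net = random_network(rng, n=6, t=2)
        labels = np.array([0, 0, 0, 1, 1, 1])
        s = within_cluster_similarity_score(net, labels)
        expected = 0.0
        for lay in net.layers:
            A = np.nan_to_num(lay.A)
            tot = 0.0
            for c in (0, 1):
                members = [i for i in range(6) if labels[i] == c]
                for ii, a in enumerate(members):
                    for b in members[ii + 1:]:
                        if lay.W[a, b] > 0:
                            tot += A[a, b]
            expected += tot / lay.n_layer**2
        assert np.isclose(s, expected, atol=1e-12)

    def test_empty_candidates(self, two_layer_network):
        with pytest.raises(ValueError):
            select_eta(two_layer_network, [], r=2)


class TestClusterNetwork:
    def test_end_to_end_separable(self, two_layer_cohort, two_layer_network):
        res = cluster_network(
            two_layer_network, 2, n_runs=8, n_subsets=3, seed=0
        )
        assert ari(two_layer_cohort.truth_labels, res.labels) == 1.0
        assert res.pac == 0.0
        assert len(res.pac_dist) == 3
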