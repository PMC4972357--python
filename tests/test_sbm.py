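import numpy as np
import pytest

from multiweb.sbm import (
    MultiplexSBM,
    adjusted_rand,
    emission_logprob,
    layer_subset_fit,
    outcome_codes,
    robustness_to_removal,
    trophic_cascade,
)
from multiweb.synth import planted_multiplex, separable_theta
from conftest import make_net


def brute_force_ari(p1, p2):
    """Contingency-table adjusted Rand, computed from first principles."""
    from math import comb

    p1, p2 = np.asarray(p1), np.asarray(p2)
    n = len(p1)
    cats1, cats2 = np.unique(p1), np.unique(p2)
    table = np.array([[np.sum((p1 == a) & (p2 == b)) for b in cats2] for a in cats1])
    sum_ij = sum(comb(int(x), 2) for x in table.ravel())
    sum_a = sum(comb(int(x), 2) for x in table.sum(axis=1))
    sum_b = sum(comb(int(x), 2) for x in table.sum(axis=0))
    expected = sum_a * sum_b / comb(n, 2)
    maximum = (sum_a + sum_b) / 2
    if maximum == expected:
        return 1.0
    return (sum_ij - expected) / (maximum - expected)


class TestEmission:
    def test_uniform_cells(self):
        theta = np.full(8, 1 / 8)
        assert emission_logprob((1, 0, 1), theta) == pytest.approx(np.log(1 / 8))

    def test_degenerate_mass(self):
        eps = 1e-10
        theta = np.full(8, eps)
        theta[0] = 1 - 7 * eps
        assert emission_logprob((0, 0, 0), theta) == pytest.approx(np.log(1 - 7 * eps))

    def test_normalization(self):
        rng = np.random.default_rng(3)
        theta = rng.dirichlet(np.ones(8))
        total = sum(np.exp(emission_logprob(((c >> 0) & 1, (c >> 1) & 1, (c >> 2) & 1), theta))
                    for c in range(8))
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_outcome_codes_little_endian(self):
        net = make_net(2, [(0, 1, "T"), (0, 1, "N")])
        codes = outcome_codes(net)
        assert codes[0, 1] == 1 + 4  # trophic bit 0, negative bit 2


class TestInit:
    def test_Q_equals_n_singletons(self, random_net):
        parts = MultiplexSBM(random_net).init_partitions(random_net.n, 1, seed=0)
        assert len(np.unique(parts[0])) == random_net.n

    def test_kmeans_recovers_planted_blocks(self):
        # two blocks with disjoint partner sets (dense within-block trophic
        # links only) are separated already by the unperturbed k-means start
        theta = separable_theta(2, p_in=0.8, p_out=0.02)
        net, z = planted_multiplex(40, 2, [0.5, 0.5], theta, seed=0)
        base = MultiplexSBM(net).init_partitions(2, 1, seed=1)[0]
        assert adjusted_rand(z, base) == 1.0

    def test_deterministic_given_seed(self, random_net):
        m = MultiplexSBM(random_net)
        a = m.init_partitions(3, 5, seed=7)
        b = m.init_partitions(3, 5, seed=7)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_perturbation_switches_5_to_15(self):
        theta = separable_theta(2)
        net, _ = planted_multiplex(40, 2, [0.5, 0.5], theta, seed=0)
        m = MultiplexSBM(net)
        parts = m.init_partitions(2, 10, seed=0)
        for p in parts[1:]:
            n_diff = int((p != parts[0]).sum())
            assert 1 <= n_diff <= 15

    def test_Q_too_large_errors(self, tiny_net):
        with pytest.raises(ValueError):
            MultiplexSBM(tiny_net).init_partitions(10, 1, seed=0)


class TestVEM:
    def test_single_cluster_closed_form(self, random_net):
        res = MultiplexSBM(random_net).fit(1)
        assert np.allclose(res.a, [1.0])
        codes = outcome_codes(random_net)
        n = random_net.n
        off = ~np.eye(n, dtype=bool)
        freq = np.bincount(codes[off], minlength=8) / (n * (n - 1))
        assert np.allclose(res.theta[0, 0], freq, atol=1e-8)

    def test_planted_three_blocks_recovered(self):
        theta = separable_theta(3)
        net, z = planted_multiplex(60, 3, [1 / 3] * 3, theta, seed=5)
        res = MultiplexSBM(net).fit_best(3, n_restarts=5, seed=0)
        assert adjusted_rand(z, res.membership) == 1.0

    def test_elbo_trace_monotone(self, random_net):
        res = MultiplexSBM(random_net).fit_best(3, n_restarts=3, seed=0)
        diffs = np.diff(res.elbo_trace)
        assert (diffs >= -1e-8).all()

    def test_normalization_invariants(self, random_net):
        res = MultiplexSBM(random_net).fit_best(3, n_restarts=3, seed=1)
        assert np.allclose(res.tau.sum(axis=1), 1.0, atol=1e-10)
        assert np.allclose(res.theta.sum(axis=2), 1.0, atol=1e-10)
        assert res.a.sum() == pytest.approx(1.0, abs=1e-10)

    def test_fit_best_at_least_single_run(self):
        theta = separable_theta(3)
        net, _ = planted_multiplex(45, 3, [1 / 3] * 3, theta, seed=2)
        m = MultiplexSBM(net)
        single = m.fit(3, seed=0)
        best = m.fit_best(3, n_restarts=5, seed=0)
        assert best.elbo >= single.elbo - 1e-9

    def test_label_permutation_invariance(self, random_net):
        m = MultiplexSBM(random_net)
        res = m.fit_best(3, n_restarts=3, seed=2)
        perm = np.array([2, 0, 1])
        tau_p = res.tau[:, perm]
        a_p = res.a[perm]
        theta_p = res.theta[np.ix_(perm, perm)]
        elbo_p = m._elbo(tau_p, a_p, np.log(np.maximum(theta_p, m.eps)))
        assert elbo_p == pytest.approx(res.elbo, abs=1e-6)


class TestICL:
    def test_single_cluster_penalty_closed_form(self, random_net):
        res = MultiplexSBM(random_net).fit(1)
        n = random_net.n
        expected = res.completed_loglik() - 3.5 * np.log(n * (n - 1))
        assert res.icl == pytest.approx(expected)

    def test_icl_below_completed_loglik(self, random_net):
        for Q in (1, 2, 4):
            res = MultiplexSBM(random_net).fit_best(Q, n_restarts=2, seed=0)
            assert res.icl <= res.completed_loglik()

    def test_planted_two_blocks_selected(self):
        theta = separable_theta(2)
        net, _ = planted_multiplex(50, 2, [0.5, 0.5], theta, seed=3)
        best = MultiplexSBM(net).select_Q(range(1, 6), n_restarts=3, seed=0)
        assert best.Q == 2
        assert len(best.scan_table) == 5

    def test_width_one_range(self, random_net):
        best = MultiplexSBM(random_net).select_Q([2], n_restarts=2, seed=0)
        assert best.Q == 2

    def test_pure_noise_selects_one(self):
        theta = separable_theta(1, p_in=0.15, p_out=0.15)
        net, _ = planted_multiplex(40, 1, [1.0], theta, seed=4)
        best = MultiplexSBM(net).select_Q(range(1, 5), n_restarts=2, seed=0)
        assert best.Q == 1


class TestAdjustedRand:
    def test_identical_and_permuted(self):
        p = np.array([0, 0, 1, 1, 2])
        assert adjusted_rand(p, p) == 1.0
        assert adjusted_rand(p, (p + 1) % 3) == 1.0

    def test_crossed_partitions_match_contingency_oracle(self):
        p1 = [0, 0, 1, 1]
        p2 = [0, 1, 0, 1]
        assert adjusted_rand(p1, p2) == pytest.approx(brute_force_ari(p1, p2))

    def test_random_partitions_match_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            p1 = rng.integers(0, 3, 20)
            p2 = rng.integers(0, 4, 20)
            assert adjusted_rand(p1, p2) == pytest.approx(brute_force_ari(p1, p2))

    def test_intersection_on_id_lists(self):
        ari = adjusted_rand([0, 0, 1], [0, 1], ids1=["a", "b", "c"], ids2=["a", "c"])
        assert ari == adjusted_rand([0, 1], [0, 1])

    def test_empty_intersection_errors(self):
        with pytest.raises(ValueError):
            adjusted_rand([0], [0], ids1=["a"], ids2=["b"])


class TestLayerSubset:
    def test_emission_cells_scale(self, random_net):
        m = MultiplexSBM(random_net, layers=("T", "N"))
        assert m.n_cells == 4
        res = m.fit(2, seed=0)
        assert res.theta.shape == (2, 2, 4)

    def test_full_subset_matches_full_fit(self, random_net):
        a = MultiplexSBM(random_net).fit_best(2, n_restarts=3, seed=9)
        b = layer_subset_fit(random_net, ("T", "P", "N"), 2, n_restarts=3, seed=9)
        assert a.elbo == pytest.approx(b.elbo)
        assert np.array_equal(a.membership, b.membership)

    def test_informative_vs_noise_layer(self):
        # block structure lives only in T; P is empty, N is unstructured noise
        rng = np.random.default_rng(0)
        n = 40
        z = np.repeat([0, 1], n // 2)
        T = np.zeros((n, n), dtype=np.int8)
        for i in range(n):
            for j in range(n):
                if i != j and z[i] == z[j]:
                    T[i, j] = rng.random() < 0.7
        N = (rng.random((n, n)) < 0.2).astype(np.int8)
        np.fill_diagonal(N, 0)
        from multiweb.net import MultiplexNet

        net = MultiplexNet(tuple(f"s{i}" for i in range(n)), T, np.zeros_like(T), N)
        res_T = layer_subset_fit(net, ("T",), 2, n_restarts=3, seed=1)
        res_N = layer_subset_fit(net, ("N",), 2, n_restarts=3, seed=1)
        assert adjusted_rand(z, res_T.membership) == 1.0
        assert adjusted_rand(z, res_N.membership) < 0.2


class TestRemovalRobustness:
    def test_cascade_on_linear_chain(self):
        # a eats b eats c; remove the basal resource c -> everything starves
        net = make_net(3, [(0, 1, "T"), (1, 2, "T")])
        assert trophic_cascade(net, [2]).size == 0
        # removing the top predator leaves the rest intact
        assert trophic_cascade(net, [0]).tolist() == [1, 2]

    def test_zero_removal_gives_ari_one(self):
        theta = separable_theta(2)
        net, _ = planted_multiplex(30, 2, [0.5, 0.5], theta, seed=1)
        ref = MultiplexSBM(net).fit_best(2, n_restarts=2, seed=0)
        table = robustness_to_removal(net, ref, fractions=[0.01], reps=2, seed=0,
                                      Q_range=[2], n_restarts=2)
        assert table["mean_ari"].iloc[0] == 1.0

    def test_planted_robust_to_small_removal(self):
        theta = separable_theta(3)
        net, _ = planted_multiplex(45, 3, [1 / 3] * 3, theta, seed=6)
        ref = MultiplexSBM(net).fit_best(3, n_restarts=3, seed=0)
        table = robustness_to_removal(net, ref, fractions=[0.1], reps=3, seed=1,
                                      Q_range=[2, 3, 4], n_restarts=3)
        assert table["mean_ari"].iloc[0] >= 0.9


def test_results_serialization_round_trip(tmp_path, random_net):
    res = MultiplexSBM(random_net).fit_best(2, n_restarts=2, seed=0)
    res.to_json(tmp_path / "m.json")
    import json

    doc = json.loads((tmp_path / "m.json").read_text())
    assert doc["Q"] == 2
    assert np.allclose(doc["theta"], res.theta)
    res.write_partition_csv(tmp_path / "p.csv")
    lines = (tmp_path / "p.csv").read_text().splitlines()
    assert lines[0] == "species_id,cluster"
    assert len(lines) == random_net.n + 1
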