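import numpy as np
import pytest

from multiweb.dynamics import (
    ClusterDynamics,
    ClusterWeb,
    DynParams,
    NTIMapping,
    aggregate_layers,
    cluster_web_from_sbm,
    compare_to_random_nti,
    functional_response,
    growth_modifier,
    mortality_rate,
    parameter_sweep,
    recruitment_rate,
    refuge_attack,
    relative_consumption,
    removal_experiment,
    rhs,
    rhs_trophic,
    simulate,
)
from multiweb.synth import facilitation_scenario
from conftest import make_net


def chain_web(k=2):
    """Node 0 eats node 1 (k=2) or a longer chain."""
    TR = np.zeros((k, k))
    for i in range(k - 1):
        TR[i, i + 1] = 1.0
    return ClusterWeb(tuple(f"n{i}" for i in range(k)), TR)


class TestTerms:
    def test_relative_consumption(self):
        TR = np.zeros((3, 3))
        TR[0, 1] = TR[0, 2] = 0.5
        TR[1, 2] = 1.0
        w = relative_consumption(TR)
        assert w[0] == 0.5 and w[1] == 1.0 and w[2] == 0.0

    def test_holling_ii_reduction(self):
        web = chain_web()
        p = DynParams.defaults(web, q=0.0)
        B = np.array([1.0, 0.7])
        F = functional_response(0, 1, B, web, p)
        w, b, h = 1.0, p.b[0, 1], p.h[0]
        assert F == pytest.approx(w * b * B[1] / (1 + w * h * b * B[1]))

    def test_saturation_limit(self):
        web = chain_web()
        p = DynParams.defaults(web)
        F = functional_response(0, 1, np.array([1.0, 1e12]), web, p)
        assert F == pytest.approx(1.0 / p.h[0], rel=1e-6)

    def test_two_identical_prey_split(self):
        TR = np.zeros((3, 3))
        TR[0, 1] = TR[0, 2] = 1.0
        web = ClusterWeb(("c", "p1", "p2"), TR)
        p = DynParams.defaults(web)
        B = np.array([1.0, 0.8, 0.8])
        F1 = functional_response(0, 1, B, web, p)
        F2 = functional_response(0, 2, B, web, p)
        assert F1 == pytest.approx(F2)
        # same total attack load in a single-prey web with w=0.5 gives 2*F1
        TRs = np.zeros((2, 2))
        TRs[0, 1] = 1.0
        web_s = ClusterWeb(("c", "p"), TRs)
        p_s = DynParams.defaults(web_s)
        F_single = (0.5 * p.b[0, 1] * 0.8) / (1 + 0.5 * p.h[0] * (p.b[0, 1] * 0.8 * 2))
        assert F1 == pytest.approx(F_single)

    def test_interference_reduces_feeding(self):
        # two predators of the same prey interfering with each other
        TR = np.zeros((3, 3))
        TR[0, 2] = TR[1, 2] = 1.0
        INT = np.zeros((3, 3))
        INT[1, 0] = 1.0
        web_no = ClusterWeb(("p1", "p2", "prey"), TR)
        web_int = ClusterWeb(("p1", "p2", "prey"), TR, INT=INT)
        p = DynParams.defaults(web_no, intneg=1.0)
        B = np.array([1.0, 1.0, 1.0])
        assert functional_response(0, 2, B, web_int, p) < functional_response(0, 2, B, web_no, p)


class TestModifierLimits:
    def setup_method(self):
        TR = np.zeros((2, 2))
        TR[0, 1] = 1.0
        REF = np.zeros((2, 2))
        REF[1, 1] = 1.0  # prey provides its own refuge, simplest driver
        self.web = ClusterWeb(("pred", "prey"), TR, REF=REF)
        self.p = DynParams.defaults(self.web, intpos=1.0)

    def test_refuge_no_facilitator(self):
        b = refuge_attack(np.array([1.0, 0.0]), self.web, self.p)
        assert b[0, 1] == self.p.b[0, 1]

    def test_refuge_infinite_facilitator_hits_floor(self):
        b = refuge_attack(np.array([1.0, 1e12]), self.web, self.p)
        assert b[0, 1] == pytest.approx(self.p.b_min[0, 1], rel=1e-6)

    def test_refuge_midpoint(self):
        b = refuge_attack(np.array([1.0, 1.0]), self.web, self.p)
        expected = self.p.b[0, 1] - (self.p.b[0, 1] - self.p.b_min[0, 1]) * 0.5
        assert b[0, 1] == pytest.approx(expected)

    def test_refuge_strict_form_additive_limit(self):
        self.p.strict_refuge = True
        b = refuge_attack(np.array([1.0, 1e12]), self.web, self.p)
        assert b[0, 1] == pytest.approx(self.p.b[0, 1] + self.p.b_min[0, 1], rel=1e-6)

    def test_growth_modifier_and_floor(self):
        COMP = np.zeros((2, 2))
        COMP[0, 1] = 1.0
        web = ClusterWeb(("k", "i"), np.zeros((2, 2)), COMP=COMP)
        p = DynParams.defaults(web, intneg=1.0)
        g = growth_modifier(np.array([0.3, 1.0]), web, p)
        assert g[1] == pytest.approx(0.7)
        g2 = growth_modifier(np.array([5.0, 1.0]), web, p)
        assert g2[1] == 0.0

    def test_recruitment_limits(self):
        REC = np.zeros((2, 2))
        REC[0, 1] = 1.0
        web = ClusterWeb(("f", "p"), np.zeros((2, 2)), REC=REC)
        p = DynParams.defaults(web, intpos=1.0)
        assert recruitment_rate(np.array([0.0, 1.0]), web, p)[1] == p.r[1]
        r_inf = recruitment_rate(np.array([1e12, 1.0]), web, p)[1]
        assert r_inf == pytest.approx(p.r[1] + p.r_max[1], rel=1e-6)
        r_mid = recruitment_rate(np.array([1.0, 1.0]), web, p)[1]
        assert r_mid == pytest.approx(p.r[1] + p.r_max[1] / 2)

    def test_mortality_limits_including_simultaneous(self):
        FAC = np.zeros((2, 2))
        FAC[0, 1] = 1.0
        MORT = np.zeros((2, 2))
        MORT[0, 1] = 1.0
        TR = np.zeros((2, 2))
        TR[1, 0] = 1.0  # make node 1 a consumer so x > 0
        web = ClusterWeb(("other", "i"), TR, FAC=FAC, MORT=MORT)
        p = DynParams.defaults(web, intpos=1.0, intneg=1.0)
        x = mortality_rate(np.array([0.0, 1.0]), web, p)
        assert x[1] == p.x[1]
        x_inf = mortality_rate(np.array([1e12, 1.0]), web, p)
        both = p.x_min[1] + (p.x_max[1] - p.x[1])
        assert x_inf[1] == pytest.approx(both, rel=1e-6)


class TestRHSAndSimulate:
    def test_logistic_producer(self):
        web = ClusterWeb(("p",), np.zeros((1, 1)))
        p = DynParams.defaults(web, K0=2.0)
        res = simulate(web, p, t_end=100)
        assert res.final[0] == pytest.approx(2.0, abs=1e-4)

    def test_producer_with_mortality_equilibrium(self):
        web = ClusterWeb(("p",), np.zeros((1, 1)))
        p = DynParams.defaults(web, K0=1.5)
        p.x = np.array([0.4])
        p.x_min = np.array([0.2])
        p.x_max = np.array([0.8])
        res = simulate(web, p, t_end=300)
        assert res.final[0] == pytest.approx(1.5 * (1 - 0.4 / 1.0), abs=1e-4)

    def test_zero_state_absorbing(self):
        web = chain_web(3)
        p = DynParams.defaults(web)
        assert np.array_equal(rhs(0.0, np.zeros(3), web, p), np.zeros(3))

    def test_starving_consumer_goes_extinct(self):
        web = ClusterWeb(("c",), np.zeros((1, 1)), producers=np.array([False]))
        p = DynParams.defaults(web)
        res = simulate(web, p, t_end=200)
        assert res.extinct == [0] and res.persistence == 0

    def test_clamped_stays_zero(self):
        web = ClusterWeb(("c", "p"), np.array([[0, 0], [0, 0.0]]),
                         producers=np.array([False, True]))
        p = DynParams.defaults(web)
        res = simulate(web, p, t_end=300)
        # once the consumer hits the threshold its trajectory is exactly 0
        traj = res.biomass[:, 0]
        first_zero = np.argmax(traj == 0.0)
        assert traj[first_zero:].max() == 0.0

    def test_persistence_plus_extinct_partition_nodes(self):
        net, z, prod = facilitation_scenario(4, seed=0)
        TR, P, N, labels = aggregate_layers(net, z)
        web = cluster_web_from_sbm((TR, P, N), NTIMapping(producers=prod))
        res = ClusterDynamics(web).simulate(t_end=150)
        assert res.persistence + len(res.extinct) == web.k

    def test_zero_nti_reduction_bitwise(self):
        rng = np.random.default_rng(3)
        k = 5
        TR = (rng.random((k, k)) < 0.4) * rng.random((k, k))
        np.fill_diagonal(TR, 0)
        TR[:2, :] = 0
        web = ClusterWeb(tuple(f"c{i}" for i in range(k)), TR)
        p = DynParams.defaults(web, q=0.1)
        for _ in range(10):
            B = rng.random(k) * 2
            assert np.array_equal(rhs(0, B, web, p), rhs_trophic(0, B, web, p))
        full = simulate(web, p, t_end=40)
        plain = simulate(web, p, t_end=40, rhs_fn=rhs_trophic)
        assert np.array_equal(full.biomass, plain.biomass)


class TestClusterWeb:
    def test_zero_theta_gives_empty_web(self):
        theta = np.zeros((2, 2, 8))
        theta[:, :, 0] = 1.0

        class Shim:
            pass

        shim = Shim()
        shim.theta = theta
        web = cluster_web_from_sbm(shim, NTIMapping(producers=np.array([True, False])))
        assert web.TR.sum() == 0 and web.COMP.sum() == 0

    def test_trophic_marginal(self):
        theta = np.zeros((1, 1, 8))
        theta[0, 0, 1] = 0.6  # trophic only
        theta[0, 0, 0] = 0.4
        shim = type("S", (), {"theta": theta})()
        web = cluster_web_from_sbm(shim, NTIMapping(producers=np.array([False])))
        assert web.TR[0, 0] == pytest.approx(0.6)

    def test_planted_marginals_round_trip(self):
        from multiweb.synth import separable_theta

        theta = separable_theta(3, p_in=0.5, p_out=0.1, p_pos_in=0.3, p_neg_out=0.2)
        shim = type("S", (), {"theta": theta})()
        web = cluster_web_from_sbm(shim, NTIMapping(producers=np.zeros(3, bool)))
        codes = np.arange(8)
        TR = theta[:, :, (codes & 1) > 0].sum(axis=2)
        assert np.allclose(web.TR, TR)
        POS = theta[:, :, (codes & 2) > 0].sum(axis=2)
        total_pos = sum(getattr(web, nm).sum() for nm in ("REC", "REF", "FAC"))
        assert total_pos == pytest.approx(POS.sum())

    def test_plankton_substitution(self):
        TR = np.array([[0, 0.5], [0.0, 0]])
        web = cluster_web_from_sbm((TR, np.zeros((2, 2)), np.zeros((2, 2))),
                                   plankton_cluster=0)
        assert web.TR[0].sum() == 0 and web.producers[0]

    def test_aggregation_frequencies(self):
        net = make_net(4, [(0, 2, "T"), (1, 2, "T"), (0, 3, "T")])
        z = [0, 0, 1, 1]
        TR, P, N, labels = aggregate_layers(net, z)
        # 3 of the 4 ordered pairs between block 0 and block 1 carry a link
        assert TR[0, 1] == pytest.approx(3 / 4)
        assert TR[1, 0] == 0.0 and P.sum() == 0


class TestExperiments:
    def test_removing_isolated_node_harmless(self):
        TR = np.zeros((2, 2))
        web = ClusterWeb(("a", "b"), TR)
        p = DynParams.defaults(web)
        sec, var = removal_experiment(web, p, 1, t_end=100)
        assert sec == 0

    def test_removing_sole_producer_starves_consumer(self):
        web = chain_web(2)  # node 0 eats node 1; node 1 is the producer
        p = DynParams.defaults(web)
        sec, var = removal_experiment(web, p, 1, t_end=300)
        assert sec == 1
        assert var < 0

    def test_zero_nti_null_is_degenerate(self):
        # without non-trophic links the null webs equal the observed one
        net = make_net(4, [(0, 2, "T"), (1, 3, "T")])
        rep = compare_to_random_nti(net, [0, 0, 1, 1], n_random=5, seed=0, t_end=50)
        assert rep["p_biomass"] == pytest.approx(0.5)

    def test_compare_deterministic(self):
        net, z, prod = facilitation_scenario(4, seed=0)
        kw = dict(mapping=NTIMapping(producers=prod), n_random=5, seed=3, t_end=50)
        a = compare_to_random_nti(net, z, **kw)
        b = compare_to_random_nti(net, z, **kw)
        assert np.array_equal(a["null_biomass"], b["null_biomass"])
        assert a["p_biomass"] == b["p_biomass"]

    def test_parameter_sweep_single_cell(self):
        net, z, prod = facilitation_scenario(4, seed=0)
        df = parameter_sweep(net, z, {"intpos": [1.0], "intneg": [0.2]},
                             n_random=5, seed=0,
                             mapping=NTIMapping(producers=prod), t_end=50)
        assert len(df) == 1
        assert {"intpos", "intneg", "p_biomass"} <= set(df.columns)

    def test_sweep_grid_shape(self):
        net, z, prod = facilitation_scenario(3, seed=0)
        df = parameter_sweep(net, z, {"intpos": [0.5, 1.0], "intneg": [0.1]},
                             n_random=3, seed=0,
                             mapping=NTIMapping(producers=prod), t_end=30)
        assert len(df) == 2
        assert sorted(df["intpos"]) == [0.5, 1.0]


class TestParamValidation:
    def test_bounds_enforced(self):
        web = chain_web()
        p = DynParams.defaults(web)
        with pytest.raises(ValueError):
            DynParams(r=p.r, K=p.K, e=p.e, x=p.x, h=p.h, r_max=p.r_max,
                      x_min=p.x + 1.0, x_max=p.x_max, b=p.b, b_min=p.b_min,
                      c=p.c, d=p.d)

    def test_matrix_range_enforced(self):
        with pytest.raises(ValueError):
            ClusterWeb(("a",), np.array([[1.5]]))
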