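import networkx as nx
import numpy as np
import pytest

from micronet import (
    louvain_modules, power_law_fit, random_ensemble, small_world_report,
    topology_summary,
)
from micronet.topology import RandomEnsembleSummary


class TestTopologySummary:
    def test_triangle(self):
        s = topology_summary(nx.complete_graph(3))
        assert s.density == pytest.approx(1.0)
        assert s.acc == pytest.approx(1.0)
        assert s.apl == pytest.approx(1.0)
        assert s.diameter == 1

    def test_path_graph_apl(self):
        # pairs of a-b-c-d: distances 1,1,1,2,2,3 -> mean 5/3
        s = topology_summary(nx.path_graph(4))
        assert s.apl == pytest.approx(5 / 3)
        assert s.diameter == 3
        assert s.acc == pytest.approx(0.0)

    def test_disconnected_apl_over_reachable_pairs(self):
        g = nx.Graph([("a", "b"), ("c", "d"), ("d", "e")])
        # reachable pairs: ab=1; cd=1, de=1, ce=2 -> mean 5/4
        s = topology_summary(g)
        assert s.apl == pytest.approx(5 / 4)
        assert s.diameter == 2  # largest component c-d-e

    def test_density_invariant(self, rng):
        for _ in range(10):
            n = int(rng.integers(3, 20))
            m = int(rng.integers(1, n * (n - 1) // 2 + 1))
            g = nx.gnm_random_graph(n, m, seed=int(rng.integers(1 << 30)))
            s = topology_summary(g)
            assert s.density == pytest.approx(2 * s.edges / (s.nodes * (s.nodes - 1)))

    def test_sign_fractions(self):
        g = nx.Graph()
        g.add_edge(1, 2, sign=1)
        g.add_edge(2, 3, sign=-1)
        g.add_edge(3, 4, sign=1)
        g.add_edge(4, 1, sign=1)
        s = topology_summary(g)
        assert s.pos_frac == pytest.approx(0.75)
        assert s.neg_frac == pytest.approx(0.25)
        assert s.pos_frac + s.neg_frac == pytest.approx(1.0)

    def test_empty_graph_all_zero(self):
        s = topology_summary(nx.Graph())
        assert (s.nodes, s.edges, s.acc, s.apl, s.diameter) == (0, 0, 0.0, 0.0, 0)


class TestPowerLaw:
    def test_exact_power_law_r2_one(self):
        # degree counts proportional to k^-2 over k=1..10
        g = nx.Graph()
        node = 0
        ks = range(1, 11)
        # build a degree histogram directly via a configuration-style check:
        # power_law_fit only looks at the degree sequence, so use disjoint stars
        # counts(k) = round(1000 * k**-2) nodes of degree k is impractical as a
        # graph; instead fit the regression through a crafted degree sequence.
        from micronet.topology import PowerLawFit
        import micronet.topology as topo
        counts = {k: int(round(1000 * k ** -2.0)) for k in ks}

        class FakeGraph:
            def degree(self):
                out = []
                i = 0
                for k, c in counts.items():
                    for _ in range(c):
                        out.append((i, k))
                        i += 1
                return out

        fit = power_law_fit(FakeGraph())
        assert fit.r2 > 0.999
        assert fit.exponent == pytest.approx(2.0, abs=0.05)

    def test_regular_graph_undefined(self):
        with pytest.raises(ValueError, match="distinct degrees"):
            power_law_fit(nx.cycle_graph(10))

    def test_matches_independent_regression(self, rng):
        g = nx.barabasi_albert_graph(300, 2, seed=4)
        fit = power_law_fit(g)
        degrees = np.array([d for _, d in g.degree() if d > 0])
        ks, counts = np.unique(degrees, return_counts=True)
        slope, intercept = np.polyfit(np.log(ks), np.log(counts), 1)
        resid = np.log(counts) - (slope * np.log(ks) + intercept)
        r2 = 1 - resid.var() / np.log(counts).var()
        assert fit.r2 == pytest.approx(r2, abs=1e-9)
        assert fit.exponent == pytest.approx(-slope, abs=1e-9)


class TestLouvain:
    def test_two_cliques_modularity(self):
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
        modules, q = louvain_modules(g, seed=0)
        # the planted 2-module partition has Q = 0.5 on these 6 edges
        assert q >= 0.5 - 1e-12
        assert len({modules[n] for n in range(3)}) == 1
        assert len({modules[n] for n in range(3, 6)}) == 1

    def test_single_clique_q_zero(self):
        _, q = louvain_modules(nx.complete_graph(5), seed=0)
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_given_seed(self):
        g = nx.gnm_random_graph(60, 150, seed=3)
        a1, q1 = louvain_modules(g, seed=11)
        a2, q2 = louvain_modules(g, seed=11)
        assert a1 == a2 and q1 == q2

    def test_edgeless_raises(self):
        g = nx.Graph()
        g.add_nodes_from([1, 2])
        with pytest.raises(ValueError, match="edge"):
            louvain_modules(g)


class TestRandomEnsemble:
    def test_complete_graph_limit(self):
        ens = random_ensemble(5, 10, n_realizations=5, seed=0)
        assert ens.aplr_mean == pytest.approx(1.0)
        assert ens.accr_mean == pytest.approx(1.0)
        assert ens.aplr_sd == pytest.approx(0.0)

    def test_acc_converges_to_edge_density(self):
        """For ER graphs, expected local clustering equals the edge
        probability p = 2m / (n(n-1))."""
        n, m, reps = 60, 250, 200
        ens = random_ensemble(n, m, n_realizations=reps, seed=5)
        p = 2 * m / (n * (n - 1))
        assert abs(ens.accr_mean - p) < 3 * ens.accr_sd / np.sqrt(reps) + 0.01

    def test_impossible_edge_count(self):
        with pytest.raises(ValueError, match="impossible"):
            random_ensemble(4, 7)

    def test_deterministic(self):
        a = random_ensemble(30, 60, n_realizations=10, seed=9)
        b = random_ensemble(30, 60, n_realizations=10, seed=9)
        assert a == b


class TestSmallWorld:
    def test_ratios_one_at_ensemble_mean(self):
        obs = topology_summary(nx.complete_graph(4))
        null = RandomEnsembleSummary(10, obs.apl, 0.1, 0.03, obs.acc, 0.1, 0.03)
        rep = small_world_report(obs, null)
        assert rep["acc_ratio"] == pytest.approx(1.0)
        assert rep["apl_ratio"] == pytest.approx(1.0)

    def test_zero_sd_reports_ratio_only(self):
        obs = topology_summary(nx.complete_graph(4))
        null = RandomEnsembleSummary(10, 2.0, 0.0, 0.0, 0.5, 0.0, 0.0)
        rep = small_world_report(obs, null)
        assert rep["acc_z"] is None
        assert rep["acc_ratio"] == pytest.approx(obs.acc / 0.5)

    def test_watts_strogatz_clustering_excess(self):
        g = nx.watts_strogatz_graph(200, 8, 0.05, seed=2)
        obs = topology_summary(g)
        null = random_ensemble(200, g.number_of_edges(),
                               n_realizations=20, seed=3)
        rep = small_world_report(obs, null)
        assert rep["acc_ratio"] > 5
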