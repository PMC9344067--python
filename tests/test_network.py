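import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from micronet import build_network, correlation_screen
from conftest import make_relative, make_taxonomy


def brute_spearman(x, y):
    """Rank-based Spearman oracle: Pearson correlation of average ranks."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx ** 2).sum() * (ry ** 2).sum()))


def screen_of(rows, **kwargs):
    rel = make_relative(np.asarray(rows) / np.asarray(rows).sum(axis=0))
    return correlation_screen(rel)


class TestCorrelationScreen:
    def test_monotone_pair_rho_one(self):
        a = np.array([1, 2, 3, 4, 5, 6], dtype=float)
        b = np.array([2, 4, 8, 9, 12, 20], dtype=float)
        c = 200 - a - b  # constant column sums keep relative ranks = count ranks
        rows = np.vstack([a, b, c])
        rel = make_relative(rows / rows.sum(axis=0), otu_ids=["a", "b", "c"])
        rec = correlation_screen(rel).set_index(["otu_a", "otu_b"])
        assert rec.loc[("a", "b"), "rho"] == pytest.approx(1.0)
        assert rec.loc[("a", "c"), "rho"] == pytest.approx(-1.0)

    def test_matches_rank_oracle_with_ties(self):
        x = np.array([1, 2, 3, 4, 5], dtype=float)
        y = np.array([5, 6, 7, 8, 7], dtype=float)
        rows = np.vstack([x, y, np.ones(5)])
        rel = make_relative(rows / rows.sum(axis=0), otu_ids=["x", "y", "z"])
        rec = correlation_screen(rel).set_index(["otu_a", "otu_b"])
        expected = brute_spearman(x / rows.sum(axis=0), y / rows.sum(axis=0))
        assert rec.loc[("x", "y"), "rho"] == pytest.approx(expected, abs=1e-12)
        ref_rho, ref_p = stats.spearmanr(x / rows.sum(axis=0),
                                         y / rows.sum(axis=0))
        assert rec.loc[("x", "y"), "rho"] == pytest.approx(ref_rho, abs=1e-12)
        assert rec.loc[("x", "y"), "p"] == pytest.approx(ref_p, rel=1e-6)

    def test_matches_scipy_on_random_table(self, rng):
        values = rng.random((8, 10))
        rel = make_relative(values / values.sum(axis=0))
        rec = correlation_screen(rel).set_index(["otu_a", "otu_b"])
        norm = values / values.sum(axis=0)
        for (i, a), (j, b) in itertools.combinations(enumerate(rel.otu_ids), 2):
            ref_rho, ref_p = stats.spearmanr(norm[i], norm[j])
            assert rec.loc[(a, b), "rho"] == pytest.approx(ref_rho, abs=1e-12)
            assert rec.loc[(a, b), "p"] == pytest.approx(ref_p, rel=1e-9)

    def test_bh_equal_pvalues_unchanged(self):
        """BH on m equal p-values leaves them untouched."""
        from statsmodels.stats.multitest import multipletests
        q = multipletests(np.full(10, 0.01), method="fdr_bh")[1]
        np.testing.assert_allclose(q, 0.01)

    def test_q_at_least_p(self, rng):
        values = rng.random((12, 9))
        rel = make_relative(values / values.sum(axis=0))
        rec = correlation_screen(rel)
        assert (rec["q"] >= rec["p"] - 1e-15).all()

    def test_constant_otu_excluded(self, rng):
        values = rng.random((4, 8))
        values[0] = 0.0  # zero everywhere -> constant relative abundance
        values[1] += 1.0
        rel = make_relative(values / values.sum(axis=0))
        rec = correlation_screen(rel)
        assert "OTU1" not in set(rec["otu_a"]) | set(rec["otu_b"])

    def test_too_few_samples(self):
        rel = make_relative(np.full((3, 4), 1 / 3))
        with pytest.raises(ValueError, match="five samples"):
            correlation_screen(rel)


class TestBuildNetwork:
    def _tax(self, ids):
        return make_taxonomy({o: "Bacteria" for o in ids})

    def _records(self, rows):
        return pd.DataFrame(rows, columns=["otu_a", "otu_b", "rho", "p", "q"])

    def test_threshold_rules(self):
        rec = self._records([
            ("a", "b", 0.9, 0.001, 0.01),    # edge, positive
            ("a", "c", -0.9, 0.001, 0.01),   # edge, negative (|rho| rule)
            ("b", "c", 0.79, 0.0001, 0.001), # below r_min
            ("a", "d", 0.95, 0.2, 0.4),      # not significant
        ])
        g = build_network(rec, self._tax("abcd"))
        assert set(map(frozenset, g.edges)) == {frozenset("ab"), frozenset("ac")}
        assert g.edges["a", "b"]["sign"] == 1
        assert g.edges["a", "c"]["sign"] == -1
        assert "d" not in g  # isolated OTUs excluded

    def test_raw_p_mode(self):
        rec = self._records([("a", "b", 0.9, 0.01, 0.2)])
        assert build_network(rec, self._tax("ab")).number_of_edges() == 0
        g = build_network(rec, self._tax("ab"), use_raw_p=True)
        assert g.number_of_edges() == 1

    def test_order_invariance(self, rng):
        rows = [(f"o{i}", f"o{j}", float(rng.uniform(-1, 1)),
                 0.001, float(rng.uniform(0, 0.1)))
                for i, j in itertools.combinations(range(8), 2)]
        rec = self._records(rows)
        tax = self._tax([f"o{i}" for i in range(8)])
        g1 = build_network(rec, tax)
        g2 = build_network(rec.sample(frac=1, random_state=7), tax)
        assert set(map(frozenset, g1.edges)) == set(map(frozenset, g2.edges))

    def test_every_edge_satisfies_thresholds(self, rng):
        values = rng.random((15, 10))
        rel = make_relative(values / values.sum(axis=0))
        rec = correlation_screen(rel)
        tax = self._tax(rel.otu_ids)
        g = build_network(rec, tax, r_min=0.5, q_max=0.5)
        lookup = rec.set_index(["otu_a", "otu_b"])
        for u, v, attrs in g.edges(data=True):
            key = (u, v) if (u, v) in lookup.index else (v, u)
            assert abs(lookup.loc[key, "rho"]) > 0.5
            assert lookup.loc[key, "q"] < 0.5
            assert attrs["rho"] == pytest.approx(lookup.loc[key, "rho"])

    def test_empty_edge_set_warns_not_raises(self):
        rec = self._records([("a", "b", 0.1, 0.9, 0.95)])
        g = build_network(rec, self._tax("ab"))
        assert g.number_of_nodes() == 0
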