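"""Enrichment, clustering and network comparison."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from cosmotherm.core_io import CausalNetwork
from cosmotherm.net_analysis import (ClusterAssignment, cluster_fast_greedy,
                                     compare_network_enrichments,
                                     jaccard_compare, ora)


def exact_upper_tail(k, N, K, n):
    """Independent oracle: exact hypergeometric upper tail via rational
    arithmetic."""
    total = Fraction(math.comb(N, n))
    return float(sum(Fraction(math.comb(K, i) * math.comb(N - K, n - i))
                     for i in range(k, min(n, K) + 1)) / total)


class TestOra:
    def _db(self, sets):
        return {name: (name, frozenset(members))
                for name, members in sets.items()}

    def test_closed_form_pvalue(self):
        background = {f"g{i}" for i in range(100)}
        pathway = {f"g{i}" for i in range(10)}
        query = {f"g{i}" for i in range(5)} | {f"g{i}" for i in range(50, 55)}
        res = ora(query, background, self._db({"P": pathway}))
        assert res["pvalue"][0] == pytest.approx(
            exact_upper_tail(5, 100, 10, 10), abs=1e-12)

    def test_matches_exact_oracle_on_random_tables(self):
        rng = np.random.default_rng(0)
        background = {f"g{i}" for i in range(60)}
        for _ in range(100):
            K = int(rng.integers(5, 30))
            n = int(rng.integers(5, 30))
            pathway = set(rng.choice(sorted(background), K, replace=False))
            query = set(rng.choice(sorted(background), n, replace=False))
            res = ora(query, background, self._db({"P": pathway}),
                      min_size=1, max_size=60)
            k = len(pathway & query)
            assert res["pvalue"][0] == pytest.approx(
                exact_upper_tail(k, 60, K, n), abs=1e-10)

    def test_size_window_excludes_pathways(self):
        background = {f"g{i}" for i in range(30)}
        db = self._db({"TINY": {"g0", "g1", "g2", "g3"},
                       "OK": {f"g{i}" for i in range(6)}})
        res = ora({"g0"}, background, db, min_size=5, max_size=500)
        assert list(res["pathway"]) == ["OK"]

    def test_zero_overlap_not_significant(self):
        background = {f"g{i}" for i in range(50)}
        db = self._db({"P": {f"g{i}" for i in range(10)}})
        res = ora({f"g{i}" for i in range(40, 45)}, background, db)
        assert res["pvalue"][0] == pytest.approx(1.0, abs=1e-9) or \
            res["pvalue"][0] > 0.5
        assert not res["significant"][0]

    def test_query_outside_background_errors(self):
        with pytest.raises(ValueError):
            ora({"x"}, {"a", "b"}, self._db({"P": {"a"}}))

    def test_haldane_odds_ratio_finite(self):
        background = {f"g{i}" for i in range(20)}
        db = self._db({"P": {f"g{i}" for i in range(5)}})
        res = ora({f"g{i}" for i in range(5)}, background, db)
        assert np.isfinite(res["odds_ratio"][0])


def two_cliques_network():
    """Two 4-cliques joined by a single bridge edge."""
    edges = set()
    a = ["A1", "A2", "A3", "A4"]
    b = ["B1", "B2", "B3", "B4"]
    for u, v in itertools.combinations(a, 2):
        edges.add((u, 1, v, "run1"))
    for u, v in itertools.combinations(b, 2):
        edges.add((u, 1, v, "run1"))
    edges.add(("A4", 1, "B1", "run1"))
    state = {v: 1 for v in a + b}
    return CausalNetwork(edges=edges, node_state=state, objective_value=0.0)


class TestClustering:
    def test_two_cliques_give_two_clusters(self):
        ca = cluster_fast_greedy(two_cliques_network())
        groups = {}
        for v, c in ca.assignment.items():
            groups.setdefault(c, set()).add(v)
        assert sorted(map(sorted, groups.values())) == [
            ["A1", "A2", "A3", "A4"], ["B1", "B2", "B3", "B4"]]

    def test_modularity_matches_exhaustive_bipartition(self):
        """CNM modularity equals the best over all bipartitions of the
        two-clique graph (small-graph oracle)."""
        import networkx as nx
        net = two_cliques_network()
        ca = cluster_fast_greedy(net)
        g = nx.Graph()
        for s, _, t, _ in net.edges:
            g.add_edge(s, t)
        nodes = sorted(g)
        best = -1.0
        for mask in range(1, 2 ** (len(nodes) - 1)):
            part1 = {nodes[i] for i in range(len(nodes)) if mask >> i & 1}
            part2 = set(nodes) - part1
            if part1 and part2:
                q = nx.community.modularity(g, [part1, part2])
                best = max(best, q)
        assert ca.modularity == pytest.approx(best, abs=1e-12)

    def test_empty_network_errors(self):
        with pytest.raises(ValueError):
            cluster_fast_greedy(CausalNetwork(edges=set(), node_state={},
                                              objective_value=0.0))


class TestJaccard:
    def test_identical_clusterings_diagonal_one(self):
        a = ClusterAssignment({"x": 1, "y": 1, "z": 2}, 0.1)
        mat = jaccard_compare(a, a)
        assert mat.loc[1, 1] == 1.0 and mat.loc[2, 2] == 1.0

    def test_disjoint_universes_all_zero(self):
        a = ClusterAssignment({"x": 1}, 0.0)
        b = ClusterAssignment({"y": 1}, 0.0)
        assert jaccard_compare(a, b).to_numpy().max() == 0.0

    def test_hand_computed_overlap(self):
        a = ClusterAssignment({"1": 1, "2": 1, "3": 1}, 0.0)
        b = ClusterAssignment({"2": 1, "3": 1, "4": 1}, 0.0)
        assert jaccard_compare(a, b).loc[1, 1] == pytest.approx(0.5)

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(1)
        a = ClusterAssignment(
            {f"n{i}": int(rng.integers(1, 4)) for i in range(30)}, 0.0)
        b = ClusterAssignment(
            {f"n{i}": int(rng.integers(1, 3)) for i in range(20, 50)}, 0.0)
        m1 = jaccard_compare(a, b)
        m2 = jaccard_compare(b, a)
        assert np.allclose(m1.to_numpy(), m2.to_numpy().T)
        assert (m1.to_numpy() >= 0).all() and (m1.to_numpy() <= 1).all()


class TestCompareEnrichments:
    def _enr(self, pathways, ors, ks, qs):
        return pd.DataFrame({
            "pathway": pathways, "odds_ratio": ors, "k": ks,
            "qvalue": qs, "significant": [q < 0.05 for q in qs]})

    def test_identical_enrichments_zero_delta(self):
        enr = self._enr(["P1", "P2"], [2.0, 3.0], [5, 6], [0.01, 0.01])
        table, tests = compare_network_enrichments(
            enr, enr, {"P1": "cc", "P2": "cc"})
        assert np.allclose(table["delta"], 0.0)

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(2)
        n = 20
        paths_a = [f"A{i}" for i in range(n)]
        paths_b = [f"B{i}" for i in range(n)]
        base = rng.uniform(1.5, 3.0, size=2 * n)
        enr_b = self._enr(paths_a + paths_b, base, [5] * 2 * n,
                          [0.01] * 2 * n)
        shifted = base.copy()
        shifted[:n] *= np.e          # delta +1 on the log-OR scale
        enr_a = self._enr(paths_a + paths_b, shifted, [5] * 2 * n,
                          [0.01] * 2 * n)
        groups = {p: "ddr" for p in paths_a} | {p: "other" for p in paths_b}
        _, tests = compare_network_enrichments(enr_a, enr_b, groups)
        assert tests["pvalue"][0] < 0.05

    def test_small_pathways_excluded(self):
        enr = self._enr(["P1", "P2"], [2.0, 2.0], [3, 6], [0.01, 0.01])
        table, _ = compare_network_enrichments(enr, enr, {})
        assert list(table["pathway"]) == ["P2"]

    def test_nonsignificant_everywhere_excluded(self):
        enr = self._enr(["P1"], [2.0], [6], [0.5])
        table, _ = compare_network_enrichments(enr, enr, {})
        assert table.empty
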