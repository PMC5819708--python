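import networkx as nx
import numpy as np
import pytest

from netheat.diffusion import DiffusionOperator, build_diffusion, heat_from_fdr
from netheat.io import InteractionNetwork
from netheat.modules import (_min_delta_for_lmax, consensus, extract_modules,
                             module_significance, select_delta, Module,
                             ModuleSet, SignificanceTable)


def random_network(n, p, seed, name="r"):
    g = nx.gnp_random_graph(n, p, seed=seed)
    return InteractionNetwork(name, nx.relabel_nodes(g, str))


def bruteforce_scc(adjacency):
    """Reachability-based strong components: transitive closure oracle."""
    n = adjacency.shape[0]
    reach = adjacency.astype(bool) | np.eye(n, dtype=bool)
    for _ in range(n):
        reach = reach | (reach @ reach)
    mutual = reach & reach.T
    labels = -np.ones(n, dtype=int)
    nxt = 0
    for i in range(n):
        if labels[i] < 0:
            labels[mutual[i]] = nxt
            nxt += 1
    return labels


class TestHeat:
    def test_closed_forms_and_cap(self):
        np.testing.assert_allclose(heat_from_fdr([1.0]), [0.0])
        np.testing.assert_allclose(heat_from_fdr([0.01]), [2.0])
        np.testing.assert_allclose(heat_from_fdr([1e-15]), [10.0])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            heat_from_fdr([0.0])
        with pytest.raises(ValueError):
            heat_from_fdr([1.5])


class TestDiffusionOperator:
    def test_two_node_closed_form(self):
        net = InteractionNetwork("toy", nx.Graph([("A", "B")]))
        op = build_diffusion(net, beta=0.5)
        np.testing.assert_allclose(op.F, [[2 / 3, 1 / 3], [1 / 3, 2 / 3]],
                                   atol=1e-12)

    def test_columns_sum_to_one(self):
        for seed in range(5):
            net = random_network(60, 0.06, seed)
            op = build_diffusion(net, beta=0.4)
            np.testing.assert_allclose(op.F.sum(axis=0), 1.0, atol=1e-10)
            assert (op.F >= -1e-14).all()

    def test_matches_power_series(self):
        for seed in range(3):
            net = random_network(15, 0.25, seed)
            beta = 0.4
            op = build_diffusion(net, beta=beta)
            adj = nx.to_numpy_array(net.graph, nodelist=op.nodes)
            W = adj / adj.sum(axis=0, keepdims=True)
            F = np.zeros_like(W)
            Wt = np.eye(len(op.nodes))
            for _ in range(200):
                F += beta * Wt
                Wt = (1 - beta) * W @ Wt
            np.testing.assert_allclose(op.F, F, atol=1e-8)

    def test_heat_conservation_of_exchanged_heat(self):
        net = random_network(40, 0.1, 3)
        op = build_diffusion(net)
        h = np.random.default_rng(0).uniform(size=len(op.nodes))
        E = op.exchanged_heat(h)
        np.testing.assert_allclose(E.sum(axis=0), h, atol=1e-10)

    def test_invalid_beta(self):
        net = random_network(5, 0.5, 0)
        with pytest.raises(ValueError):
            build_diffusion(net, beta=1.0)


class TestExtractModules:
    def test_delta_above_everything_gives_no_modules(self):
        rng = np.random.default_rng(1)
        E = rng.uniform(size=(6, 6))
        ms = extract_modules(E, [f"n{i}" for i in range(6)], delta=2.0)
        assert len(ms) == 0

    def test_zero_heat_gives_no_modules(self):
        net = random_network(10, 0.3, 2)
        op = build_diffusion(net)
        E = op.exchanged_heat(np.zeros(len(op.nodes)))
        ms = extract_modules(E, op.nodes, delta=1e-9)
        assert len(ms) == 0

    def test_hot_clique_is_extracted(self):
        # two 4-cliques joined by one edge; heat only on the first
        g = nx.Graph()
        hot = ["h1", "h2", "h3", "h4"]
        cold = ["c1", "c2", "c3", "c4"]
        for grp in (hot, cold):
            for i, a in enumerate(grp):
                for b in grp[i + 1:]:
                    g.add_edge(a, b)
        g.add_edge("h4", "c1")
        op = build_diffusion(InteractionNetwork("two", g))
        h = np.array([5.0 if n in hot else 0.01 for n in op.nodes])
        E = op.exchanged_heat(h)
        hot_idx = [op.nodes.index(n) for n in hot]
        cold_idx = [op.nodes.index(n) for n in cold]
        within_hot = min(E[i, j] for i in hot_idx for j in hot_idx if i != j)
        background = max(E[i, j] for i in cold_idx for j in range(len(op.nodes))
                         if i != j)
        delta = 0.5 * (background + within_hot)
        ms = extract_modules(E, op.nodes, delta, heat=h)
        assert [set(m.genes) for m in ms.modules] == [set(hot)]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_scc(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        E = rng.uniform(size=(n, n))
        delta = float(rng.uniform(0.3, 0.9))
        nodes = [f"n{i:02d}" for i in range(n)]
        ms = extract_modules(E, nodes, delta, min_size=1)
        mask = (E >= delta)
        np.fill_diagonal(mask, False)
        labels = bruteforce_scc(mask)
        oracle = sorted(
            sorted(nodes[i] for i in np.flatnonzero(labels == lab))
            for lab in range(labels.max() + 1))
        assert sorted(m.genes for m in ms.modules) == oracle

    def test_raising_delta_refines_modules(self):
        net = random_network(30, 0.15, 7)
        op = build_diffusion(net)
        h = np.random.default_rng(7).exponential(size=len(op.nodes))
        E = op.exchanged_heat(h)
        low = extract_modules(E, op.nodes, 0.01, min_size=1)
        high = extract_modules(E, op.nodes, 0.05, min_size=1)
        for small in high.gene_sets():
            assert any(small <= big for big in low.gene_sets())


class TestSelectDelta:
    def test_constant_heat_is_seed_invariant(self):
        net = InteractionNetwork("cyc", nx.cycle_graph(8))
        op = build_diffusion(net)
        h = np.ones(8)
        deltas = {select_delta(op, h, n_perm=5, seed=s) for s in range(4)}
        assert len(deltas) == 1

    def test_lmax_one_exceeds_largest_entry(self):
        net = InteractionNetwork("cyc", nx.cycle_graph(6))
        op = build_diffusion(net)
        h = np.ones(6)
        delta = select_delta(op, h, n_perm=3, l_max=1, seed=0)
        E = op.exchanged_heat(h)
        off = E[~np.eye(6, dtype=bool)]
        # up to one ulp of solver asymmetry in the symmetric entries
        assert delta >= off.max() * (1 - 1e-12)

    def test_min_delta_matches_exhaustive_scan(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            E = rng.uniform(size=(9, 9))
            l_max = int(rng.integers(1, 5))
            got = _min_delta_for_lmax(E, l_max)
            off = E[~np.eye(9, dtype=bool)]
            candidates = np.unique(off[off > 0])
            oracle = None
            for c in candidates:
                mask = E >= c
                np.fill_diagonal(mask, False)
                if np.bincount(bruteforce_scc(mask)).max() <= l_max:
                    oracle = c
                    break
            if oracle is None:
                assert got > candidates.max()
            else:
                assert got == pytest.approx(oracle)

    def test_planted_scenario_delta_separates_scales(self):
        # 30-node graph with a hot 6-clique: the chosen delta must sit between
        # the background exchange scale and the planted within-module scale
        g = nx.gnp_random_graph(30, 0.12, seed=5)
        hot = list(range(6))
        for i in hot:
            for j in hot:
                if i < j:
                    g.add_edge(i, j)
        net = InteractionNetwork("p", nx.relabel_nodes(g, lambda x: f"n{x:02d}"))
        op = build_diffusion(net)
        h = np.array([8.0 if int(n[1:]) < 6 else 0.05 for n in op.nodes])
        delta = select_delta(op, h, n_perm=20, l_max=3, seed=1)
        E = op.exchanged_heat(h)
        hot_idx = [i for i, n in enumerate(op.nodes) if int(n[1:]) < 6]
        cold_idx = [i for i in range(len(op.nodes)) if i not in hot_idx]
        within_hot = min(E[i, j] for i in hot_idx for j in hot_idx if i != j)
        background = np.median([E[i, j] for i in cold_idx for j in cold_idx
                                if i != j])
        assert background < delta < within_hot
        ms = extract_modules(E, op.nodes, delta, heat=h)
        assert set(op.nodes[i] for i in hot_idx) in ms.gene_sets()


class TestSignificance:
    def test_no_observed_modules_gives_p_one(self):
        net = random_network(12, 0.3, 1)
        op = build_diffusion(net)
        h = np.zeros(len(op.nodes))
        ms = extract_modules(op.exchanged_heat(h), op.nodes, delta=1.0)
        table = module_significance(ms, op, h, delta=1.0, n_perm=19, seed=0)
        assert (table.observed == 0).all()
        assert (table.p == 1.0).all()

    def test_constant_heat_not_significant(self):
        net = InteractionNetwork("cyc", nx.cycle_graph(10))
        op = build_diffusion(net)
        h = np.ones(10)
        delta = float(np.median(op.exchanged_heat(h)))
        ms = extract_modules(op.exchanged_heat(h), op.nodes, delta)
        table = module_significance(ms, op, h, delta, n_perm=19, seed=0)
        assert (table.p > 0.5).all()

    def test_planted_module_flagged_null_heat_not(self):
        """A hot connected module over graded background heat is reported
        significant in most seeds; permutation-exchangeable background alone
        never is."""
        planted_hits = 0
        null_hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 300
            g = nx.barabasi_albert_graph(n, 2, seed=seed)
            deg = dict(g.degree)
            start = min(range(n), key=lambda x: (deg[x], x))
            hot, frontier, seen = [start], [start], {start}
            while len(hot) < 8 and frontier:
                u = frontier.pop(0)
                for v in sorted(g.neighbors(u), key=lambda x: deg[x]):
                    if v not in seen:
                        seen.add(v)
                        hot.append(v)
                        frontier.append(v)
                        if len(hot) == 8:
                            break
            net = InteractionNetwork("p", nx.relabel_nodes(g, str))
            op = build_diffusion(net)
            hotset = {str(x) for x in hot}
            h = np.array([6.0 if nd in hotset else rng.exponential(0.3)
                          for nd in op.nodes])
            delta = select_delta(op, h, n_perm=10, l_max=3, seed=seed)
            ms = extract_modules(op.exchanged_heat(h), op.nodes, delta, heat=h)
            module_significance(ms, op, h, delta, n_perm=99, seed=seed)
            planted_hits += len(ms.significant_modules()) > 0
            h0 = rng.exponential(0.3, size=n)
            d0 = select_delta(op, h0, n_perm=10, l_max=3, seed=seed)
            ms0 = extract_modules(op.exchanged_heat(h0), op.nodes, d0, heat=h0)
            module_significance(ms0, op, h0, d0, n_perm=99, seed=seed)
            null_hits += len(ms0.significant_modules()) > 0
        assert planted_hits >= 7
        assert null_hits <= 1

    def test_significance_p_within_bounds_and_counts_monotone(self):
        net = random_network(25, 0.15, 3)
        op = build_diffusion(net)
        h = np.random.default_rng(3).exponential(size=len(op.nodes))
        delta = select_delta(op, h, n_perm=5, seed=3)
        ms = extract_modules(op.exchanged_heat(h), op.nodes, delta, heat=h)
        t = module_significance(ms, op, h, delta, n_perm=19, seed=3)
        assert np.all(np.diff(t.observed) <= 0)
        assert np.all((t.p > 0) & (t.p <= 1))


class TestConsensus:
    def _ms(self, sets, network):
        mods = [Module(genes=sorted(s), mean_heat=1.0, support=[network])
                for s in sets]
        return ModuleSet(modules=mods, network=network, contrast="c")

    def test_single_network_identity(self):
        ms = self._ms([{"A", "B", "C"}], "n1")
        cons = consensus([ms])
        assert cons.gene_sets() == [{"A", "B", "C"}]
        assert cons.modules[0].support == ["n1"]

    def test_two_identical_networks(self):
        a = self._ms([{"A", "B", "C"}], "n1")
        b = self._ms([{"A", "B", "C"}], "n2")
        cons = consensus([a, b])
        assert cons.gene_sets() == [{"A", "B", "C"}]
        assert cons.modules[0].support == ["n1", "n2"]

    def test_majority_rule_three_networks(self):
        a = self._ms([{"A", "B", "C"}], "n1")
        b = self._ms([{"A", "B", "C"}], "n2")
        c = self._ms([{"C", "D", "E"}], "n3")
        cons = consensus([a, b, c])
        # {A,B,C} co-occurs in 2 of 3 networks (majority); {C,D,E} in one only
        assert cons.gene_sets() == [{"A", "B", "C"}]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            consensus([])
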