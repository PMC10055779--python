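import math
from collections import Counter

import numpy as np
import pytest
from scipy.stats import chi2

from soilnet import conet
from soilnet.io_tables import CountTable


def make_table(counts, prefix="t"):
    counts = np.asarray(counts)
    return CountTable([f"{prefix}{i}" for i in range(counts.shape[0])],
                      [f"s{j}" for j in range(counts.shape[1])], counts)


class TestFilterTaxa:
    def test_below_threshold_dropped(self):
        # t1 mean rel abundance 0.0005 < 0.001
        counts = np.array([[1, 1], [999, 999], [1000, 1000]])
        out = conet.filter_taxa(make_table(counts), 0.001)
        assert out.taxa == ["t1", "t2"]

    def test_exact_threshold_dropped_strict(self):
        counts = np.array([[1, 1], [99, 99]])  # t0 at exactly 1%
        out = conet.filter_taxa(make_table(counts), 0.01)
        assert out.taxa == ["t1"]

    def test_all_above_is_identity(self, small_table):
        out = conet.filter_taxa(small_table, 0.0)
        assert out == small_table

    def test_bad_threshold(self, small_table):
        with pytest.raises(ValueError):
            conet.filter_taxa(small_table, 1.5)


def _brute_force_mi(x, y, k):
    """Plug-in MI with equal-frequency bins, written independently."""
    n = len(x)

    def bins(v):
        order = np.argsort(v, kind="stable")
        lab = np.empty(n, dtype=int)
        for pos, idx in enumerate(order):
            lab[idx] = pos * k // n
        return lab

    bx, by = bins(x), bins(y)
    joint = Counter(zip(bx, by))
    px, py = Counter(bx), Counter(by)
    total = 0.0
    for (a, b), c in joint.items():
        pxy = c / n
        total += pxy * math.log(pxy / (px[a] / n * py[b] / n))
    return total


class TestPairwiseMeasures:
    def test_self_pair_oracle(self):
        # duplicate a profile as two taxa: spearman 1, KL 0, BC 0
        counts = np.array([[5, 1, 9, 3, 7, 2], [5, 1, 9, 3, 7, 2], [1, 1, 1, 1, 1, 10]])
        assoc = conet.pairwise_measures(make_table(counts))
        assert assoc.scores["spearman"][0, 1] == pytest.approx(1.0)
        assert assoc.scores["kl"][0, 1] == pytest.approx(0.0, abs=1e-12)
        assert assoc.scores["bray_curtis"][0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_exact_linearity(self):
        counts = np.array([[1, 2, 3, 4], [2, 4, 6, 8], [9, 9, 1, 9]])
        table = make_table(counts)
        assoc = conet.pairwise_measures(table)
        # on per-sample relative abundances the two profiles stay monotone
        assert assoc.scores["spearman"][0, 1] == pytest.approx(1.0)

    def test_anti_monotone_and_mi_oracle(self):
        counts = np.array([[1, 2, 3, 4, 5, 6, 7, 8, 9],
                           [9, 8, 7, 6, 5, 4, 3, 2, 1],
                           [4, 4, 4, 4, 4, 4, 4, 4, 5]])
        table = make_table(counts)
        assoc = conet.pairwise_measures(table)
        assert assoc.scores["spearman"][0, 1] == pytest.approx(-1.0)
        rel = table.relative_abundance()
        k = int(np.floor(np.sqrt(9)))
        expected = _brute_force_mi(rel[0], rel[1], k)
        assert assoc.scores["mutual_info"][0, 1] == pytest.approx(expected, abs=1e-12)

    def test_constant_profile_flagged_missing(self):
        counts = np.array([[5, 5, 5, 5], [1, 2, 3, 4], [2, 3, 1, 4]])
        # make t0 constant in relative abundance: equal library sizes
        counts = np.array([[5, 5, 5, 5], [1, 2, 3, 4], [4, 3, 2, 1]])
        with pytest.warns(UserWarning, match="constant"):
            assoc = conet.pairwise_measures(make_table(counts))
        assert np.isnan(assoc.scores["spearman"][0, 1])
        assert np.isfinite(assoc.scores["bray_curtis"][0, 1])

    def test_symmetry_and_pearson_spearman_against_scipy(self, rng):
        from scipy.stats import pearsonr, spearmanr

        counts = rng.integers(0, 40, size=(6, 12))
        counts[0] += 1
        table = make_table(counts)
        assoc = conet.pairwise_measures(table)
        rel = table.relative_abundance()
        for i in range(6):
            for j in range(i + 1, 6):
                if rel[i].std() == 0 or rel[j].std() == 0:
                    continue
                assert assoc.scores["pearson"][i, j] == pytest.approx(
                    pearsonr(rel[i], rel[j]).statistic, abs=1e-10)
                assert assoc.scores["spearman"][i, j] == pytest.approx(
                    spearmanr(rel[i], rel[j]).statistic, abs=1e-10)
                for m in conet.MEASURES:
                    assert assoc.scores[m][i, j] == assoc.scores[m][j, i]

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            conet.pairwise_measures(make_table(np.ones((3, 3), dtype=int)))


class TestPermutationPvalues:
    def test_b_floor(self, small_table):
        with pytest.raises(ValueError):
            conet.permutation_pvalues(small_table, b=50)

    def test_add_one_bound(self):
        # constant column sums keep the relative-abundance profiles exactly
        # anti-monotone: no permutation can beat |rho| = 1
        base = np.arange(1, 13)
        counts = np.vstack([base, 20 - base])
        assoc = conet.permutation_pvalues(make_table(counts), b=99, seed=0)
        assert assoc.scores["spearman"][0, 1] == pytest.approx(-1.0)
        assert assoc.pvalues["spearman"][0, 1] == pytest.approx(1 / 100)

    def test_independent_taxa_p_uniform(self):
        from scipy.stats import kstest

        rng = np.random.default_rng(7)
        counts = rng.poisson(50, size=(14, 30)) + 1
        assoc = conet.permutation_pvalues(make_table(counts), b=199, seed=1)
        ps = [assoc.pvalues["spearman"][i, j] for i, j in assoc.pairs()]
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_planted_pair_significant(self):
        from soilnet.synthetic_community import generate_dataset
        from tests.conftest import make_flat_config
        from soilnet.synthetic_community import AssociationBlock

        hits = 0
        for seed in range(10):
            cfg = make_flat_config(8, blocks=[AssociationBlock(("t00", "t01"), 1.5, 1)])
            table, *_ = generate_dataset(cfg, seed=seed)
            assoc = conet.permutation_pvalues(table, b=199, seed=seed)
            if assoc.pvalues["spearman"][0, 1] <= 0.01:
                hits += 1
        assert hits >= 9


class TestBrownCombination:
    def test_fisher_closed_form(self):
        # chi-square oracle: X = -2(ln .05 + ln .05), 4 df
        x = -2 * (np.log(0.05) + np.log(0.05))
        expected = float(chi2.sf(x, 4))
        assert conet.fisher_combine([0.05, 0.05]) == pytest.approx(expected)
        assert conet.brown_from_cov([0.05, 0.05], np.diag([4.0, 4.0])) == (
            pytest.approx(expected))

    def test_degenerate_dependence_recovers_common_p(self):
        for p in (0.9, 0.5, 0.05, 0.001):
            cov = np.full((5, 5), 4.0)  # perfectly dependent transforms
            assert conet.brown_from_cov([p] * 5, cov) == pytest.approx(p, rel=1e-9)

    def test_all_ones_combine_to_one(self):
        assert conet.fisher_combine([1.0] * 5) == pytest.approx(1.0)
        assert conet.brown_from_cov([1.0] * 5, np.diag([4.0] * 5)) == pytest.approx(1.0)

    def test_brown_equals_fisher_for_independent_empirical_cov(self):
        # compare on the combined-p scale in [0.001, 0.5]; deeper tails
        # amplify the sampling error of the covariance estimate
        rng = np.random.default_rng(0)
        w = -2 * np.log(rng.uniform(size=(5, 200_000)))
        cov = np.cov(w)
        for p in (0.06, 0.1, 0.2, 0.3, 0.4):
            pvec = [p] * 5
            fisher = conet.fisher_combine(pvec)
            assert 0.001 <= fisher <= 0.55
            assert conet.brown_from_cov(pvec, cov) == pytest.approx(fisher, rel=0.05)

    def test_requires_pvalues(self, small_table):
        assoc = conet.pairwise_measures(small_table)
        with pytest.raises(ValueError):
            conet.brown_combine(assoc)

    def test_end_to_end_brown_in_range(self, rng):
        counts = rng.poisson(40, size=(6, 20)) + 1
        table = make_table(counts)
        assoc = conet.permutation_pvalues(table, b=199, seed=0)
        assoc = conet.brown_combine(assoc)
        ps = np.array([assoc.brown_p[i, j] for i, j in assoc.pairs()])
        assert np.all((ps > 0) & (ps <= 1))


def _assoc_with(spearman, brown_p, taxa=("a", "b")):
    n = len(taxa)
    scores = {m: np.full((n, n), np.nan) for m in conet.MEASURES}
    scores["spearman"][0, 1] = scores["spearman"][1, 0] = spearman
    bp = np.full((n, n), np.nan)
    bp[0, 1] = bp[1, 0] = brown_p
    return conet.AssociationResult(list(taxa), scores, n_samples=10, brown_p=bp)


class TestBuildNetwork:
    def table(self):
        return make_table(np.array([[5, 1, 9, 3], [1, 5, 3, 9]]), prefix="")

    def test_passes_both_gates(self):
        table = make_table(np.array([[5, 1, 9, 3], [1, 5, 3, 9]]))
        net = conet.build_network(_assoc_with(0.9, 0.001, ("t0", "t1")), table)
        assert net.n_edges == 1 and net.edges[0].sign == 1

    def test_p_gate_fails(self):
        table = make_table(np.array([[5, 1, 9, 3], [1, 5, 3, 9]]))
        net = conet.build_network(_assoc_with(0.9, 0.2, ("t0", "t1")), table)
        assert net.n_edges == 0 and net.n_nodes == 0

    def test_score_gate_strict(self):
        table = make_table(np.array([[5, 1, 9, 3], [1, 5, 3, 9]]))
        net = conet.build_network(_assoc_with(0.6, 0.001, ("t0", "t1")), table)
        assert net.n_edges == 0

    def test_negative_edge_sign(self):
        table = make_table(np.array([[5, 1, 9, 3], [1, 5, 3, 9]]))
        net = conet.build_network(_assoc_with(-0.8, 0.001, ("t0", "t1")), table)
        assert net.edges[0].sign == -1

    def test_monotone_in_thresholds(self, rng):
        counts = rng.poisson(30, size=(8, 16)) + 1
        table = make_table(counts)
        assoc = conet.brown_combine(conet.permutation_pvalues(table, b=199, seed=2))
        base = conet.build_network(assoc, table, score_threshold=0.2, p_threshold=0.5)
        tighter = conet.build_network(assoc, table, score_threshold=0.4, p_threshold=0.2)
        base_pairs = {frozenset((e.a, e.b)) for e in base.edges}
        tighter_pairs = {frozenset((e.a, e.b)) for e in tighter.edges}
        assert tighter_pairs <= base_pairs

    def test_invariant_under_reordering(self, rng):
        counts = rng.poisson(30, size=(6, 14)) + 1
        table = make_table(counts)

        def edges_of(tb):
            assoc = conet.brown_combine(conet.permutation_pvalues(tb, b=199, seed=5))
            net = conet.build_network(assoc, tb, score_threshold=0.2, p_threshold=0.6)
            return {frozenset((e.a, e.b)): e.sign for e in net.edges}

        shuffled = table.subset_taxa(table.taxa[::-1])
        assert edges_of(table) == edges_of(shuffled)


def _net_from_pairs(pairs, signs=None):
    nodes = {}
    edges = []
    signs = signs or {}
    for a, b in pairs:
        nodes.setdefault(a, 0.1)
        nodes.setdefault(b, 0.1)
        edges.append(conet.Edge(a, b, signs.get((a, b), 1), 0.01, 0.8))
    return conet.CoNetwork(nodes, edges)


class TestTopology:
    def test_density_from_reported_counts(self):
        assert round(conet.density(44, 566), 2) == 0.60

    def test_triangle(self):
        net = _net_from_pairs([("a", "b"), ("b", "c"), ("a", "c")])
        t = conet.topology(net)
        assert t.clustering_coefficient == pytest.approx(1.0)
        assert t.average_path_length == pytest.approx(1.0)
        assert t.network_density == pytest.approx(1.0)

    def test_path_graph_hand_enumeration(self):
        net = _net_from_pairs([("a", "b"), ("b", "c"), ("c", "d")])
        t = conet.topology(net)
        assert t.clustering_coefficient == 0.0
        assert t.average_path_length == pytest.approx(5 / 3)

    def test_sign_percentages(self):
        net = _net_from_pairs([("a", "b"), ("b", "c"), ("a", "c")],
                              signs={("a", "c"): -1})
        t = conet.topology(net)
        assert t.positive_pct == pytest.approx(200 / 3)
        assert t.positive_pct + t.negative_pct == pytest.approx(100.0)

    def test_matches_networkx(self, rng):
        import networkx as nx

        g = nx.gnp_random_graph(15, 0.3, seed=4)
        pairs = [(f"n{u}", f"n{v}") for u, v in g.edges]
        net = _net_from_pairs(pairs)
        for u in g.nodes:
            net.nodes.setdefault(f"n{u}", 0.1)
        t = conet.topology(net)
        assert t.clustering_coefficient == pytest.approx(nx.average_clustering(g))
        assert t.network_density == pytest.approx(nx.density(g))

    def test_too_small_rejected(self):
        net = conet.CoNetwork({"a": 0.1}, [])
        with pytest.raises(ValueError):
            conet.topology(net)


class TestDetectHubs:
    def test_star_graph(self):
        net = _net_from_pairs([("hub", f"leaf{i}") for i in range(5)])
        hubs = conet.detect_hubs(net, cutoff=0.2)
        assert hubs[0] == "hub"
        assert set(hubs) == {"hub", "leaf0", "leaf1", "leaf2", "leaf3", "leaf4"}

    def test_empty_network(self):
        assert conet.detect_hubs(conet.CoNetwork({}, [])) == []

    def test_cutoff_excludes_low_degree(self):
        net = _net_from_pairs([("hub", f"leaf{i}") for i in range(5)])
        assert conet.detect_hubs(net, cutoff=0.5) == ["hub"]


class TestCoNetworkInvariants:
    def test_self_loop_rejected(self):
        with pytest.raises(ValueError):
            conet.CoNetwork({"a": 0.1}, [conet.Edge("a", "a", 1, 0.01, 0.9)])

    def test_parallel_edge_rejected(self):
        with pytest.raises(ValueError):
            conet.CoNetwork({"a": 0.1, "b": 0.1},
                            [conet.Edge("a", "b", 1, 0.01, 0.9),
                             conet.Edge("b", "a", -1, 0.01, -0.9)])

    def test_dangling_endpoint_rejected(self):
        with pytest.raises(ValueError):
            conet.CoNetwork({"a": 0.1}, [conet.Edge("a", "b", 1, 0.01, 0.9)])
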