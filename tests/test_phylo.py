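import itertools
import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.linalg import expm
from scipy.stats import gamma as gamma_dist

from elemtrace import (
    GtrGammaModel,
    Msa,
    PhyloTree,
    QueryElement,
    bootstrap_support,
    discrete_gamma_rates,
    jc_distance_matrix,
    log_likelihood,
    neighbor_joining,
    optimize_branch_lengths,
    parse_newick,
    read_newick,
    write_newick,
)
from elemtrace.fixtures import SimSpec, evolve_along_tree
from elemtrace.phylo import (
    JC_DISTANCE_CAP,
    LikelihoodEngine,
    TreeNode,
    write_tree_files,
)
from elemtrace.sequence_io import DataError

from conftest import random_dna


def tree_distances(tree: PhyloTree) -> dict[tuple[str, str], float]:
    """Leaf-to-leaf path lengths (independent of NJ internals)."""
    import networkx as nx

    g = nx.Graph()

    def walk(node, name_of):
        my = name_of[id(node)]
        for ch in node.children:
            name_of[id(ch)] = ch.label if ch.is_leaf else f"i{id(ch)}"
            g.add_edge(my, name_of[id(ch)], weight=ch.length or 0.0)
            walk(ch, name_of)

    names = {id(tree.root): "root"}
    walk(tree.root, names)
    leaves = tree.leaf_labels()
    out = {}
    for a, b in itertools.combinations(sorted(leaves), 2):
        out[(a, b)] = nx.shortest_path_length(g, a, b, weight="weight")
    return out


def additive_splits(dist: np.ndarray, labels: list[str]) -> set[frozenset]:
    """Brute-force oracle: all splits supported by every quartet of distances."""
    n = len(labels)
    idx = range(n)
    ref = min(labels)
    valid = set()
    for size in range(2, n - 1):
        for side in itertools.combinations(idx, size):
            other = [i for i in idx if i not in side]
            if len(other) < 2:
                continue
            ok = True
            for i, j in itertools.combinations(side, 2):
                for k, l in itertools.combinations(other, 2):
                    same = dist[i, j] + dist[k, l]
                    cross = min(
                        dist[i, k] + dist[j, l], dist[i, l] + dist[j, k]
                    )
                    if same >= cross:
                        ok = False
                        break
                if not ok:
                    break
            if ok:
                names = frozenset(labels[i] for i in side)
                if ref in names:
                    names = frozenset(labels) - names
                valid.add(names)
    return valid


def random_binary_tree(rng, labels: list[str]) -> PhyloTree:
    """Random topology by sequential attachment, positive branch lengths."""
    nodes = [TreeNode(label=labels[0]), TreeNode(label=labels[1]), TreeNode(label=labels[2])]
    for node in nodes:
        node.length = float(rng.uniform(0.1, 1.0))
    root = TreeNode(children=list(nodes))
    edges = list(nodes)
    for label in labels[3:]:
        target = edges[rng.integers(0, len(edges))]
        parent = next(n for n in _all_nodes(root) if target in n.children)
        split = TreeNode(length=float(rng.uniform(0.1, 1.0)))
        leaf = TreeNode(label=label, length=float(rng.uniform(0.1, 1.0)))
        parent.children.remove(target)
        target.length = float(rng.uniform(0.1, 1.0))
        split.children = [target, leaf]
        parent.children.append(split)
        edges.extend([split, leaf])
    return PhyloTree(root=root)


def _all_nodes(root):
    yield root
    for ch in root.children:
        yield from _all_nodes(ch)


class TestJcDistances:
    def test_identical_rows_zero(self):
        msa = Msa(rows=[("a", "ACGTAC"), ("b", "ACGTAC")])
        assert jc_distance_matrix(msa)[0, 1] == 0.0

    def test_closed_form_at_p_03(self):
        # 3 mismatches over 10 shared columns -> p = 0.3
        msa = Msa(rows=[("a", "AAAAAAAAAA"), ("b", "CCCAAAAAAA")])
        d = jc_distance_matrix(msa)[0, 1]
        assert d == pytest.approx(-0.75 * math.log(1 - 0.4), abs=1e-12)

    def test_saturation_capped(self):
        msa = Msa(rows=[("a", "AAAA"), ("b", "CCCA")])  # p = 0.75
        assert jc_distance_matrix(msa)[0, 1] == JC_DISTANCE_CAP

    def test_gaps_and_n_excluded(self):
        msa = Msa(rows=[("a", "ACGT-A"), ("b", "ACGTAN")])
        # only the first 4 columns count; all match
        assert jc_distance_matrix(msa)[0, 1] == 0.0


class TestNeighborJoining:
    def test_hand_additive_four_taxon_case(self):
        labels = ["A", "B", "C", "D"]
        d = np.array(
            [
                [0, 3, 6, 7],
                [3, 0, 7, 8],
                [6, 7, 0, 7],
                [7, 8, 7, 0],
            ],
            dtype=float,
        )
        tree = neighbor_joining(d, labels)
        splits = set(tree.bipartitions())
        assert splits == {frozenset({"C", "D"})}
        paths = tree_distances(tree)
        for (a, b), expected in {
            ("A", "B"): 3.0,
            ("C", "D"): 7.0,
            ("A", "C"): 6.0,
            ("A", "D"): 7.0,
            ("B", "C"): 7.0,
            ("B", "D"): 8.0,
        }.items():
            assert paths[(a, b)] == pytest.approx(expected)

    def test_three_leaves_three_point_formula(self):
        d = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], dtype=float)
        tree = neighbor_joining(d, ["A", "B", "C"])
        lengths = {n.label: n.length for n in tree.root.children}
        assert lengths["A"] == pytest.approx(1.0)
        assert lengths["B"] == pytest.approx(3.0)
        assert lengths["C"] == pytest.approx(5.0)

    def test_all_equal_distances_deterministic(self):
        d = np.ones((5, 5)) - np.eye(5)
        t1 = neighbor_joining(d, list("ABCDE")).newick()
        t2 = neighbor_joining(d, list("ABCDE")).newick()
        assert t1 == t2

    def test_two_taxa_single_edge(self):
        tree = neighbor_joining(np.array([[0.0, 1.0], [1.0, 0.0]]), ["A", "B"])
        assert tree_distances(tree)[("A", "B")] == pytest.approx(1.0)

    @pytest.mark.parametrize("n_taxa", [4, 5, 6, 7, 8])
    def test_recovers_additive_topologies(self, n_taxa):
        """NJ on additive matrices returns the generating tree's splits.

        For <= 6 taxa the splits are cross-checked against a brute-force
        quartet enumeration oracle over all label subsets.
        """
        rng = np.random.default_rng(100 + n_taxa)
        labels = [f"t{i}" for i in range(n_taxa)]
        for _ in range(5):
            truth = random_binary_tree(rng, labels)
            paths = tree_distances(truth)
            d = np.zeros((n_taxa, n_taxa))
            for (a, b), v in paths.items():
                i, j = labels.index(a), labels.index(b)
                d[i, j] = d[j, i] = v
            nj = neighbor_joining(d, labels)
            assert set(nj.bipartitions()) == set(truth.bipartitions())
            if n_taxa <= 6:
                assert set(nj.bipartitions()) == additive_splits(d, labels)


class TestDiscreteGamma:
    def test_large_alpha_limit(self):
        # the outermost bin mean deviates from 1 by ~1.27/sqrt(alpha)
        rates = discrete_gamma_rates(1e6, 4)
        assert np.allclose(rates, 1.0, atol=1.5e-3)
        assert np.allclose(discrete_gamma_rates(1e8, 4), 1.0, atol=1.5e-4)

    @pytest.mark.parametrize("alpha", [0.2, 0.5, 1.0, 3.7])
    def test_mean_is_one(self, alpha):
        assert discrete_gamma_rates(alpha, 4).mean() == pytest.approx(1.0, abs=1e-14)

    def test_matches_quadrature_oracle(self):
        alpha, n = 0.5, 4
        edges = gamma_dist.ppf(np.arange(n + 1) / n, a=alpha, scale=1 / alpha)
        expected = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            val, _ = quad(
                lambda x: x * gamma_dist.pdf(x, a=alpha, scale=1 / alpha),
                lo,
                min(hi, 1e3),
                limit=200,
            )
            expected.append(n * val)
        rates = discrete_gamma_rates(alpha, n)
        assert np.allclose(rates, expected, atol=1e-6)


def jc_model(alpha=1.0, n_categories=1):
    return GtrGammaModel(alpha=alpha, n_categories=n_categories)


class TestLogLikelihood:
    def test_single_leaf_single_base(self):
        tree = PhyloTree(root=TreeNode(label="a"))
        msa = Msa(rows=[("a", "A")])
        assert log_likelihood(tree, msa, jc_model()) == pytest.approx(math.log(0.25))

    def test_long_branch_independence_limit(self):
        tree = PhyloTree(
            root=TreeNode(
                children=[TreeNode(label="a", length=25.0), TreeNode(label="b", length=25.0)]
            )
        )
        for x, y in [("A", "A"), ("A", "C"), ("G", "T")]:
            msa = Msa(rows=[("a", x), ("b", y)])
            lnl = log_likelihood(tree, msa, jc_model())
            assert math.exp(lnl) == pytest.approx(1.0 / 16.0, abs=1e-6)

    def test_three_leaf_matches_exhaustive_enumeration(self):
        """Pruning equals a brute-force sum over internal states using scipy expm."""
        model = GtrGammaModel(
            exchangeabilities=(1.2, 2.5, 0.8, 1.1, 3.0, 1.0),
            base_freqs=(0.3, 0.2, 0.25, 0.25),
            alpha=0.7,
            n_categories=4,
        )
        t = {"a": 0.1, "b": 0.35, "c": 0.6}
        tree = PhyloTree(
            root=TreeNode(
                children=[TreeNode(label=n, length=t[n]) for n in ("a", "b", "c")]
            )
        )
        msa = Msa(rows=[("a", "AG"), ("b", "CG"), ("c", "AT")])
        lnl = log_likelihood(tree, msa, model)

        Q = model.rate_matrix
        pi = np.array(model.base_freqs)
        code = {"A": 0, "C": 1, "G": 2, "T": 3}
        rates = discrete_gamma_rates(model.alpha, model.n_categories)
        expected = 0.0
        for col in ["ACA", "GGT"]:
            col_lik = 0.0
            for rate in rates:
                P = {n: expm(Q * t[n] * rate) for n in t}
                s = 0.0
                for x in range(4):  # internal (root) state enumeration
                    s += (
                        pi[x]
                        * P["a"][x, code[col[0]]]
                        * P["b"][x, code[col[1]]]
                        * P["c"][x, code[col[2]]]
                    )
                col_lik += s / len(rates)
            expected += math.log(col_lik)
        assert lnl == pytest.approx(expected, abs=1e-10)

    def test_gaps_are_missing_data(self):
        tree = PhyloTree(
            root=TreeNode(
                children=[TreeNode(label="a", length=0.1), TreeNode(label="b", length=0.1)]
            )
        )
        full = log_likelihood(tree, Msa(rows=[("a", "A"), ("b", "-")]), jc_model())
        assert full == pytest.approx(math.log(0.25))

    def test_pulley_principle_rerooting_invariance(self, rng):
        """lnL is identical for different rootings of the same unrooted tree."""
        model = GtrGammaModel(alpha=0.8)
        seqs = {n: random_dna(rng, 200) for n in "abcd"}
        msa = Msa(rows=list(seqs.items()))
        # rooting 1: trifurcation at the inner node next to (a,b)
        t1 = parse_newick("((a:0.1,b:0.2):0.15,c:0.3,d:0.25);")
        # rooting 2: same unrooted tree, trifurcation next to (c,d)
        t2 = parse_newick("((c:0.3,d:0.25):0.15,a:0.1,b:0.2);")
        # rooting 3: rooted on the internal edge (bifurcating root)
        t3 = parse_newick("((a:0.1,b:0.2):0.05,(c:0.3,d:0.25):0.1);")
        l1 = log_likelihood(t1, msa, model)
        l2 = log_likelihood(t2, msa, model)
        l3 = log_likelihood(t3, msa, model)
        assert l1 == pytest.approx(l2, abs=1e-8)
        assert l1 == pytest.approx(l3, abs=1e-8)

    def test_zero_columns_error(self):
        tree = PhyloTree(root=TreeNode(label="a"))
        msa = Msa.__new__(Msa)
        msa.rows = [("a", "")]
        with pytest.raises(DataError):
            log_likelihood(tree, msa, jc_model())


class TestOptimizeBranchLengths:
    def test_two_leaf_matches_grid_search(self, rng):
        model = jc_model()
        a = random_dna(rng, 400)
        b = list(a)
        for i in rng.choice(400, size=40, replace=False):
            b[i] = "ACGT"[(("ACGT".index(b[i])) + 1 + rng.integers(0, 3)) % 4]
        msa = Msa(rows=[("a", a), ("b", "".join(b))])
        tree = PhyloTree(
            root=TreeNode(
                children=[TreeNode(label="a", length=0.05), TreeNode(label="b", length=0.05)]
            )
        )
        opt = optimize_branch_lengths(tree, msa, model)
        total = sum(n.length for n in opt.root.children)
        engine = LikelihoodEngine(msa, model)
        grid = np.linspace(1e-6, 1.0, 2001)
        best_t = None
        best_l = -np.inf
        for t in grid:
            probe = parse_newick(f"(a:{t/2:.8f},b:{t/2:.8f});")
            l = engine.log_likelihood(probe)
            if l > best_l:
                best_l, best_t = l, t
        assert total == pytest.approx(best_t, abs=1e-3)
        assert opt.log_likelihood >= best_l - 1e-6

    def test_already_optimal_is_fixed_point(self, rng):
        model = jc_model()
        seqs = {n: random_dna(rng, 150) for n in "abc"}
        msa = Msa(rows=list(seqs.items()))
        tree = neighbor_joining(jc_distance_matrix(msa), list(seqs))
        once = optimize_branch_lengths(tree, msa, model)
        twice = optimize_branch_lengths(once, msa, model)
        assert twice.log_likelihood == pytest.approx(once.log_likelihood, abs=2e-3)

    def test_recovers_simulated_branch_lengths(self):
        """Edge lengths recovered within 15% on a 5000-column simulation."""
        truth = parse_newick("((A:0.12,B:0.08):0.1,C:0.15,D:0.2);")
        model = jc_model(n_categories=1)
        query = QueryElement(
            id="root", seq=random_dna(np.random.default_rng(77), 5000)
        )
        spec = SimSpec(query=query, tree=truth, model=model, seed=77)
        leaves = evolve_along_tree(spec)
        msa = Msa(rows=[(n, leaves[n]) for n in ("A", "B", "C", "D")])
        start = neighbor_joining(jc_distance_matrix(msa), list("ABCD"))
        fitted = optimize_branch_lengths(start, msa, model, tol=1e-4)
        assert set(fitted.bipartitions()) == set(truth.bipartitions())
        true_paths = tree_distances(truth)
        fit_paths = tree_distances(fitted)
        for pair, tv in true_paths.items():
            assert fit_paths[pair] == pytest.approx(tv, rel=0.15)


class TestBootstrap:
    def test_identical_rows_full_support(self, rng):
        seq = random_dna(rng, 60)
        msa = Msa(rows=[(f"s{i}", seq) for i in range(5)])
        result = bootstrap_support(msa, n_replicates=20, seed=3, optimize=False)
        supports = [
            n.support
            for n in result.tree.postorder()
            if n.support is not None
        ]
        assert supports and all(s == 100 for s in supports)

    def test_replicate_count_and_seeding(self, rng):
        seqs = [(f"s{i}", random_dna(rng, 80)) for i in range(5)]
        msa = Msa(rows=seqs)
        r1 = bootstrap_support(msa, n_replicates=25, seed=11, optimize=False)
        r2 = bootstrap_support(msa, n_replicates=25, seed=11, optimize=False)
        assert len(r1.replicates) == 25
        assert [t.newick() for t in r1.replicates] == [t.newick() for t in r2.replicates]
        supports1 = sorted(
            n.support for n in r1.tree.postorder() if n.support is not None
        )
        supports2 = sorted(
            n.support for n in r2.tree.postorder() if n.support is not None
        )
        assert supports1 == supports2

    def test_short_internal_edge_gets_lower_support(self):
        """A hard-to-resolve (short) internal edge earns less support than easy ones."""
        newick = (
            "(((A:0.1,B:0.1):0.004,(C:0.1,D:0.1):0.004):0.1,(E:0.1,F:0.1):0.1,G:0.3);"
        )
        truth = parse_newick(newick)
        model = jc_model(n_categories=1)
        wins = 0
        trials = 12
        for trial in range(trials):
            query = QueryElement(
                id="root", seq=random_dna(np.random.default_rng(500 + trial), 400)
            )
            spec = SimSpec(query=query, tree=truth, model=model, seed=500 + trial)
            leaves = evolve_along_tree(spec)
            msa = Msa(rows=sorted(leaves.items()))
            result = bootstrap_support(
                msa, model, n_replicates=30, seed=trial, optimize=False
            )
            supports = {
                frozenset(split): node.support
                for split, node in result.tree.bipartitions().items()
                if node.support is not None
            }
            short_split = frozenset({"A", "B", "C", "D"})
            easy_split = frozenset({"E", "F"})
            if short_split in supports and easy_split in supports:
                if supports[short_split] <= supports[easy_split]:
                    wins += 1
            else:
                wins += 1  # short edge not even recovered: counts as low support
        assert wins >= trials - 2

    def test_small_alignment_no_supports(self, rng):
        msa = Msa(rows=[("a", random_dna(rng, 40)), ("b", random_dna(rng, 40)), ("c", random_dna(rng, 40))])
        result = bootstrap_support(msa, n_replicates=10, seed=1, optimize=False)
        assert all(n.support is None for n in result.tree.postorder())


class TestNewick:
    def test_round_trip_topology_lengths_supports(self, tmp_path):
        tree = parse_newick("((A:1,B:2)62:2,(C:3,D:4)88:1,E:2.5);")
        p = tmp_path / "t.nwk"
        write_newick(tree, p)
        back = read_newick(p)
        assert back.newick() == tree.newick()
        supports = sorted(
            n.support for n in back.postorder() if n.support is not None
        )
        assert supports == [62, 88]

    def test_branch_length_precision(self, tmp_path):
        tree = parse_newick("(A:0.123456789,B:0.000001234);")
        p = tmp_path / "t.nwk"
        write_newick(tree, p)
        lengths = sorted(
            n.length for n in read_newick(p).postorder() if n.length is not None
        )
        assert lengths[0] == pytest.approx(0.000001, abs=1e-6)
        assert lengths[1] == pytest.approx(0.123457, abs=1e-6)

    def test_malformed_reports_position(self):
        with pytest.raises(DataError, match="position"):
            parse_newick("((A:1,B:2:2,C:3);")

    def test_dendropy_can_parse_output(self, rng):
        dendropy = pytest.importorskip("dendropy")
        seqs = [(f"s{i}", random_dna(rng, 60)) for i in range(5)]
        msa = Msa(rows=seqs)
        result = bootstrap_support(msa, n_replicates=10, seed=2, optimize=False)
        t = dendropy.Tree.get(data=result.tree.newick(), schema="newick")
        assert {l.taxon.label for l in t.leaf_node_iter()} == {n for n, _ in seqs}

    def test_tree_files_written(self, tmp_path, rng):
        seqs = [(f"s{i}", random_dna(rng, 60)) for i in range(4)]
        result = bootstrap_support(Msa(rows=seqs), n_replicates=7, seed=5, optimize=False)
        paths = write_tree_files(result, tmp_path)
        assert len(open(paths["tree_bootstraps"]).readlines()) == 7
        assert "n_replicates\t7" in open(paths["tree_info"]).read()
        read_newick(paths["tree_best"])
        read_newick(paths["tree_support"])
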