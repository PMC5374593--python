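import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from epitree.datatypes import MISSING, DiscreteData
from epitree.simulate import SimulationSpec, simulate_dataset
from epitree.tree import (
    auc,
    auc_cv,
    auc_resub,
    build_mwdt,
    cmi_from_counts,
    cmi_matrix,
    estimate_cmi,
    fit_cpts,
    fit_mwdt,
    joint_counts,
    log_likelihood,
    maximum_spanning_tree,
    score_samples,
)

from oracles import (
    all_labeled_trees,
    auc_pair_counting,
    cmi_direct,
    max_tree_weight_exhaustive,
    tree_loglik_direct,
)


def _orient(edges, root=0):
    """Direct an undirected tree away from the root: (child, parent) pairs."""
    adj = {}
    for a, b in edges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    out, seen, stack = [], {root}, [root]
    while stack:
        u = stack.pop()
        for v in adj.get(u, []):
            if v not in seen:
                seen.add(v)
                out.append((v, u))
                stack.append(v)
    return out


def _data_from_counts(counts):
    """Expand a (2, kx, ky) count cube into x, y, c sample vectors."""
    xs, ys, cs = [], [], []
    counts = np.asarray(counts, dtype=int)
    for c, a, b in itertools.product(*map(range, counts.shape)):
        xs += [a] * counts[c, a, b]
        ys += [b] * counts[c, a, b]
        cs += [c] * counts[c, a, b]
    return np.array(xs), np.array(ys), np.array(cs)


class TestCMI:
    def test_independence_gives_zero(self):
        counts = np.array([[[10, 10], [10, 10]], [[10, 10], [10, 10]]])
        assert cmi_from_counts(counts) == pytest.approx(0.0, abs=1e-12)

    def test_identical_binary_uniform_gives_log2(self):
        x = np.tile([0, 1], 50)
        c = np.repeat([0, 1], 50)
        assert estimate_cmi(x, x, c, 2, 2) == pytest.approx(np.log(2))

    def test_arbitrary_table_matches_direct_oracle(self, rng):
        counts = rng.integers(0, 20, size=(2, 3, 3))
        counts[0, 0, 0] += 1  # ensure nonempty
        assert cmi_from_counts(counts) == pytest.approx(
            cmi_direct(counts), abs=1e-12
        )

    def test_pairwise_complete_drops_missing(self):
        x = np.array([0, 1, MISSING, 1, 0, 1])
        y = np.array([0, 1, 1, MISSING, 0, 1])
        c = np.array([0, 0, 0, 1, 1, 1])
        counts = joint_counts(x, y, c, 2, 2)
        assert counts.sum() == 4

    def test_no_complete_triples_error(self):
        x = np.full(4, MISSING)
        with pytest.raises(ValueError):
            estimate_cmi(x, x, np.zeros(4, dtype=int), 2, 2)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_bounds_property(self, seed):
        """0 <= I(X,Y|C) <= min(log kx, log ky) for any count cube."""
        r = np.random.default_rng(seed)
        kx, ky = int(r.integers(2, 5)), int(r.integers(2, 5))
        counts = r.integers(0, 15, size=(2, kx, ky))
        if counts.sum() == 0:
            counts[0, 0, 0] = 1
        v = cmi_from_counts(counts)
        assert -1e-12 <= v <= min(np.log(kx), np.log(ky)) + 1e-9


class TestStructure:
    def test_known_matrix_matches_exhaustive_max(self, rng):
        for _ in range(10):
            W = rng.random((4, 4))
            W = (W + W.T) / 2
            np.fill_diagonal(W, 0)
            edges = maximum_spanning_tree(W)
            total = sum(W[a, b] for a, b in edges)
            assert total == pytest.approx(max_tree_weight_exhaustive(W))

    def test_matches_networkx_oracle(self, rng):
        nx = pytest.importorskip("networkx")
        W = rng.random((8, 8))
        W = (W + W.T) / 2
        g = nx.Graph()
        for i in range(8):
            for j in range(i + 1, 8):
                g.add_edge(i, j, weight=W[i, j])
        t = nx.maximum_spanning_tree(g)
        expected = sum(d["weight"] for _, _, d in t.edges(data=True))
        total = sum(W[a, b] for a, b in maximum_spanning_tree(W))
        assert total == pytest.approx(expected)

    def test_two_variables_single_edge(self, rng):
        X = rng.integers(0, 3, size=(50, 2)).astype(np.int16)
        data = DiscreteData(X, rng.integers(0, 2, 50).astype(np.int8),
                            ["a", "b"], [3, 3])
        tree = build_mwdt(data)
        assert tree.undirected_edges() == {frozenset({"a", "b"})}

    def test_equal_weights_deterministic_tie_break(self):
        W = np.ones((4, 4)) - np.eye(4)
        edges = maximum_spanning_tree(W)
        # lexicographic tie-break: star on node 0
        assert edges == [(0, 1), (0, 2), (0, 3)]

    def test_fewer_than_two_variables_error(self, rng):
        data = DiscreteData(
            rng.integers(0, 3, size=(10, 1)).astype(np.int16),
            rng.integers(0, 2, 10).astype(np.int8), ["a"], [3],
        )
        with pytest.raises(ValueError):
            build_mwdt(data)

    def test_root_has_largest_incident_weight(self, rng):
        X = rng.integers(0, 3, size=(200, 6)).astype(np.int16)
        y = rng.integers(0, 2, 200).astype(np.int8)
        data = DiscreteData(X, y, list("abcdef"), [3] * 6)
        tree = build_mwdt(data)
        inc = {n: 0.0 for n in tree.nodes}
        for child, parent in tree.edges():
            w = tree.edge_weights[(child, parent)]
            inc[child] += w
            inc[parent] += w
        root = tree.roots[0]
        assert inc[root] == pytest.approx(max(inc.values()))


def _small_complete_data(seed=3, n=400, p=5):
    spec = SimulationSpec(seed=seed, n_cases=n // 2, n_controls=n // 2,
                          n_snps=p, n_tree=p, n_causal=0, n_background=0,
                          n_ld_blocks=0, missing_rate=0.0,
                          dependence_noise=0.4, edge_effect=0.3)
    ds, _ = simulate_dataset(spec)
    return DiscreteData.from_dataset(ds, demographics=[])


class TestCPTs:
    def test_alpha_zero_gives_raw_frequencies(self):
        data = _small_complete_data()
        tree = fit_cpts(build_mwdt(data), data, alpha=0.0)
        root = tree.roots[0]
        x = data.column(root)
        for cls in (0, 1):
            sub = x[data.y == cls]
            freq = np.bincount(sub, minlength=3) / len(sub)
            np.testing.assert_allclose(tree.cpts[root][:, cls], freq)

    def test_empty_parent_cell_alpha_one_uniform(self):
        X = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], dtype=np.int16)
        y = np.array([0, 0, 1, 1], dtype=np.int8)
        data = DiscreteData(X, y, ["a", "b"], [3, 3])
        tree = build_mwdt(data)
        tree = fit_cpts(tree, data, alpha=1.0)
        child = tree.edges()[0][0]
        cpt = tree.cpts[child]
        # parent state 2 never occurs: Laplace gives the uniform column
        np.testing.assert_allclose(cpt[:, 2, 0], [1 / 3] * 3)

    def test_three_node_hand_counted(self):
        """CPT entries match manual counting on a tiny chain a->b."""
        X = np.array(
            [[0, 0], [0, 0], [1, 1], [0, 1],  # class 0
             [1, 1], [1, 1], [0, 0], [1, 0]],  # class 1
            dtype=np.int16,
        )
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=np.int8)
        data = DiscreteData(X, y, ["a", "b"], [2, 2])
        tree = build_mwdt(data, root="a")
        tree = fit_cpts(tree, data, alpha=0.0)
        # class 0: a=0 three times (b: 0,0,1), a=1 once (b=1)
        np.testing.assert_allclose(tree.cpts["b"][:, 0, 0], [2 / 3, 1 / 3])
        np.testing.assert_allclose(tree.cpts["b"][:, 1, 0], [0.0, 1.0])
        # class 1: a=1 three times (b: 1,1,0), a=0 once (b=0)
        np.testing.assert_allclose(tree.cpts["b"][:, 1, 1], [1 / 3, 2 / 3])
        np.testing.assert_allclose(tree.cpts["a"][:, 0], [3 / 4, 1 / 4])
        assert np.allclose(tree.class_prior, [0.5, 0.5])

    def test_normalization_of_implied_joint(self):
        """The fitted model's joint over all configurations sums to 1."""
        data = _small_complete_data(p=5)
        tree = fit_mwdt(data, alpha=1.0)
        total = 0.0
        names = tree.nodes
        for config in itertools.product(range(3), repeat=len(names)):
            for cls in (0, 1):
                ll = 0.0
                for name in names:
                    par = tree.parent[name]
                    a = config[names.index(name)]
                    if par is None:
                        ll += np.log(tree.cpts[name][a, cls])
                    else:
                        b = config[names.index(par)]
                        ll += np.log(tree.cpts[name][a, b, cls])
                total += tree.class_prior[cls] * np.exp(ll)
        assert total == pytest.approx(1.0, abs=1e-9)


class TestScoring:
    def test_symmetric_cpts_give_zero_scores(self):
        data = _small_complete_data()
        tree = fit_mwdt(data)
        for name in tree.nodes:
            cpt = tree.cpts[name]
            cpt[..., 1] = cpt[..., 0]
        assert np.allclose(score_samples(tree, data), 0.0)

    def test_root_invariance_of_mle_factorization(self):
        """At alpha = 0 on complete data, any root gives the same scores."""
        data = _small_complete_data(seed=8, n=2000, p=6)
        scores = None
        for root in data.names:
            tree = fit_cpts(build_mwdt(data, root=root), data, alpha=0.0)
            s = score_samples(tree, data)
            if scores is None:
                scores = s
            else:
                np.testing.assert_allclose(s, scores, atol=1e-9)

    def test_three_node_product_oracle(self):
        data = _small_complete_data(p=3)
        tree = fit_mwdt(data)
        s = score_samples(tree, data)
        for i in range(5):
            direct = 0.0
            for name in tree.nodes:
                a = data.column(name)[i]
                par = tree.parent[name]
                if par is None:
                    direct += np.log(tree.cpts[name][a, 1] / tree.cpts[name][a, 0])
                else:
                    b = data.column(par)[i]
                    direct += np.log(
                        tree.cpts[name][a, b, 1] / tree.cpts[name][a, b, 0]
                    )
            assert s[i] == pytest.approx(direct, rel=1e-12)

    def test_missing_factors_skipped_symmetrically(self):
        data = _small_complete_data(p=3)
        tree = fit_mwdt(data)
        X2 = data.X.copy()
        X2[0, :] = MISSING
        data2 = DiscreteData(X2, data.y, data.names, data.ks)
        assert score_samples(tree, data2)[0] == pytest.approx(0.0)


class TestMLEEquivalence:
    def test_mwdt_maximizes_training_likelihood(self, rng):
        """The learned tree's alpha=0 log-likelihood beats every other
        labeled spanning tree (exhaustive check at n=4)."""
        for _ in range(5):
            n, p = 300, 4
            X = rng.integers(0, 3, size=(n, p)).astype(np.int16)
            # plant correlation so the choice is not degenerate
            X[:, 1] = np.where(rng.random(n) < 0.7, X[:, 0], X[:, 1])
            y = rng.integers(0, 2, n).astype(np.int8)
            data = DiscreteData(X, y, list("abcd"), [3] * p)
            best = fit_cpts(build_mwdt(data), data, alpha=0.0)
            ll_best = log_likelihood(best, data)
            for edges in all_labeled_trees(p):
                directed = _orient(edges, root=0)
                ll = tree_loglik_direct(directed, 0, X, y)
                assert ll <= ll_best + 1e-9


class TestAUC:
    def test_perfect_separation(self):
        assert auc([1, 2, 3, -1, -2], [1, 1, 1, 0, 0]) == pytest.approx(1.0)

    def test_all_ties(self):
        assert auc([5, 5, 5, 5], [0, 1, 0, 1]) == pytest.approx(0.5)

    def test_pair_counting_oracle(self):
        scores = [0.3, 0.1, 0.4, 0.4, 0.2, 0.9]
        labels = [1, 0, 1, 0, 0, 1]
        assert auc(scores, labels) == pytest.approx(
            auc_pair_counting(scores, labels)
        )

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            auc([1, 2], [1, 1])


class TestCrossValidation:
    def test_deterministic_given_seed(self):
        data = _small_complete_data()
        a = auc_cv(data, k=3, seed=42)
        b = auc_cv(data, k=3, seed=42)
        assert a == b

    def test_deterministic_variable_gives_perfect_auc(self, rng):
        n = 120
        y = np.repeat([0, 1], n // 2).astype(np.int8)
        X = np.column_stack(
            [y.astype(np.int16), rng.integers(0, 3, n).astype(np.int16)]
        )
        data = DiscreteData(X, y, ["copy", "noise"], [2, 3])
        assert auc_cv(data, k=3, seed=0) == pytest.approx(1.0)

    def test_null_auc_near_half(self, rng):
        n, p = 600, 6
        X = rng.integers(0, 3, size=(n, p)).astype(np.int16)
        y = np.repeat([0, 1], n // 2).astype(np.int8)
        data = DiscreteData(X, y, [f"v{i}" for i in range(p)], [3] * p)
        assert abs(auc_cv(data, k=3, seed=1) - 0.5) < 0.06

    def test_resub_definitional(self):
        data = _small_complete_data()
        tree = fit_mwdt(data)
        assert auc_resub(data, tree) == pytest.approx(
            auc(score_samples(tree, data), data.y)
        )

    def test_resub_optimism(self):
        """Resubstitution AUC >= CV AUC on planted-signal data (mean
        over replicates)."""
        diffs = []
        for seed in range(8):
            spec = SimulationSpec(seed=seed, n_cases=100, n_controls=100,
                                  n_snps=10, n_tree=6, n_causal=2,
                                  n_background=0, n_ld_blocks=0,
                                  causal_delta=0.15, missing_rate=0.0)
            ds, _ = simulate_dataset(spec)
            data = DiscreteData.from_dataset(ds, demographics=[])
            tree = fit_mwdt(data)
            diffs.append(auc_resub(data, tree) - auc_cv(data, k=3, seed=seed))
        assert np.mean(diffs) > 0
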