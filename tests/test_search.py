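import numpy as np
import pytest

from epitree.assoc import rank_snps_cmh
from epitree.datatypes import MISSING
from epitree.search import (
    backward_search,
    bin_and_tag,
    build_final_network,
    ld_r2,
)
from epitree.simulate import SimulationSpec, simulate_dataset

from conftest import make_dataset


class TestLDr2:
    def test_self_correlation(self, rng):
        g = rng.binomial(2, 0.3, size=100).astype(np.int8)
        assert ld_r2(g, g) == pytest.approx(1.0)

    def test_independent_snps_near_zero(self, rng):
        vals = []
        for _ in range(100):
            a = rng.binomial(2, 0.3, size=2000).astype(np.int8)
            b = rng.binomial(2, 0.3, size=2000).astype(np.int8)
            vals.append(ld_r2(a, b))
        assert np.mean(vals) < 0.005

    def test_duplicate_with_flips_matches_direct_corr(self, rng):
        a = rng.binomial(2, 0.4, size=500).astype(np.int8)
        b = a.copy()
        flip = rng.random(500) < 0.1
        b[flip] = rng.binomial(2, 0.4, size=500).astype(np.int8)[flip]
        r = np.corrcoef(a.astype(float), b.astype(float))[0, 1]
        assert ld_r2(a, b) == pytest.approx(r * r, rel=1e-12)

    def test_pairwise_complete_and_monomorphic(self, rng):
        a = rng.binomial(2, 0.4, size=100).astype(np.int8)
        b = a.copy()
        a[:10] = MISSING
        ok = a != MISSING
        r = np.corrcoef(a[ok].astype(float), b[ok].astype(float))[0, 1]
        assert ld_r2(a, b) == pytest.approx(r * r)
        mono = np.zeros(100, dtype=np.int8)
        with pytest.warns(UserWarning, match="monomorphic"):
            assert ld_r2(mono, b) == 0.0


def _ld_fixture():
    """6 SNPs on one chromosome: {rs1,rs2,rs3} tightly linked, rs4/rs5
    moderately linked, rs6 independent."""
    rng = np.random.default_rng(21)
    n = 500
    base = rng.binomial(2, 0.4, size=n).astype(np.int8)

    def noisy(src, flip_p):
        out = src.copy()
        flip = rng.random(n) < flip_p
        out[flip] = rng.binomial(2, 0.4, size=n).astype(np.int8)[flip]
        return out

    G = np.column_stack(
        [
            base,
            noisy(base, 0.05),
            noisy(base, 0.05),
            (b2 := rng.binomial(2, 0.3, size=n).astype(np.int8)),
            noisy(b2, 0.2),
            rng.binomial(2, 0.5, size=n).astype(np.int8),
        ]
    )
    y = np.tile([0, 1], n // 2)
    return make_dataset(G, y)


class TestBinAndTag:
    def test_no_linkage_all_singletons(self, rng):
        n = 300
        G = rng.binomial(2, 0.3, size=(n, 5)).astype(np.int8)
        ds = make_dataset(G, np.tile([0, 1], n // 2))
        bins = bin_and_tag(ds, ds.snp_ids, r2_threshold=0.4)
        assert sorted(bins.tags) == sorted(ds.snp_ids)
        assert all(len(b) == 1 for b in bins.bins)

    def test_perfect_ld_one_bin_lowest_p_tag(self, rng):
        g = rng.binomial(2, 0.4, size=100).astype(np.int8)
        G = np.column_stack([g, g, g])
        ds = make_dataset(G, np.tile([0, 1], 50))
        p = {"rs1": 0.5, "rs2": 0.01, "rs3": 0.2}
        bins = bin_and_tag(ds, ds.snp_ids, 0.4, p)
        assert len(bins.bins) == 1
        assert bins.tags == ["rs2"]

    def test_greedy_trace_on_constructed_fixture(self):
        """Bins match a hand-executed greedy trace on the 6-SNP fixture."""
        ds = _ld_fixture()
        p = {f"rs{i}": i / 10 for i in range(1, 7)}
        bins = bin_and_tag(ds, ds.snp_ids, r2_threshold=0.4, p_values=p)
        as_sets = {frozenset(b) for b in bins.bins}
        assert as_sets == {
            frozenset({"rs1", "rs2", "rs3"}),
            frozenset({"rs4", "rs5"}),
            frozenset({"rs6"}),
        }
        tag_of = bins.snp_to_tag
        assert tag_of["rs1"] == "rs1"  # smallest p in its bin
        assert tag_of["rs4"] == "rs4"
        assert tag_of["rs6"] == "rs6"

    def test_partition_and_proxy_property(self):
        ds = _ld_fixture()
        bins = bin_and_tag(ds, ds.snp_ids, r2_threshold=0.4)
        flat = sorted(s for b in bins.bins for s in b)
        assert flat == sorted(ds.snp_ids)
        for tag, members in zip(bins.tags, bins.bins):
            for m in members:
                if m != tag:
                    gi = ds.genotypes[:, ds.snp_index(tag)]
                    gj = ds.genotypes[:, ds.snp_index(m)]
                    assert ld_r2(gi, gj) >= 0.4

    def test_cross_chromosome_never_binned(self, rng):
        g = rng.binomial(2, 0.4, size=200).astype(np.int8)
        G = np.column_stack([g, g])
        ds = make_dataset(G, np.tile([0, 1], 100), chromosomes=["1", "2"])
        bins = bin_and_tag(ds, ds.snp_ids, r2_threshold=0.4)
        assert len(bins.bins) == 2


def _search_dataset(n_snps, seed=5, n=300):
    spec = SimulationSpec(
        seed=seed, n_cases=n // 2, n_controls=n // 2, n_snps=n_snps,
        n_tree=0, n_causal=3, n_background=5, n_ld_blocks=0,
        missing_rate=0.0,
        demographics=[d for d in SimulationSpec(seed=0).demographics
                      if d.name in ("race", "sex", "education")],
    )
    return simulate_dataset(spec)


class TestBackwardSearch:
    def test_single_iteration_when_under_step(self):
        ds, _ = _search_dataset(50)
        cand = ds.snp_ids[:40]
        cmh_p = {s: i / 100 for i, s in enumerate(cand)}
        _, trace, _ = backward_search(ds, cand, cmh_p, step=50, seed=0)
        assert [r["n_snps"] for r in trace.records] == [40]

    def test_schedule_arithmetic(self):
        ds, _ = _search_dataset(120)
        cand = ds.snp_ids
        cmh_p = {s: i / 1000 for i, s in enumerate(cand)}
        _, trace, _ = backward_search(ds, cand, cmh_p, step=50, seed=0)
        assert [r["n_snps"] for r in trace.records] == [120, 70, 20]
        # the removed SNPs are always those with the largest p-values
        removed_first = set(trace.records[1]["removed"])
        worst_50 = set(sorted(cand, key=lambda s: -cmh_p[s])[:50])
        assert removed_first == worst_50

    def test_demographics_always_included(self):
        ds, _ = _search_dataset(60)
        cand = ds.snp_ids
        cmh_p = {s: i / 1000 for i, s in enumerate(cand)}
        tree, _, _ = backward_search(ds, cand, cmh_p, step=50, seed=0)
        for demo in ds.samples.schema.variables:
            assert demo in tree.nodes

    def test_planted_informative_snps_retained(self):
        """Best network keeps the informative SNPs when noise SNPs are
        given larger CMH p-values."""
        kept_counts = []
        for seed in range(4):
            spec = SimulationSpec(
                seed=seed, n_cases=250, n_controls=250, n_snps=100,
                n_tree=0, n_causal=10, n_background=0, n_ld_blocks=0,
                causal_delta=0.3, missing_rate=0.0,
                demographics=[d for d in SimulationSpec(seed=0).demographics
                              if d.name in ("race", "sex")],
            )
            ds, truth = simulate_dataset(spec)
            table, _ = rank_snps_cmh(ds, strata="race", p_threshold=1.1)
            cmh_p = dict(zip(table["SNP"], table["P"]))
            tree, _, _ = backward_search(
                ds, ds.snp_ids, cmh_p, step=30, seed=seed
            )
            kept = sum(1 for s in truth["causal_snps"] if s in tree.nodes)
            kept_counts.append(kept)
        assert np.mean(kept_counts) >= 8


class TestFinalNetwork:
    def test_ld_free_candidates_identical_branches(self):
        ds, _ = _search_dataset(30, seed=13)
        table, _ = rank_snps_cmh(ds, strata="race", p_threshold=1.1)
        cand = list(table["SNP"].head(20))
        tree, traces, summary = build_final_network(
            ds, table, cand, step=50, seed=0
        )
        assert summary["n_tags"] == len(cand)
        assert summary["auc_backward"] == pytest.approx(
            summary["auc_ld_backward"]
        )
        assert summary["winner"] == "backward"

    def test_duplicated_snp_dropped_by_ld_branch(self, rng):
        n = 400
        g = rng.binomial(2, 0.4, size=n).astype(np.int8)
        G = np.column_stack(
            [g, g] + [rng.binomial(2, 0.3, size=n).astype(np.int8)
                      for _ in range(4)]
        )
        y = np.tile([0, 1], n // 2)
        ds = make_dataset(G, y, race=rng.integers(0, 2, n),
                          sex=rng.integers(0, 2, n))
        table, _ = rank_snps_cmh(ds, strata="race", p_threshold=1.1)
        _, traces, summary = build_final_network(
            ds, table, ds.snp_ids, step=50, seed=0
        )
        assert summary["n_tags"] == 5  # one of the duplicates collapsed
        assert traces["ld+backward"].records[0]["n_snps"] == 5
        assert traces["backward"].records[0]["n_snps"] == 6

    def test_deterministic_given_seed(self):
        ds, _ = _search_dataset(30, seed=17)
        table, cand = rank_snps_cmh(ds, strata="race", p_threshold=1.1)
        cand = list(table["SNP"].head(15))
        t1, _, s1 = build_final_network(ds, table, cand, seed=3)
        t2, _, s2 = build_final_network(ds, table, cand, seed=3)
        assert s1 == s2
        assert t1.parent == t2.parent
        for n in t1.nodes:
            np.testing.assert_array_equal(t1.cpts[n], t2.cpts[n])
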