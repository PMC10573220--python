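import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import perionet as pn
from perionet.master_regulators import _condition_samples, ppi_score_lookup


def k5():
    g = nx.DiGraph()
    g.add_edges_from((u, v) for u, v in
                     itertools.permutations(range(1, 6), 2))
    return g


def random_digraph(rng, n_max=40, p=0.15):
    n = int(rng.integers(5, n_max + 1))
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    for u, v in itertools.permutations(range(n), 2):
        if rng.random() < p:
            g.add_edge(u, v)
    return g


class TestMannWhitneyU:
    def test_complete_separation_reaches_bound(self):
        assert pn.mann_whitney_u([5, 6, 7, 8], [10, 11, 12, 13]) == 16.0

    def test_complete_reversal_is_zero(self):
        assert pn.mann_whitney_u([10, 11, 12, 13], [5, 6, 7, 8]) == 0.0

    def test_interleaved_case(self):
        assert pn.mann_whitney_u([1, 3, 5, 7], [2, 4, 6, 8]) == 10.0

    def test_tie_convention(self):
        assert pn.mann_whitney_u([1.0], [1.0]) == 0.5
        assert pn.mann_whitney_u([2, 2], [2, 2]) == 2.0  # n1*n2/2

    def test_complement_identity_and_scipy_crosscheck(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            n1, n2 = rng.integers(2, 8, size=2)
            h = rng.integers(0, 6, size=n1).astype(float)
            d = rng.integers(0, 6, size=n2).astype(float)
            u_d = pn.mann_whitney_u(h, d)
            u_h = pn.mann_whitney_u(d, h)
            assert u_d + u_h == pytest.approx(n1 * n2)
            ref = stats.mannwhitneyu(d, h, alternative="two-sided",
                                     method="asymptotic").statistic
            assert u_d == pytest.approx(ref)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            pn.mann_whitney_u([], [1.0])


class TestAssignCondition:
    @pytest.mark.parametrize("u,expected", [
        (16, "disease_higher"), (10, "disease_higher"),
        (0, "healthy_higher"), (5, "healthy_higher"),
        (8, "inconsistent"), (6, "inconsistent"), (9, "inconsistent"),
    ])
    def test_u_ranges(self, u, expected):
        assert pn.assign_condition(u, 4, 4) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pn.assign_condition(17, 4, 4)


class TestPruneByDegree:
    def test_complete_digraph_is_fixed_point(self):
        pruned = pn.prune_by_degree(k5(), 4, 4)
        assert set(pruned.nodes()) == set(range(1, 6))
        assert pruned.number_of_edges() == 20

    def test_pendant_removed_core_survives(self):
        g = k5()
        g.add_edge(6, 1)  # pendant TF: out=1, in=0
        pruned = pn.prune_by_degree(g, 4, 4)
        assert set(pruned.nodes()) == set(range(1, 6))

    def test_directed_chain_cascades_to_empty(self):
        g = nx.DiGraph([(i, i + 1) for i in range(6)])
        assert pn.prune_by_degree(g, 4, 4).number_of_nodes() == 0

    def test_initial_both_le_pass_deletes_k5(self):
        # documents why the one-pass "both <= 4" rule conflicts with the
        # iterative ">= 4" retention criterion: K5 has in = out = 4
        pruned = pn.prune_by_degree(k5(), 4, 4, initial_both_le=4)
        assert pruned.number_of_nodes() == 0

    def test_self_loops_do_not_count(self):
        g = k5()
        g.add_edge(7, 7)
        pruned = pn.prune_by_degree(g, 1, 1)
        assert 7 not in pruned

    def test_fixed_point_and_idempotence_on_random_digraphs(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            g = random_digraph(rng)
            pruned = pn.prune_by_degree(g, 4, 4)
            for n in pruned:
                assert pruned.in_degree(n) >= 4
                assert pruned.out_degree(n) >= 4
            again = pn.prune_by_degree(pruned, 4, 4)
            assert set(again.nodes()) == set(pruned.nodes())
            assert set(again.edges()) == set(pruned.edges())


class TestPpiEdgeFilter:
    def test_empty_ppi_removes_all_edges(self):
        g = k5()
        ppi = pd.DataFrame(columns=["protein1", "protein2",
                                    "combined_score"])
        filtered = pn.filter_edges_by_ppi(g, ppi)
        assert filtered.number_of_edges() == 0
        assert set(filtered.nodes()) == set(g.nodes())

    def test_score_exactly_point7_retained(self):
        g = nx.DiGraph([("A", "B"), ("C", "D")])
        ppi = pd.DataFrame({"protein1": ["A", "C"], "protein2": ["B", "D"],
                            "combined_score": [0.7, 0.699]})
        filtered = pn.filter_edges_by_ppi(g, ppi)
        assert set(filtered.edges()) == {("A", "B")}

    def test_lookup_is_order_insensitive(self):
        g = nx.DiGraph([("A", "B")])
        ppi = pd.DataFrame({"protein1": ["B"], "protein2": ["A"],
                            "combined_score": [0.9]})
        assert set(pn.filter_edges_by_ppi(g, ppi).edges()) == {("A", "B")}


class TestSeedsAndSubnetwork:
    def test_seed_group_bookkeeping(self):
        modules = pd.Series({"a": "M1", "b": "M1", "c": "M3", "d": "M8"})
        cfg = pn.MRConfig(seed_modules=["M1", "M3", "M8"],
                          extra_seed_genes=["Tnfsf11", "Tnfrsf11b"])
        groups = pn.select_seeds(modules, cfg)
        assert len(groups) == 4
        assert sum(len(g) for g in groups.values()) == 6

    def test_duplicate_gene_may_appear_in_multiple_groups(self):
        modules = pd.Series({"a": "M1"})
        cfg = pn.MRConfig(seed_modules=["M1"], extra_seed_genes=["a"])
        groups = pn.select_seeds(modules, cfg)
        assert groups["M1"] == groups["extra"] == {"A"}

    def test_unknown_module_label_is_skipped(self):
        modules = pd.Series({"a": "M1"})
        cfg = pn.MRConfig(seed_modules=["M1", "M99"], extra_seed_genes=[])
        groups = pn.select_seeds(modules, cfg)
        assert set(groups) == {"M1"}

    def test_all_empty_groups_rejected(self):
        modules = pd.Series({"a": "M1"})
        cfg = pn.MRConfig(seed_modules=["M99"], extra_seed_genes=[])
        with pytest.raises(ValueError):
            pn.select_seeds(modules, cfg)

    def test_non_tf_seed_dropped_and_isolates_removed(self):
        # tf1 -> g -> tf2 with seed {g}, order 1: after removing the
        # non-TF g, both TFs are isolated and dropped
        g = nx.DiGraph([("TF1", "G"), ("G", "TF2")])
        cfg = pn.MRConfig(neighbor_order=1)
        sub = pn.build_seed_subnetwork(g, {"G"}, tfs={"TF1", "TF2"},
                                       config=cfg)
        assert sub.number_of_nodes() == 0

    def test_pooled_seed_pool_is_superset_of_each_group(self):
        rng = np.random.default_rng(10)
        g = random_digraph(rng, n_max=30)
        tfs = set(range(0, 30, 2))
        seeds_a, seeds_b = {1, 3}, {5, 7}
        cfg = pn.MRConfig()
        pooled = pn.neighbor_expansion(g, seeds_a | seeds_b, 2)
        for seeds in (seeds_a, seeds_b):
            assert pn.neighbor_expansion(g, seeds, 2) <= pooled


class TestTargetReports:
    def test_count_de_targets(self):
        g = nx.DiGraph([("MR", "A"), ("MR", "B"), ("MR", "C"),
                        ("MR", "MR")])
        de = pd.DataFrame(
            {"padj": [0.01] * 4, "log2fc": [2.0] * 4,
             "status": ["up", "up", "ns", "up"]},
            index=pd.Index(["B", "C", "A", "D"], name="gene"))
        assert pn.count_de_targets("MR", g, de) == 2

    def test_unknown_mr_rejected(self):
        g = nx.DiGraph([("MR", "A")])
        de = pd.DataFrame({"padj": [], "log2fc": [], "status": []})
        with pytest.raises(KeyError):
            pn.count_de_targets("ZZ", g, de)

    def test_rank_targets_order_and_truncation(self):
        g = nx.DiGraph([("MR", t) for t in ["T1", "T2", "T3", "T4"]])
        de = pd.DataFrame(
            {"padj": [0.01, 0.01, 0.5, 0.9],
             "log2fc": [1.5, 3.0, 0.2, 2.5],
             "status": ["up", "up", "ns", "ns"]},
            index=pd.Index(["T1", "T2", "T3", "T4"], name="gene"))
        # DE targets first: equal padj -> larger |lfc| first; then
        # non-DE by |lfc| descending
        assert pn.rank_targets("MR", g, de, top_n=50) == \
            ["T2", "T1", "T4", "T3"]
        assert pn.rank_targets("MR", g, de, top_n=2) == ["T2", "T1"]

    def test_rank_is_deterministic(self):
        g = nx.DiGraph([("MR", t) for t in ["A", "B", "C"]])
        de = pd.DataFrame(
            {"padj": [0.01, 0.01, 0.01], "log2fc": [2.0, 2.0, 2.0],
             "status": ["up", "up", "up"]},
            index=pd.Index(["A", "B", "C"], name="gene"))
        r1 = pn.rank_targets("MR", g, de)
        assert r1 == pn.rank_targets("MR", g, de) == ["A", "B", "C"]


class TestIdentifyMasterRegulators:
    def test_no_ppi_support_empties_mr_set(self, synthetic_dataset):
        truth = synthetic_dataset["truth"]
        reg = synthetic_dataset["regulon"]
        norm = synthetic_dataset["norm"]
        edges = pd.DataFrame(list(reg.graph.edges()),
                             columns=["regulator", "target"])
        ref = pn.merge_reference_networks([edges], ["syn"])
        counts = synthetic_dataset["counts"]
        ga = pn.build_context_grn(ref, norm, counts.samples_of("healthy"),
                                  context="healthy")
        gb = pn.build_context_grn(ref, norm,
                                  counts.samples_of("periodontitis"),
                                  context="periodontitis")
        comb = pn.compare_grns(ga, gb, tfs=ref.tfs)
        modules = pd.Series({g.upper(): b.replace("B", "M")
                             for g, b in truth.module_labels.items()})
        de = pn.differential_expression(norm)
        empty_ppi = pd.DataFrame(
            {"protein1": ["X"], "protein2": ["Y"], "combined_score": [0.1]})
        rep = pn.identify_master_regulators(
            comb, modules, norm, empty_ppi, de,
            pn.MRConfig(seed_modules=["M1"]), tfs=ref.tfs)
        assert rep.mr_set == set()
        assert rep.table.empty

    def test_report_invariants_on_synthetic_data(self, synthetic_dataset):
        truth = synthetic_dataset["truth"]
        reg = synthetic_dataset["regulon"]
        norm = synthetic_dataset["norm"]
        counts = synthetic_dataset["counts"]
        ppi = synthetic_dataset["ppi"]
        edges = pd.DataFrame(list(reg.graph.edges()),
                             columns=["regulator", "target"])
        ref = pn.merge_reference_networks([edges], ["syn"])
        ga = pn.build_context_grn(ref, norm, counts.samples_of("healthy"),
                                  context="healthy")
        gb = pn.build_context_grn(ref, norm,
                                  counts.samples_of("periodontitis"),
                                  context="periodontitis")
        comb = pn.compare_grns(ga, gb, tfs=ref.tfs)
        modules = pd.Series({g.upper(): b.replace("B", "M")
                             for g, b in truth.module_labels.items()})
        de = pn.differential_expression(norm)
        cfg = pn.MRConfig(seed_modules=["M1"])
        rep = pn.identify_master_regulators(comb, modules, norm, ppi, de,
                                            cfg, tfs=ref.tfs)
        assert rep.mr_set <= ref.tfs
        lookup = ppi_score_lookup(ppi)
        for u, v in rep.mr_subnetwork.edges():
            assert u in rep.mr_set and v in rep.mr_set
            assert lookup[frozenset((u, v))] >= cfg.ppi_min_score
        for n in rep.mr_subnetwork:
            assert rep.mr_subnetwork.in_degree(n) >= cfg.min_indegree
            assert rep.mr_subnetwork.out_degree(n) >= cfg.min_outdegree
        n1 = len(counts.samples_of("healthy"))
        n2 = len(counts.samples_of("periodontitis"))
        assert rep.table["u"].between(0, n1 * n2).all()

    def test_two_conditions_required(self, synthetic_dataset):
        norm = synthetic_dataset["norm"]
        h, d = _condition_samples(norm)
        assert len(h) == len(d) == 4
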