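import itertools
from math import comb

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from csfmet.datatypes import ValidationError
from csfmet.network import (
    annotate_nodes,
    betweenness,
    build_network,
    enrich_pathways,
    export_sif,
    hypergeom_enrich,
    pathway_graph,
    pathway_impact,
    read_sif,
    tanimoto,
)
from csfmet.univariate import ContrastResult


def fp(bits, length=16):
    v = np.zeros(length, dtype=np.uint8)
    v[list(bits)] = 1
    return v


def met_table(fps):
    return pd.DataFrame(
        {"name": list(fps), "chem_class": ["misc"] * len(fps),
         "fingerprint": list(fps.values())},
        index=pd.Index(list(fps), name="metabolite_id"),
    )


class TestTanimoto:
    def test_identical_nonempty_is_one(self):
        assert tanimoto(fp({1, 2, 3}), fp({1, 2, 3})) == 1.0

    def test_disjoint_is_zero(self):
        assert tanimoto(fp({0, 1}), fp({2, 3})) == 0.0

    def test_formula_case(self):
        assert tanimoto(fp({0, 1, 2}), fp({1, 2, 5})) == 0.5

    def test_symmetric_and_identity_property(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a = (rng.random(12) < 0.4).astype(np.uint8)
            b = (rng.random(12) < 0.4).astype(np.uint8)
            if not (a.any() or b.any()):
                continue
            assert tanimoto(a, b) == tanimoto(b, a)
            if a.any():
                assert tanimoto(a, a) == 1.0
            if tanimoto(a, b) == 1.0:
                np.testing.assert_array_equal(a, b)

    def test_both_empty_undefined(self):
        with pytest.raises(ValidationError):
            tanimoto(fp(set()), fp(set()))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            tanimoto(fp({1}, 8), fp({1}, 9))


class TestBuildNetwork:
    def test_edgeless_at_cutoff_one_with_distinct_fps(self):
        mets = met_table({"a": fp({0, 1}), "b": fp({1, 2}), "c": fp({4})})
        net = build_network(mets, cutoff=1.0)
        assert net.graph.number_of_edges() == 0
        assert set(net.graph.nodes) == {"a", "b", "c"}

    def test_matches_brute_force_all_pairs(self):
        rng = np.random.default_rng(1)
        fps = {f"m{i:02d}": (rng.random(24) < 0.5).astype(np.uint8)
               for i in range(30)}
        net = build_network(met_table(fps), cutoff=0.7)
        expected = set()
        ids = sorted(fps)
        for a, b in itertools.combinations(ids, 2):
            union = np.logical_or(fps[a], fps[b]).sum()
            if union and np.logical_and(fps[a], fps[b]).sum() / union >= 0.7:
                expected.add((a, b))
        got = {(min(u, v), max(u, v)) for u, v in net.graph.edges}
        assert got == expected

    def test_monotone_decreasing_in_cutoff(self):
        rng = np.random.default_rng(2)
        fps = {f"m{i}": (rng.random(20) < 0.5).astype(np.uint8) for i in range(15)}
        mets = met_table(fps)
        prev = None
        for cutoff in (0.3, 0.5, 0.7, 0.9):
            edges = {frozenset(e) for e in build_network(mets, cutoff).graph.edges}
            if prev is not None:
                assert edges <= prev
            prev = edges

    def test_rpair_overlay_and_both_type(self):
        mets = met_table({"a": fp({0, 1, 2}), "b": fp({0, 1, 2}), "c": fp({9})})
        net = build_network(mets, cutoff=0.7, rpairs=[("a", "b"), ("a", "c")])
        assert net.graph.edges["a", "b"]["type"] == "both"
        assert net.graph.edges["a", "c"]["type"] == "rpair"

    def test_unknown_rpair_member_skipped_with_warning(self, caplog):
        mets = met_table({"a": fp({0}), "b": fp({1})})
        with caplog.at_level("WARNING"):
            net = build_network(mets, cutoff=0.7, rpairs=[("a", "ghost")])
        assert net.graph.number_of_edges() == 0
        assert "ghost" in caplog.text

    def test_class_structured_fps_give_modular_network(self, cohort):
        from csfmet.datatypes import rpair_table

        net = build_network(cohort.metabolites, cutoff=0.7,
                            rpairs=rpair_table(cohort.metabolites))
        cls = cohort.metabolites["chem_class"]
        within = between = 0
        for u, v, d in net.graph.edges(data=True):
            if d["type"] == "rpair":
                continue
            if cls[u] == cls[v]:
                within += 1
            else:
                between += 1
        assert within > 0 and between == 0


def contrast_fixture():
    table = pd.DataFrame(
        {
            "p_value": [1e-4, 0.5, 1e-3],
            "fold_change": [1.72, 2.0, 0.5],
            "direction": ["up", "up", "down"],
            "testable": [True, True, True],
            "p_adjusted": [np.nan] * 3,
            "significant": [True, False, True],
        },
        index=["a", "b", "c"],
    )
    return ContrastResult(contrast="CTRL_vs_MS", table=table, alpha=0.05,
                          adjusted=False)


class TestAnnotateExport:
    def test_significant_up_node_annotated(self):
        mets = met_table({"a": fp({0}), "b": fp({1}), "c": fp({2})})
        net = annotate_nodes(build_network(mets), contrast_fixture())
        assert net.graph.nodes["a"]["direction"] == "up"
        assert net.graph.nodes["a"]["size"] == pytest.approx(np.log2(1.72))
        assert net.graph.nodes["c"]["direction"] == "down"
        assert net.graph.nodes["b"]["direction"] == "ns"
        assert not net.graph.nodes["b"]["significant"]

    def test_sif_round_trip(self, tmp_path):
        mets = met_table({"a": fp({0, 1}), "b": fp({0, 1}), "c": fp({0, 1})})
        net = build_network(mets, cutoff=0.7, rpairs=[("a", "c")])
        sif, attrs = export_sif(net, tmp_path / "net.sif")
        back = read_sif(sif)
        assert {frozenset(e) for e in back.edges} == \
            {frozenset(e) for e in net.graph.edges}
        at = pd.read_csv(attrs, sep="\t")
        assert list(at.columns) == ["node", "fold_change", "direction",
                                    "significant"]

    def test_two_node_network_single_line(self, tmp_path):
        mets = met_table({"a": fp({0}), "b": fp({0})})
        net = build_network(mets, cutoff=0.7)
        sif, _ = export_sif(net, tmp_path / "two.sif")
        lines = sif.read_text().strip().splitlines()
        assert lines == ["a\ttanimoto\tb"]

    def test_empty_network_empty_sif(self, tmp_path):
        mets = met_table({"a": fp({0}), "b": fp({1})})
        net = build_network(mets, cutoff=0.9)
        sif, attrs = export_sif(net, tmp_path / "empty.sif")
        assert sif.read_text() == ""
        assert pd.read_csv(attrs, sep="\t").shape[0] == 2


def hypergeom_oracle(N, K, n, k):
    """P(X >= k) by summing the exact hypergeometric pmf."""
    total = comb(N, n)
    return sum(comb(K, j) * comb(N - K, n - j)
               for j in range(k, min(K, n) + 1)) / total


class TestHypergeom:
    def test_zero_hits_p_one(self):
        u = set(range(10))
        assert hypergeom_enrich(set(), set(range(4)), u) == 1.0

    def test_pathway_equals_universe_p_one(self):
        u = set(range(6))
        assert hypergeom_enrich({1, 2}, u, u) == pytest.approx(1.0)

    def test_textbook_case(self):
        # N=10, K=4, n=3, k=2: p = (C(4,2)C(6,1)+C(4,3))/C(10,3) = 40/120
        u = set(range(10))
        pw = set(range(4))
        hits = {0, 1, 9}
        assert hypergeom_enrich(hits, pw, u) == pytest.approx(1 / 3)

    def test_matches_enumeration_for_all_small_cases(self):
        for N in range(1, 13):
            u = set(range(N))
            for K in range(N + 1):
                pw = set(range(K))
                for n in range(N + 1):
                    hits = set(range(N - n, N))  # arbitrary n-subset
                    k = len(hits & pw)
                    got = hypergeom_enrich(hits, pw, u)
                    assert got == pytest.approx(hypergeom_oracle(N, K, n, k),
                                                abs=1e-12)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValidationError):
            hypergeom_enrich(set(), set(), set())


def betweenness_oracle(g):
    """Exhaustive shortest-path enumeration for tiny graphs."""
    nodes = list(g.nodes)
    n = len(nodes)
    out = {v: 0.0 for v in nodes}
    if n < 3:
        return out
    for s, t in itertools.combinations(nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(g, s, t))
        except nx.NetworkXNoPath:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(v in p for p in paths)
            out[v] += through / len(paths)
    norm = (n - 1) * (n - 2) / 2
    return {v: c / norm for v, c in out.items()}


class TestBetweennessImpact:
    def test_path_graph_center(self):
        g = nx.path_graph(["A", "B", "C"])
        c = betweenness(g)
        assert c == {"A": 0.0, "B": 1.0, "C": 0.0}

    def test_star_center_is_one(self):
        g = nx.star_graph(5)
        assert betweenness(g)[0] == pytest.approx(1.0)

    def test_matches_enumeration_on_random_graphs(self):
        rng = np.random.default_rng(3)
        for trial in range(50):
            n = int(rng.integers(3, 9))
            g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(1e6)))
            got = betweenness(g)
            expected = betweenness_oracle(g)
            for v in g.nodes:
                assert got[v] == pytest.approx(expected[v], abs=1e-10)

    def test_tiny_graph_all_zero(self):
        g = nx.path_graph(2)
        assert set(betweenness(g).values()) == {0.0}

    def test_impact_boundaries(self):
        g = nx.path_graph(["A", "B", "C"])
        assert pathway_impact(set(), g) == 0.0
        assert pathway_impact({"A", "B", "C"}, g) == 1.0
        assert pathway_impact({"B"}, g) == 1.0  # B carries all centrality

    def test_impact_monotone_in_hits(self):
        g = nx.gnp_random_graph(7, 0.5, seed=11)
        nodes = list(g.nodes)
        prev = 0.0
        for i in range(len(nodes) + 1):
            cur = pathway_impact(set(nodes[:i]), g)
            assert cur >= prev - 1e-12
            prev = cur

    def test_non_member_hit_rejected(self):
        g = nx.path_graph(["A", "B"])
        with pytest.raises(ValidationError):
            pathway_impact({"Z"}, g)


class TestEnrichment:
    def test_pathway_table_on_cohort(self, cohort):
        from csfmet.datatypes import rpair_table

        hits = {"capric acid", "lauric acid", "myristic acid", "stearic acid"}
        enr = enrich_pathways(hits, cohort.metabolites,
                              rpair_table(cohort.metabolites))
        fa = enr.loc["Fatty acid biosynthesis"]
        assert fa["n_hits_pathway"] == 4
        assert fa["p_hyper"] < 0.01
        assert 0 <= fa["impact"] <= 1
        other = enr.drop(index="Fatty acid biosynthesis")["p_hyper"]
        assert fa["p_hyper"] <= other.min()

    def test_pathway_graph_restricted_to_members(self):
        g = pathway_graph({"a", "b"}, [("a", "b"), ("a", "z")])
        assert set(g.nodes) == {"a", "b"}
        assert g.number_of_edges() == 1
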