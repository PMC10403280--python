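import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from coevoscreen.coevolution_networks import (
    build_spsn,
    build_ssn,
    chord_table,
    cluster_graph,
    cross_reactivity_profile,
    hamming,
    trace_pathway,
    write_edge_list,
    write_graphml,
)
from coevoscreen.pair_enrichment import EnrichedPairSet
from coevoscreen.screen_simulator import PairCountTable

# The published single-mutation evolutionary pathway from the founder
# Z-A sequence to the prominent late mutants of the expanded library.
PATHWAY = ["QFLI", "VFLI", "VFLV", "VFLF", "VVLF", "LVLF", "LVFF", "IVFF"]


def pairs_table(rows, label="r1"):
    return PairCountTable(
        label, pd.DataFrame(rows, columns=["seq_a", "seq_b", "count"])
    )


def enriched_from(rows):
    df = pd.DataFrame(rows, columns=["seq_a", "seq_b", "k"])
    df["c_a"] = df["c_b"] = df["n"] = 1
    df["p_value"] = 0.01
    return EnrichedPairSet(["r1"], 0.05, df)


class TestHamming:
    def test_identical(self):
        assert hamming("QFLI", "QFLI") == 0

    def test_published_pathway_steps_are_single_mutations(self):
        assert hamming("QFLI", "VFLI") == 1
        assert hamming("LVLF", "LVFF") == 1

    def test_unequal_length_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            hamming("QFLI", "QFL")


class TestSSN:
    def test_threshold_zero_unique_keys_edgeless(self):
        t = pairs_table([("FFFF", "LLLL", 1), ("FFFL", "LLLF", 1)])
        g = build_ssn([t], threshold=0)
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() == 2

    def test_edges_monotone_in_threshold(self):
        rows = [("FFFF", "LLLL", 1), ("FFFL", "LLLL", 2), ("FLLL", "LFLL", 1),
                ("LLLL", "FFFF", 1), ("FFLL", "LLFF", 3)]
        t = pairs_table(rows)
        for thr in range(4):
            e1 = set(build_ssn([t], threshold=thr).edges())
            e2 = set(build_ssn([t], threshold=thr + 1).edges())
            assert e1 <= e2

    def test_edges_match_bruteforce_all_pairs(self):
        rows = [("FFFF", "LLLL", 1), ("FFFL", "LLLL", 2), ("FLLL", "LFLL", 1),
                ("LLLF", "FFFL", 1), ("FFLL", "LLFF", 3)]
        t = pairs_table(rows)
        g = build_ssn([t], threshold=2)
        keys = [a + b for a, b, _ in rows]
        expected = {
            tuple(sorted((k1, k2)))
            for k1, k2 in itertools.combinations(keys, 2)
            if hamming(k1, k2) <= 2
        }
        assert {tuple(sorted(e)) for e in g.edges()} == expected
        for u, v, d in g.edges(data=True):
            assert d["distance"] == hamming(u, v)

    def test_invariant_to_input_row_order(self):
        rows = [("FFFF", "LLLL", 1), ("FFFL", "LLLL", 2), ("FLLL", "LFLL", 1)]
        g1 = build_ssn([pairs_table(rows)], threshold=2)
        g2 = build_ssn([pairs_table(rows[::-1])], threshold=2)
        assert list(g1.nodes) == list(g2.nodes)
        assert list(g1.edges) == list(g2.edges)

    def test_node_attributes_first_round_and_count(self):
        t1 = pairs_table([("FFFF", "LLLL", 2)], "naive")
        t2 = pairs_table([("FFFF", "LLLL", 5), ("FFFL", "LLLL", 1)], "r1")
        g = build_ssn([t1, t2], threshold=1)
        assert g.nodes["FFFFLLLL"]["first_round"] == "naive"
        assert g.nodes["FFFFLLLL"]["count"] == 7
        assert g.nodes["FFFLLLLL"]["first_round"] == "r1"


class TestClusterGraph:
    def test_edgeless_network_gives_singletons(self):
        t = pairs_table([("FFFF", "LLLL", 1), ("LLFF", "FFLL", 1)])
        g = build_ssn([t], threshold=0)
        cg = cluster_graph(g)
        assert cg.number_of_nodes() == 2
        assert all(d["size"] == 1 for _, d in cg.nodes(data=True))

    def test_cluster_sizes_sum_to_node_count(self):
        rows = [(a, b, 1) for a, b in
                [("FFFF", "LLLL"), ("FFFL", "LLLL"), ("FLLL", "LFLL"),
                 ("LLLL", "FFFF"), ("FFLL", "LLFF"), ("LFFF", "FLLL"),
                 ("LLLF", "FFFL")]]
        g = build_ssn([pairs_table(rows)], threshold=1)
        cg = cluster_graph(g)
        assert sum(d["size"] for _, d in cg.nodes(data=True)) == g.number_of_nodes()

    def test_components_match_unionfind_oracle(self):
        rows = [(a, b, 1) for a, b in
                [("FFFF", "LLLL"), ("FFFL", "LLLL"), ("FLLL", "LFLL"),
                 ("LLLL", "FFFF"), ("FFLL", "LLFF"), ("LFFF", "FLLL"),
                 ("LLLF", "FFFL")]]
        g = build_ssn([pairs_table(rows)], threshold=1)

        parent = {n: n for n in g.nodes}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for u, v in g.edges:
            parent[find(u)] = find(v)
        oracle = {}
        for n in g.nodes:
            oracle.setdefault(find(n), set()).add(n)
        got = {frozenset(c) for c in nx.connected_components(g)}
        assert {frozenset(c) for c in oracle.values()} == got
        cg = cluster_graph(g)
        assert cg.number_of_nodes() == len(oracle)


class TestSpSN:
    def test_disjoint_partner_sets_edgeless(self):
        e = enriched_from([("A1", "B1", 1), ("A2", "B2", 1)])
        assert build_spsn(e).number_of_edges() == 0

    def test_toy_shared_partner(self):
        e = enriched_from([("A1", "B1", 1), ("A1", "B2", 1),
                           ("A2", "B2", 1), ("A2", "B3", 1),
                           ("A3", "B4", 1)])
        g = build_spsn(e, min_shared=1)
        assert set(g.edges()) == {("A1", "A2")}
        assert g.edges["A1", "A2"]["shared"] == 1

    def test_edges_nonincreasing_in_min_shared(self):
        e = enriched_from([("A1", f"B{i}", 1) for i in range(4)]
                          + [("A2", f"B{i}", 1) for i in range(3)])
        counts = [build_spsn(e, min_shared=m).number_of_edges() for m in (1, 2, 3, 4)]
        assert counts == sorted(counts, reverse=True)


class TestCrossReactivity:
    def test_single_za_scores_one(self):
        e = enriched_from([("A1", "B1", 1), ("A1", "B2", 1)])
        profile, _ = cross_reactivity_profile(e, sample_n=1, seed=0)
        assert profile.df["score"].tolist() == [1.0]

    def test_score_arithmetic(self):
        e = enriched_from([("A1", f"B{i}", 1) for i in range(3)]
                          + [("A2", "B9", 1)])
        profile, _ = cross_reactivity_profile(e, sample_n=2, seed=0)
        s = profile.df.set_index("seq_a")["score"]
        assert s["A1"] == pytest.approx(0.75)
        assert s["A2"] == pytest.approx(0.25)

    def test_scores_sum_to_one(self):
        rng = np.random.default_rng(0)
        rows = [(f"A{rng.integers(8)}", f"B{i}", 1) for i in range(60)]
        e = enriched_from(list(dict.fromkeys(rows)))
        profile, _ = cross_reactivity_profile(e, sample_n=10, seed=1)
        assert profile.df["score"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_stratified_sample_proportional_within_one(self):
        rng = np.random.default_rng(3)
        rows = []
        for a in range(10):
            for b in range(rng.integers(50, 150)):
                rows.append((f"A{a}", f"B{a}_{b}", 1))
        e = enriched_from(rows)
        _, sample = cross_reactivity_profile(e, sample_n=100, seed=2)
        assert len(sample) == 100
        sizes = e.df.groupby("seq_a").size()
        got = sample.groupby("seq_a").size().reindex(sizes.index).fillna(0)
        exact = sizes / sizes.sum() * 100
        assert (np.abs(got - exact) <= 1.0 + 1e-9).all()

    def test_sample_larger_than_pairs_rejected(self):
        e = enriched_from([("A1", "B1", 1)])
        with pytest.raises(ValueError, match="exceeds"):
            cross_reactivity_profile(e, sample_n=5, seed=0)

    def test_chord_table_equal_arcs(self):
        e = enriched_from([("A1", "B1", 1), ("A1", "B2", 1), ("A2", "B1", 1)])
        _, sample = cross_reactivity_profile(e, sample_n=2, seed=0)
        chord = chord_table(sample)
        assert chord["arc_weight"].sum() == pytest.approx(1.0)
        assert chord["arc_weight"].nunique() == 1


class TestTracePathway:
    def test_published_chain_is_a_hamming1_walk(self):
        for s1, s2 in zip(PATHWAY, PATHWAY[1:]):
            assert hamming(s1, s2) == 1

    def test_bfs_shortest_path_has_six_steps(self):
        result = trace_pathway(PATHWAY, "QFLI", "IVFF")
        assert result.connected
        assert result.n_steps == 6
        assert result.path[0] == "QFLI" and result.path[-1] == "IVFF"
        for s1, s2 in zip(result.path, result.path[1:]):
            assert hamming(s1, s2) == 1

    def test_start_equals_end(self):
        result = trace_pathway(PATHWAY, "QFLI", "QFLI")
        assert result.connected and result.path == ["QFLI"] and result.n_steps == 0

    def test_disconnected_reported_not_raised(self):
        result = trace_pathway(["QFLI", "IVFF"], "QFLI", "IVFF")
        assert not result.connected
        assert result.path == []

    def test_round_monotone_respects_chronology(self):
        rounds = {"QFLI": 0, "VFLI": 1, "VFLF": 2, "VVLF": 2, "LVLF": 3}
        res = trace_pathway(rounds, "QFLI", "LVLF", round_monotone=True)
        assert res.connected
        appearance = [rounds[s] for s in res.path]
        assert appearance == sorted(appearance)

    def test_deterministic_tiebreak_prefers_lower_pvalue(self):
        nodes = ["FF", "FL", "LF", "LL"]
        pvals = {"FL": 0.5, "LF": 0.001}
        res = trace_pathway(nodes, "FF", "LL", pvalues=pvals)
        assert res.path == ["FF", "LF", "LL"]
        res2 = trace_pathway(nodes, "FF", "LL")  # lexicographic fallback
        assert res2.path == ["FF", "FL", "LL"]

    def test_missing_endpoint_rejected(self):
        with pytest.raises(KeyError):
            trace_pathway(["FF"], "FF", "LL")


class TestExport:
    def test_graphml_and_edgelist(self, tmp_path):
        t = pairs_table([("FFFF", "LLLL", 1), ("FFFL", "LLLL", 2)])
        g = build_ssn([t], threshold=1)
        write_graphml(g, tmp_path / "g.graphml")
        loaded = nx.read_graphml(tmp_path / "g.graphml")
        assert loaded.number_of_nodes() == 2
        write_edge_list(g, tmp_path / "g.tsv")
        edges = pd.read_csv(tmp_path / "g.tsv", sep="\t")
        assert len(edges) == g.number_of_edges()


class TestSpecificityGroupSeparation:
    def test_matched_families_form_separate_components(self, ):
        """A landscape whose only signal is a strong matched-pair coupling
        creates distinct specificity families; after selection the final
        round's SSN at threshold 1 splits into >= 2 components in >= 16/20
        seeds."""
        import networkx as nx

        from conftest import make_design
        from coevoscreen.screen_simulator import (
            GroundTruthLandscape,
            SelectionConfig,
            simulate_screen,
        )

        design = make_design("fam", ["NTT", "NTT"], ["DTK"])
        qa = [len(a) for a in design.alphabets_A]
        qb = [len(b) for b in design.alphabets_B]
        n_ok = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            eps = np.zeros((qa[0], qb[0]))
            partners = rng.permutation(qb[0])[: qa[0]]
            eps[np.arange(qa[0]), partners] = 4.0
            land = GroundTruthLandscape(
                alphabets_A=list(design.alphabets_A),
                alphabets_B=list(design.alphabets_B),
                h_A=[np.zeros(q) for q in qa],
                h_B=[np.zeros(q) for q in qb],
                eps={(1, 1): eps},
                pkd0=7.0,
            )
            cfg = SelectionConfig(n_rounds=8, naive_diversity=80,
                                  cells_per_round=2000, sequencing_depth=5000,
                                  seed=seed)
            tables = simulate_screen(design, land, cfg)
            g = build_ssn([tables[-1]], threshold=1)
            n_ok += nx.number_connected_components(g) >= 2
        assert n_ok >= 16
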