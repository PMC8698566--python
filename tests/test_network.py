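"""PPI integration: restriction, hubs, ego nets, cluster-pair statistics,
the type interaction map, and cascade enumeration vs a brute-force scan."""

import itertools

import networkx as nx
import numpy as np
import pytest

import androdyn as ad
from androdyn.errors import AndrodynError, ParameterError
from androdyn.network import (CASCADE_COLUMNS, CASCADE_ROWS, cascade_counts,
                              cascade_layout)

from _oracles import brute_force_cascades, hypergeom_upper_tail
from test_enrichment import make_annotations, make_assignment


class TestRestrictNetwork:
    def test_hand_counted_induced_edges(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("c", "d"), ("d", "e"),
                      ("e", "a"), ("b", "d")])
        asn = make_assignment({"A": "X", "B": "X", "C": "Y", "D": "Y"})
        g = nx.relabel_nodes(g, str.upper)
        sub = ad.restrict_network(g, asn)
        # edges among {A,B,C,D}: A-B, B-C, C-D, B-D -> 4
        assert sub.number_of_edges() == 4
        assert sub.nodes["A"]["cluster"] == "X"

    def test_empty_intersection(self):
        g = nx.Graph([("Q1", "Q2")])
        sub = ad.restrict_network(g, make_assignment({"P1": "X", "P2": "Y"}))
        assert sub.number_of_nodes() == 0

    def test_idempotent(self):
        g = nx.Graph([("A", "B"), ("B", "C")])
        asn = make_assignment({"A": "X", "B": "Y", "C": "X"})
        once = ad.restrict_network(g, asn)
        twice = ad.restrict_network(once, asn)
        assert set(once.edges) == set(twice.edges)


class TestHubsAndEgo:
    def test_star_graph_hub(self):
        g = nx.star_graph(9)
        g = nx.relabel_nodes(g, lambda n: f"N{n}")
        hubs = ad.hub_degrees(g, top_n=1)
        assert hubs.iloc[0].protein == "N0" and hubs.iloc[0].degree == 9

    def test_tie_order_deterministic(self):
        g = nx.Graph([("B", "C"), ("A", "C"), ("A", "B")])  # all degree 2
        hubs = ad.hub_degrees(g, top_n=3)
        assert list(hubs.protein) == ["A", "B", "C"]

    def test_synthetic_hub_rank_one(self, scenario_ppi):
        hubs = ad.hub_degrees(scenario_ppi, top_n=2)
        assert hubs.iloc[0].protein == "EGFR"
        assert hubs.iloc[0].degree == 97
        assert hubs.iloc[1].protein == "TP53"
        assert hubs.iloc[1].degree == 87

    def test_ego_path_radius(self):
        g = nx.path_graph(["A", "B", "C", "D"])
        assert set(ad.ego_neighborhood(g, "A", radius=2)) == {"A", "B", "C"}
        assert set(ad.ego_neighborhood(g, "A", radius=0)) == {"A"}

    def test_ego_missing_focus_names_symbol(self):
        with pytest.raises(AndrodynError, match="XYZ9"):
            ad.ego_neighborhood(nx.Graph([("A", "B")]), "xyz9")

    def test_ar_first_shell_census(self, scenario):
        """AR wired to one protein per cluster: the first shell contains one
        member of each archetype by construction."""
        truth = scenario["truth"]
        picks = {letter: truth.members(letter)[0] for letter in "ABCDE"}
        g = nx.Graph([("AR", p) for p in picks.values()])
        ego = ad.ego_neighborhood(g, "AR", radius=1)
        shell = set(ego.nodes) - {"AR"}
        assert {truth.archetypes[p] for p in shell} == set("ABCDE")


class TestClusterPairStats:
    def test_small_fixture_exact(self):
        """2+2 nodes, 4 edges of which 3 span the clusters: 75% of counted
        edges; p by enumeration over the C(4,2)=6-pair universe is 9/15."""
        asn = make_assignment({"A1": "X", "A2": "X", "B1": "Y", "B2": "Y"})
        g = nx.Graph([("A1", "B1"), ("A1", "B2"), ("A2", "B1"),
                      ("A1", "A2")])
        stats = ad.cluster_pair_stats(g, asn)
        row = stats.table[(stats.table.cluster_1 == "X")
                          & (stats.table.cluster_2 == "Y")].iloc[0]
        assert row.edges == 3
        assert row.pct_all == pytest.approx(75.0)
        assert row.p == pytest.approx(hypergeom_upper_tail(3, 6, 4, 4))
        assert row.p == pytest.approx(9 / 15)

    def test_percentages_sum_to_100(self, scenario, scenario_ppi):
        restricted = ad.restrict_network(scenario_ppi,
                                         scenario["assignment"])
        stats = ad.cluster_pair_stats(restricted, scenario["assignment"])
        assert stats.table.pct_all.sum() == pytest.approx(100.0)
        inter = stats.table.pct_inter.dropna()
        assert inter.sum() == pytest.approx(100.0)

    def test_complete_bipartite_minimal_p(self):
        asn = make_assignment(
            {f"X{i}": "X" for i in range(4)} | {f"Y{i}": "Y" for i in range(4)}
            | {f"Z{i}": "Z" for i in range(4)})
        g = nx.Graph()
        g.add_nodes_from(asn.labels.index)
        for i, j in itertools.product(range(4), range(4)):
            g.add_edge(f"X{i}", f"Y{j}")
        g.add_edge("Z0", "Z1")
        stats = ad.cluster_pair_stats(g, asn)
        best = stats.table.iloc[0]
        assert {best.cluster_1, best.cluster_2} == {"X", "Y"}

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        labels = {f"P{i}": "XY"[rng.integers(0, 2)] for i in range(8)}
        g = nx.Graph()
        g.add_nodes_from(labels)
        for a, b in itertools.combinations(labels, 2):
            if rng.random() < 0.4:
                g.add_edge(a, b)
        stats = ad.cluster_pair_stats(g, make_assignment(labels))
        M = 8 * 7 // 2  # all unordered node pairs
        for row in stats.table.itertuples():
            expect = hypergeom_upper_tail(row.edges, M,
                                          g.number_of_edges(), row.n_pairs)
            assert row.p == pytest.approx(expect, rel=1e-10)

    def test_needs_two_clusters(self):
        asn = make_assignment({"A": "X", "B": "X"})
        with pytest.raises(ParameterError):
            ad.cluster_pair_stats(nx.Graph([("A", "B")]), asn)

    def test_rewiring_null_agrees_on_planted_pair(self):
        rng = np.random.default_rng(2)
        labels = {f"P{i}": "XYZ"[i % 3] for i in range(30)}
        g = nx.Graph()
        g.add_nodes_from(labels)
        for a, b in itertools.combinations(labels, 2):
            pair = tuple(sorted((labels[a], labels[b])))
            p = 0.5 if pair == ("X", "Y") else 0.05
            if rng.random() < p:
                g.add_edge(a, b)
        stats = ad.cluster_pair_stats(g, make_assignment(labels),
                                      permutations=99, seed=0)
        row = stats.table.iloc[0]
        assert {row.cluster_1, row.cluster_2} == {"X", "Y"}
        assert row.p_rewire <= 0.05


class TestTypeInteractionMap:
    def _setup(self, frac_edges):
        # two types, 3 proteins each, in clusters A (early) and E (late)
        labels = {f"T{i}": "A" for i in range(3)}
        labels |= {f"R{i}": "E" for i in range(3)}
        typ = {f"T{i}": "transporter" for i in range(3)}
        typ |= {f"R{i}": "transcription regulator" for i in range(3)}
        comp = {p: "cytoplasm" for p in labels}
        g = nx.Graph()
        g.add_nodes_from(labels)
        g.add_edges_from(frac_edges)
        return g, make_annotations(comp, typ), make_assignment(labels)

    def test_full_bipartite_fraction_one(self):
        edges = [(f"T{i}", f"R{j}") for i in range(3) for j in range(3)]
        g, ann, asn = self._setup(edges)
        table, graph = ad.type_interaction_map(g, ann, asn,
                                               fraction_threshold=0.01)
        row = table.iloc[0]
        assert row.fraction == pytest.approx(1.0)
        assert row.direction == "transporter->transcription regulator"
        assert graph.has_edge("transporter", "transcription regulator")

    def test_threshold_is_strict(self):
        edges = [("T0", "R0")]  # fraction exactly 1/9
        g, ann, asn = self._setup(edges)
        table, graph = ad.type_interaction_map(g, ann, asn,
                                               fraction_threshold=1 / 9)
        assert not table.iloc[0].kept
        assert graph.number_of_edges() == 0

    def test_direction_antisymmetry(self):
        """Reversing the cluster ranks reverses every directed edge."""
        edges = [(f"T{i}", f"R{j}") for i in range(3) for j in range(3)]
        g, ann, asn = self._setup(edges)
        fwd, _ = ad.type_interaction_map(g, ann, asn, 0.01)
        flipped = make_assignment(
            {p: ("E" if lab == "A" else "A")
             for p, lab in asn.labels.items()})
        rev, _ = ad.type_interaction_map(g, ann, flipped, 0.01)
        f = fwd[fwd.kept].iloc[0].direction
        r = rev[rev.kept].iloc[0].direction
        assert f.split("->") == r.split("->")[::-1]

    def test_three_type_hand_fixture(self):
        labels = {"K1": "B", "K2": "B", "E1": "C", "E2": "C",
                  "T1": "E", "T2": "E"}
        typ = {"K1": "kinase", "K2": "kinase", "E1": "enzyme",
               "E2": "enzyme", "T1": "transcription regulator",
               "T2": "transcription regulator"}
        comp = {p: "cytoplasm" for p in labels}
        g = nx.Graph([("K1", "E1"), ("K1", "E2"), ("E1", "T1")])
        g.add_nodes_from(labels)  # isolated members still count in sizes
        table, _ = ad.type_interaction_map(
            g, make_annotations(comp, typ), make_assignment(labels), 0.01)
        tbl = table.set_index(["type_1", "type_2"])
        assert tbl.loc[("enzyme", "kinase")].fraction == pytest.approx(2 / 4)
        assert tbl.loc[("enzyme", "transcription regulator")].fraction \
            == pytest.approx(1 / 4)
        assert tbl.loc[("kinase", "transcription regulator")].fraction == 0.0
        # kinases (cluster B, rank 2) precede enzymes (cluster C, rank 3)
        assert tbl.loc[("enzyme", "kinase")].direction == "kinase->enzyme"


class TestCascades:
    def _published_example(self):
        labels = {"AR": "C", "SP1": "D", "STAT3": "E"}
        typ = {"AR": "ligand-dependent nuclear receptor",
               "SP1": "transcription regulator",
               "STAT3": "transcription regulator"}
        comp = {"AR": "nucleus", "SP1": "nucleus", "STAT3": "nucleus"}
        g = nx.Graph([("AR", "SP1"), ("SP1", "STAT3")])
        return g, make_assignment(labels), make_annotations(comp, typ)

    def test_published_cascade_row(self):
        """The AR -> SP1 -> STAT3 cascade with types LD NR / Tc Reg / Tc Reg
        is returned verbatim."""
        g, asn, ann = self._published_example()
        out = ad.enumerate_cascades(g, asn, ann)
        assert len(out) == 1
        row = out.iloc[0]
        assert (row.Protein_C, row.Protein_D, row.Protein_E) == \
            ("AR", "SP1", "STAT3")
        assert row.Type_C == "ligand-dependent nuclear receptor"
        assert row.Type_D == "transcription regulator"
        assert row.Type_E == "transcription regulator"

    def test_hand_enumerated_fixture(self):
        # C={c1}, D={d1,d2}, E={e1}; edges (c1,d1),(d1,e1),(c1,d2)
        labels = {"C1": "C", "D1": "D", "D2": "D", "E1": "E"}
        g = nx.Graph([("C1", "D1"), ("D1", "E1"), ("C1", "D2")])
        out = ad.enumerate_cascades(g, make_assignment(labels),
                                    require_terminal_type=None)
        assert len(out) == 1
        assert tuple(out.iloc[0][["Protein_C", "Protein_D", "Protein_E"]]) \
            == ("C1", "D1", "E1")

    def test_terminal_type_filter(self):
        g, asn, ann = self._published_example()
        none = ad.enumerate_cascades(g, asn, ann,
                                     require_terminal_type="kinase")
        assert len(none) == 0

    def test_unknown_label_raises(self):
        g, asn, ann = self._published_example()
        with pytest.raises(AndrodynError):
            ad.enumerate_cascades(g, asn, ann, from_label="Q")

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 61))
        labels = {f"P{i}": "ABCDE"[rng.integers(0, 5)] for i in range(n)}
        g = nx.Graph()
        g.add_nodes_from(labels)
        for a, b in itertools.combinations(labels, 2):
            if rng.random() < 0.08:
                g.add_edge(a, b)
        out = ad.enumerate_cascades(g, make_assignment(labels),
                                    require_terminal_type=None)
        got = set(zip(out.Protein_C, out.Protein_D, out.Protein_E))
        expect = brute_force_cascades(g, labels)
        assert got == expect

    def test_counts_both_conventions(self):
        labels = {"C1": "C", "C2": "C", "D1": "D", "E1": "E"}
        g = nx.Graph([("C1", "D1"), ("C2", "D1"), ("D1", "E1")])
        out = ad.enumerate_cascades(g, make_assignment(labels),
                                    require_terminal_type=None)
        counts = cascade_counts(out)
        assert counts == {"triples": 2, "de_groups": 1}


class TestCascadeLayout:
    def _cascades(self):
        labels = {"C1": "C", "D1": "D", "E1": "E"}
        comp = {"C1": "extracellular space", "D1": "cytoplasm",
                "E1": "nucleus"}
        g = nx.Graph([("C1", "D1"), ("D1", "E1")])
        out = ad.enumerate_cascades(g, make_assignment(labels),
                                    require_terminal_type=None)
        return out, make_annotations(comp)

    def test_always_nine_regions(self):
        out, ann = self._cascades()
        occupancy, _, _ = cascade_layout(out, ann)
        assert occupancy.shape == (3, 3)
        assert tuple(occupancy.index) == CASCADE_ROWS
        assert tuple(occupancy.columns) == CASCADE_COLUMNS
        empty, _, _ = cascade_layout(out.iloc[0:0], ann)
        assert empty.shape == (3, 3) and empty.to_numpy().sum() == 0

    def test_extracellular_mapped_to_membrane_row(self):
        out, ann = self._cascades()
        occupancy, placement, _ = cascade_layout(out, ann)
        row = placement[placement.protein == "C1"].iloc[0]
        assert row.row == "plasma membrane"

    def test_occupancy_conservation(self, scenario, scenario_ppi,
                                    scenario_annotations):
        restricted = ad.restrict_network(scenario_ppi,
                                         scenario["assignment"],
                                         scenario_annotations)
        casc = ad.enumerate_cascades(restricted, scenario["assignment"],
                                     scenario_annotations)
        occupancy, placement, _ = cascade_layout(casc, scenario_annotations)
        members = (set(casc.Protein_C) | set(casc.Protein_D)
                   | set(casc.Protein_E))
        assert occupancy.to_numpy().sum() == len(members)
        assert occupancy.to_numpy().sum() == placement.protein.nunique()


def test_planted_pairs_flagged(scenario, scenario_ppi):
    """The planted C/E, D/E, C/D excess is exactly what the
    over-representation test flags, and those pairs dominate the
    inter-cluster link share."""
    asn = scenario["assignment"]
    restricted = ad.restrict_network(scenario_ppi, asn)
    stats = ad.cluster_pair_stats(restricted, asn, alpha=0.05)
    assert set(stats.flagged) == {("C", "E"), ("D", "E"), ("C", "D")}
    tbl = stats.table.set_index(["cluster_1", "cluster_2"])
    flagged_share = tbl.loc[list(stats.flagged)].pct_inter.sum()
    others = tbl.pct_inter.dropna().drop(list(stats.flagged))
    assert flagged_share > others.max() * 3
    assert flagged_share > 50.0
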