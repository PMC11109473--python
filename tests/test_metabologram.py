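"""Metabologram assembly and pathway-graph projection."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from isodiff.metabologram import (
    HYPOTHESIZED_SLOW,
    SOLID,
    PathwayDefinition,
    build_metabologram,
    project_subnetwork,
)


def met_results(rows):
    return pd.DataFrame(rows, columns=["feature_id", "effect", "p_adj", "significant"])


def deg(rows):
    return pd.DataFrame(rows, columns=["gene", "effect", "p_adj"])


@pytest.fixture
def pathway():
    return PathwayDefinition("TCA", ["AKG", "Mal"], ["OGDH", "GLUL"])


class TestBuildMetabologram:
    def test_symmetric_value_domain_and_segment_count(self, pathway):
        gram = build_metabologram(
            pathway,
            met_results([("AKG", 1.0, 0.01, True), ("Mal", -1.0, 0.5, False)]),
            deg([("OGDH", 2.0, 0.01), ("GLUL", -2.0, 0.9)]),
        )
        assert gram.value_domain == (-2.0, 2.0)
        assert len(gram.metabolite_segments) + len(gram.gene_segments) == 4

    def test_all_nonsignificant_flags_false(self, pathway):
        gram = build_metabologram(
            pathway,
            met_results([("AKG", 0.2, 0.9, False), ("Mal", -0.1, 0.8, False)]),
            deg([("OGDH", 0.3, 0.7), ("GLUL", -0.2, 0.9)]),
        )
        assert not any(s.significant for s in gram.metabolite_segments + gram.gene_segments)

    def test_unmeasured_member_neutral_fill(self, pathway):
        gram = build_metabologram(
            pathway,
            met_results([("AKG", 1.0, 0.01, True), ("Mal", -0.5, 0.2, False)]),
            deg([("OGDH", 2.0, 0.01)]),  # GLUL missing
        )
        glul = {s.member_id: s for s in gram.gene_segments}["GLUL"]
        assert not glul.measured and glul.value == 0.0 and not glul.significant

    def test_color_mapping_is_odd_symmetric(self, pathway):
        base_m = [("AKG", 1.2, 0.01, True), ("Mal", -0.4, 0.2, False)]
        base_g = [("OGDH", 2.0, 0.01), ("GLUL", -1.0, 0.9)]
        g1 = build_metabologram(pathway, met_results(base_m), deg(base_g))
        g2 = build_metabologram(
            pathway,
            met_results([(f, -e, p, s) for f, e, p, s in base_m]),
            deg([(g, -e, p) for g, e, p in base_g]),
        )
        assert g1.value_domain == g2.value_domain
        for s1, s2 in zip(
            g1.metabolite_segments + g1.gene_segments,
            g2.metabolite_segments + g2.gene_segments,
        ):
            assert s1.value == -s2.value
            assert s1.scaled == -s2.scaled

    def test_member_order_does_not_matter(self):
        m = met_results([("AKG", 1.0, 0.01, True), ("Mal", -1.0, 0.5, False)])
        d = deg([("OGDH", 2.0, 0.01), ("GLUL", -2.0, 0.9)])
        g1 = build_metabologram(PathwayDefinition("P", ["AKG", "Mal"], ["OGDH", "GLUL"]), m, d)
        g2 = build_metabologram(PathwayDefinition("P", ["Mal", "AKG"], ["GLUL", "OGDH"]), m, d)
        assert g1.to_frame().equals(g2.to_frame())

    def test_gene_outside_pathway_is_ignored(self, pathway):
        m = met_results([("AKG", 1.0, 0.01, True), ("Mal", -1.0, 0.5, False)])
        d1 = deg([("OGDH", 2.0, 0.01), ("GLUL", -2.0, 0.9)])
        d2 = deg([("OGDH", 2.0, 0.01), ("GLUL", -2.0, 0.9), ("MYC", 5.0, 0.001)])
        assert build_metabologram(pathway, m, d1).to_frame().equals(
            build_metabologram(pathway, m, d2).to_frame()
        )

    def test_single_sided_pathway_still_emitted(self):
        pw = PathwayDefinition("genes_only", [], ["OGDH"])
        gram = build_metabologram(pw, met_results([]), deg([("OGDH", 1.0, 0.01)]))
        assert gram.metabolite_segments == []
        assert len(gram.gene_segments) == 1

    def test_empty_pathway_rejected(self):
        with pytest.raises(ValueError, match="no members"):
            PathwayDefinition("empty", [], [])


def toy_graph():
    g = nx.DiGraph()
    g.add_node("A", node_type="metabolite")
    g.add_node("B", node_type="metabolite")
    g.add_node("G1", node_type="gene")
    g.add_edge("A", "B")
    g.add_edge("G1", "B")
    return g


def results_for(feature, effect, significant):
    return met_results([(feature, effect, 0.01 if significant else 0.9, significant)])


class TestSubnetworkProjection:
    def test_slow_flux_rule_fires_on_decreased_enrichment_with_stable_pool(self):
        """Enrichment down + abundance up = the accumulating-pool signature."""
        net = project_subnetwork(
            toy_graph(),
            abundance_results=results_for("B", +1.0, True),
            fractional_results=results_for("B", -0.2, True),
            deg_table=deg([("G1", 1.0, 0.01)]),
        )
        assert net.edge_styles()[("A", "B")] == HYPOTHESIZED_SLOW
        assert net.graph.nodes["B"]["dam"]

    def test_no_significant_features_all_edges_solid(self):
        net = project_subnetwork(
            toy_graph(),
            abundance_results=results_for("B", 0.1, False),
            fractional_results=results_for("B", -0.05, False),
            deg_table=deg([("G1", 0.2, 0.9)]),
        )
        assert set(net.edge_styles().values()) == {SOLID}

    def test_abundance_only_significance_keeps_edges_solid(self):
        """The rule needs an enrichment decrease, not just any DAM."""
        net = project_subnetwork(
            toy_graph(),
            abundance_results=results_for("B", 2.0, True),
            fractional_results=results_for("B", 0.05, False),
            deg_table=deg([("G1", 1.0, 0.01)]),
        )
        assert net.edge_styles()[("A", "B")] == SOLID
        assert net.graph.nodes["B"]["dam"]

    def test_enrichment_drop_with_shrinking_pool_is_not_slow_flux(self):
        net = project_subnetwork(
            toy_graph(),
            abundance_results=results_for("B", -1.5, True),
            fractional_results=results_for("B", -0.2, True),
            deg_table=deg([("G1", 1.0, 0.01)]),
        )
        assert net.edge_styles()[("A", "B")] == SOLID

    def test_node_shapes_follow_type_convention(self):
        net = project_subnetwork(
            toy_graph(),
            abundance_results=results_for("B", 1.0, True),
            fractional_results=results_for("B", -0.2, True),
            deg_table=deg([("G1", 1.0, 0.01)]),
        )
        assert net.graph.nodes["A"]["shape"] == "oval"
        assert net.graph.nodes["G1"]["shape"] == "rectangle"

    def test_untyped_node_rejected(self):
        g = toy_graph()
        g.add_node("X")
        with pytest.raises(ValueError, match="X"):
            project_subnetwork(
                g,
                abundance_results=results_for("B", 1.0, True),
                fractional_results=results_for("B", -0.2, True),
                deg_table=deg([("G1", 1.0, 0.01)]),
            )
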