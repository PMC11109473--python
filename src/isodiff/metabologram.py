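"""Pathway-scoped integration of metabolite and gene differential results.

A *metabologram* juxtaposes, for one pathway and one biological
comparison, the differential values of the pathway's metabolites (inner
ring) and of the genes encoding its enzymes (outer ring), on a color
scale that is symmetric about zero so that up- and down-regulation are
visually comparable across the two omics.

The same inputs can be projected onto a user-supplied pathway graph
(metabolite and gene nodes, reaction edges). Edges feeding a metabolite
whose ¹³C enrichment dropped significantly while its pool did not shrink
are styled as *hypothesized slow fluxes*: the pattern of an accumulating
pool fed ever more slowly by labeled carbon — an interpretive aid, not an
inference, and labeled as such in the output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd



@dataclass
class PathwayDefinition:
    """Named pathway with metabolite and gene member lists."""

    pathway_id: str
    metabolite_members: list[str] = field(default_factory=list)
    gene_members: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.metabolite_members and not self.gene_members:
            raise ValueError(f"pathway {self.pathway_id!r} has no members")
        for name, members in (("metabolite", self.metabolite_members),
                              ("gene", self.gene_members)):
            if len(members) != len(set(members)):
                raise ValueError(f"duplicate {name} members in {self.pathway_id!r}")


def read_pathway_definitions(path) -> list[PathwayDefinition]:
    """TSV with columns pathway_id, member_type {metabolite, gene}, member_id."""
    frame = pd.read_csv(path, sep="\t")
    out = []
    for pid, sub in frame.groupby("pathway_id", sort=True):
        out.append(
            PathwayDefinition(
                pathway_id=str(pid),
                metabolite_members=list(sub.loc[sub["member_type"] == "metabolite", "member_id"]),
                gene_members=list(sub.loc[sub["member_type"] == "gene", "member_id"]),
            )
        )
    return out


@dataclass(frozen=True)
class Segment:
    """One ring segment: a member with its differential value and status."""

    member_id: str
    value: float          # signed differential value (log2FC or Δmean)
    scaled: float         # value normalized to [-1, 1] within this side
    significant: bool
    measured: bool


@dataclass
class Metabologram:
    pathway_id: str
    comparison: str
    metabolite_segments: list[Segment]
    gene_segments: list[Segment]
    value_domain: tuple[float, float]  # symmetric about 0 across both omics

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"pathway_id": self.pathway_id, "comparison": self.comparison,
             "omics": omics, "member_id": s.member_id, "value": s.value,
             "scaled": s.scaled, "significant": s.significant, "measured": s.measured}
            for omics, segs in (("metabolite", self.metabolite_segments),
                                ("gene", self.gene_segments))
            for s in segs
        ]
        return pd.DataFrame(rows)


def _segments(
    members: list[str], values: dict[str, float], significance: dict[str, bool]
) -> list[Segment]:
    # alphabetical ordering makes the ring layout order-independent
    segs = []
    scale = max((abs(values[m]) for m in members if m in values and np.isfinite(values[m])),
                default=0.0)
    for m in sorted(members):
        if m in values and np.isfinite(values[m]):
            v = float(values[m])
            segs.append(Segment(m, v, v / scale if scale > 0 else 0.0,
                                bool(significance.get(m, False)), True))
        else:
            segs.append(Segment(m, 0.0, 0.0, False, False))
    return segs


def build_metabologram(
    pathway: PathwayDefinition,
    metabolite_results: pd.DataFrame,
    deg_table: pd.DataFrame,
    alpha: float = 0.05,
    comparison: str = "",
) -> Metabologram:
    """Assemble the paired-ring structure for one pathway.

    ``metabolite_results`` is a univariate result frame (columns
    feature_id, effect, p_adj); ``deg_table`` holds gene, effect
    (log2 fold change) and p_adj from an upstream differential-expression
    analysis. Members absent from either table enter as neutral segments
    flagged "not measured". The color domain is the symmetric envelope of
    the raw effects across both omics; within each ring, values are also
    rescaled to [−1, 1] so neither omics' dynamic range swamps the other.
    """
    if (deg_table["p_adj"].dropna() <= 0).any() or (deg_table["p_adj"].dropna() > 1).any():
        raise ValueError("DEG adjusted p-values must lie in (0, 1]")
    met_vals = dict(zip(metabolite_results["feature_id"], metabolite_results["effect"]))
    met_sig = {
        f: bool(p <= alpha) if np.isfinite(p) else False
        for f, p in zip(metabolite_results["feature_id"], metabolite_results["p_adj"])
    }
    gene_vals = dict(zip(deg_table["gene"], deg_table["effect"]))
    gene_sig = {
        g: bool(p <= alpha) if np.isfinite(p) else False
        for g, p in zip(deg_table["gene"], deg_table["p_adj"])
    }

    met_segs = _segments(pathway.metabolite_members, met_vals, met_sig)
    gene_segs = _segments(pathway.gene_members, gene_vals, gene_sig)

    extreme = max(
        (abs(s.value) for s in met_segs + gene_segs if s.measured), default=0.0
    )
    return Metabologram(
        pathway_id=pathway.pathway_id,
        comparison=comparison,
        metabolite_segments=met_segs,
        gene_segments=gene_segs,
        value_domain=(-extreme, extreme),
    )


# ---------------------------------------------------------------------------
# Network projection
# ---------------------------------------------------------------------------

SOLID = "solid"
HYPOTHESIZED_SLOW = "hypothesized-slow"


@dataclass
class PathwaySubnetwork:
    """Typed differential overlay on a reaction graph.

    Metabolite nodes render as ovals, gene nodes as rectangles; edges
    carry a style flag, dotted when hypothesized slow.
    """

    graph: nx.DiGraph
    pathway_id: str = ""
    metadata: dict = field(default_factory=dict)

    def edge_styles(self) -> dict[tuple[str, str], str]:
        return {(u, v): d["style"] for u, v, d in self.graph.edges(data=True)}


def read_pathway_graph(edge_path, node_path) -> nx.DiGraph:
    """Edge list TSV (source, target) plus node table TSV (node_id, node_type)."""
    nodes = pd.read_csv(node_path, sep="\t")
    edges = pd.read_csv(edge_path, sep="\t")
    g = nx.DiGraph()
    for _, row in nodes.iterrows():
        g.add_node(str(row["node_id"]), node_type=str(row["node_type"]))
    for _, row in edges.iterrows():
        g.add_edge(str(row["source"]), str(row["target"]))
    return g


def project_subnetwork(
    graph: nx.DiGraph,
    abundance_results: pd.DataFrame,
    fractional_results: pd.DataFrame,
    deg_table: pd.DataFrame,
    alpha: float = 0.05,
    pathway_id: str = "",
) -> PathwaySubnetwork:
    """Annotate a reaction graph with differential status and edge styles.

    Node annotations: metabolites get ``dam`` (significant in abundance
    and/or enrichment); genes get ``deg``. An edge u→v is styled
    ``hypothesized-slow`` when its product metabolite v shows a
    significant *decrease* in fractional contribution while its total
    abundance is non-decreasing — the signature of a pool that fills from
    unlabeled sources or empties more slowly than it labels.
    """
    known = set(abundance_results["feature_id"]) | set(fractional_results["feature_id"]) | set(
        deg_table["gene"]
    )
    unknown = [
        n for n, d in graph.nodes(data=True)
        if n not in known and d.get("node_type") == "metabolite"
    ]
    node_types = nx.get_node_attributes(graph, "node_type")
    missing_type = [n for n in graph.nodes if n not in node_types]
    if missing_type:
        raise ValueError(f"graph nodes without node_type annotation: {missing_type}")

    ab = abundance_results.set_index("feature_id")
    fc = fractional_results.set_index("feature_id")
    dg = deg_table.set_index("gene")

    out = graph.copy()
    for n, d in out.nodes(data=True):
        if d["node_type"] == "metabolite":
            a_sig = bool(n in ab.index and ab.loc[n, "significant"])
            f_sig = bool(n in fc.index and fc.loc[n, "significant"])
            d["dam"] = a_sig or f_sig
            d["abundance_effect"] = float(ab.loc[n, "effect"]) if n in ab.index else np.nan
            d["fractional_effect"] = float(fc.loc[n, "effect"]) if n in fc.index else np.nan
            d["abundance_significant"] = a_sig
            d["fractional_significant"] = f_sig
            d["shape"] = "oval"
        elif d["node_type"] == "gene":
            sig = bool(n in dg.index and dg.loc[n, "p_adj"] <= alpha)
            d["deg"] = sig
            d["effect"] = float(dg.loc[n, "effect"]) if n in dg.index else np.nan
            d["shape"] = "rectangle"
        else:
            raise ValueError(f"node {n!r} has unsupported type {d['node_type']!r}")

    for u, v, d in out.edges(data=True):
        nd = out.nodes[v]
        slow = (
            nd.get("node_type") == "metabolite"
            and nd.get("fractional_significant", False)
            and np.isfinite(nd.get("fractional_effect", np.nan))
            and nd["fractional_effect"] < 0
            and (not np.isfinite(nd.get("abundance_effect", np.nan))
                 or nd["abundance_effect"] >= 0)
        )
        d["style"] = HYPOTHESIZED_SLOW if slow else SOLID

    return PathwaySubnetwork(
        graph=out,
        pathway_id=pathway_id,
        metadata={
            "alpha": alpha,
            "unmeasured_metabolite_nodes": sorted(unknown),
            "edge_style_rule": (
                "hypothesized-slow: product metabolite with significant decrease in "
                "fractional contribution and non-decreasing total abundance; "
                "interpretive aid, not a flux inference"
            ),
        },
    )
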