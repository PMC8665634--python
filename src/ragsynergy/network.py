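"""Homolog-collapsed TF network annotation.

DE transcription factors are collapsed onto their best reference-species
(e.g. Arabidopsis) homolog — several soybean paralogs may share one node
("split" nodes) — annotated with DE provenance (pyramid only, pyramid plus
a monogenic line, ...), and nodes without any interaction are pruned.
Interaction edges come from an external edge list (e.g. a STRING export
keyed by homolog IDs); no interaction inference happens here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

PROVENANCE_CLASSES = (
    "pyramid_only",
    "pyramid_and_R1",
    "pyramid_and_R2",
    "pyramid_and_multiple",
    "not_in_pyramid",
)


@dataclass
class AnnotatedNode:
    homolog: str
    members: list[str]
    provenance: dict[str, str] = field(default_factory=dict)  # member -> class
    direction: dict[str, str] = field(default_factory=dict)  # member -> induced/repressed

    @property
    def split(self) -> bool:
        return len(self.members) >= 2

    @property
    def summary_class(self) -> str:
        """pyramid_only iff every member is pyramid_only; else "mixed"."""
        classes = set(self.provenance.values())
        return classes.pop() if len(classes) == 1 else "mixed"


def collapse_by_homolog(genes: list[str], homolog_map: dict[str, str]) -> dict[str, AnnotatedNode]:
    """One node per homolog; genes without a homolog are skipped with a
    logged warning.  Each gene maps to at most one homolog (many-to-one)."""
    nodes: dict[str, AnnotatedNode] = {}
    for g in sorted(set(genes)):
        hom = homolog_map.get(g)
        if hom is None:
            logger.warning("gene %s has no homolog mapping; excluded", g)
            continue
        node = nodes.setdefault(hom, AnnotatedNode(homolog=hom, members=[]))
        node.members.append(g)
    return nodes


def provenance_class(gene: str, de_sets: dict[str, set], pyramid: str = "R12") -> str:
    """DE-provenance of a gene from the per-genotype DE sets."""
    in_pyr = gene in de_sets.get(pyramid, set())
    others = sorted(g for g, s in de_sets.items() if g != pyramid and gene in s)
    if not in_pyr:
        return "not_in_pyramid"
    if not others:
        return "pyramid_only"
    if len(others) == 1:
        return f"pyramid_and_{others[0]}"
    return "pyramid_and_multiple"


def annotate_and_prune(
    nodes: dict[str, AnnotatedNode],
    edges: pd.DataFrame,
    de_sets: dict[str, set],
    directions: dict[str, str] | None = None,
    pyramid: str = "R12",
) -> nx.Graph:
    """Assign provenance, drop edges to unknown nodes, prune isolates.

    Returns an undirected graph whose node attributes carry members, split
    flag, per-member provenance and the node summary class; graph-level
    attributes report component sizes and the synergistic (pyramid-only)
    node count.
    """
    for node in nodes.values():
        for g in node.members:
            node.provenance[g] = provenance_class(g, de_sets, pyramid)
            if directions and g in directions:
                node.direction[g] = directions[g]

    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    for _, row in edges.iterrows():
        a, b = row["node_a"], row["node_b"]
        if a not in nodes or b not in nodes:
            logger.warning("edge %s--%s references unknown node; dropped", a, b)
            continue
        if a == b:
            continue
        graph.add_edge(a, b, score=float(row.get("score", 1.0)))

    isolates = [n for n in graph.nodes if graph.degree(n) == 0]
    graph.remove_nodes_from(isolates)

    for hom in graph.nodes:
        node = nodes[hom]
        graph.nodes[hom].update(
            members=",".join(node.members),
            n_members=len(node.members),
            split=node.split,
            summary_class=node.summary_class,
            provenance=";".join(f"{g}={c}" for g, c in sorted(node.provenance.items())),
            direction=";".join(f"{g}={d}" for g, d in sorted(node.direction.items())),
        )

    components = sorted((len(c) for c in nx.connected_components(graph)), reverse=True)
    graph.graph["component_sizes"] = components
    graph.graph["n_pruned_isolates"] = len(isolates)
    graph.graph["n_synergistic_nodes"] = sum(
        1 for n in graph.nodes if graph.nodes[n]["summary_class"] == "pyramid_only"
    )
    return graph


def node_table(graph: nx.Graph) -> pd.DataFrame:
    rows = [
        {
            "homolog": n,
            "members": d["members"],
            "n_members": d["n_members"],
            "split": d["split"],
            "summary_class": d["summary_class"],
            "provenance": d["provenance"],
            "degree": graph.degree(n),
        }
        for n, d in graph.nodes(data=True)
    ]
    cols = ["members", "n_members", "split", "summary_class", "provenance", "degree"]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows).set_index("homolog").sort_index()


def write_graph(graph: nx.Graph, graphml_path=None, edgelist_path=None) -> None:
    if graphml_path is not None:
        g = graph.copy()
        g.graph.pop("component_sizes", None)  # GraphML scalars only
        nx.write_graphml(g, graphml_path)
    if edgelist_path is not None:
        with open(edgelist_path, "w") as fh:
            fh.write("node_a\tnode_b\tscore\n")
            for a, b, d in sorted(graph.edges(data=True)):
                fh.write(f"{a}\t{b}\t{d.get('score', 1.0)}\n")
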