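"""Homolog-collapsed TF network for the 6 h pyramid response: collapse
pyramid-DE TFs onto reference homolog nodes, annotate DE provenance,
prune non-interacting nodes, report components."""

import json

from common import DE_DIR, GENOTYPES, NETWORK_DIR, RESULTS, SYNERGY_DIR

from ragsynergy import data_io, network
from ragsynergy.de import ContrastResult

NETWORK_DIR.mkdir(parents=True, exist_ok=True)
ann_dir = RESULTS / "annotation"
annotation = data_io.read_annotation(
    ann_dir / "genes.gff3", tf_map_path=ann_dir / "tf_map.tsv",
    homolog_map_path=ann_dir / "homolog_map.tsv",
)
edges = data_io.read_edge_list(ann_dir / "tf_edges.tsv")

with open(SYNERGY_DIR / "partition_6h.json") as fh:
    part = json.load(fh)
de_sets = {g: set() for g in GENOTYPES}
for region, genes in part["regions"].items():
    for g in region.split("&"):
        de_sets[g].update(genes)

pyramid_tfs = sorted(de_sets["R12"] & set(annotation.tf_family))
print(f"{len(pyramid_tfs)} pyramid-DE TFs at 6 h")

nodes = network.collapse_by_homolog(pyramid_tfs, annotation.homolog)
n_split = sum(1 for n in nodes.values() if n.split)
fc = ContrastResult.read(DE_DIR / "R12_6h.tsv", name="R12:6h").table["log2FC"]
directions = {g: ("induced" if fc.get(g, 0) > 0 else "repressed") for g in pyramid_tfs}
graph = network.annotate_and_prune(nodes, edges, de_sets, directions)

data_io.write_table(network.node_table(graph), NETWORK_DIR / "nodes.tsv")
network.write_graph(graph, NETWORK_DIR / "network.graphml", NETWORK_DIR / "edges.tsv")
print(f"{len(nodes)} homolog nodes ({n_split} split), "
      f"{graph.number_of_nodes()} remain after pruning "
      f"({graph.graph['n_pruned_isolates']} isolates removed)")
print(f"component sizes: {graph.graph['component_sizes']}")
print(f"synergistic (pyramid-only) nodes: {graph.graph['n_synergistic_nodes']}")
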