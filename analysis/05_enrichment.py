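"""GO-term overrepresentation of the 6 h synergy set and TF-family
synergy shares (families where >= 50% of pyramid-DE TFs are synergistic)."""

import json

from common import DE_DIR, ENRICH_DIR, RESULTS, SYNERGY_DIR, write_annotation_inputs

from ragsynergy import data_io
from ragsynergy.de import ContrastResult
from ragsynergy.enrichment import fisher_enrichment, invert_gene_map, tf_family_synergy_share

ENRICH_DIR.mkdir(parents=True, exist_ok=True)
ann_dir = write_annotation_inputs(RESULTS / "annotation")
annotation = data_io.read_annotation(
    ann_dir / "genes.gff3", ann_dir / "go_map.tsv",
    ann_dir / "tf_map.tsv", ann_dir / "homolog_map.tsv",
)

with open(SYNERGY_DIR / "partition_6h.json") as fh:
    part = json.load(fh)
synergy_set = set(part["regions"].get("R12", []))
pyramid_de = set().union(
    *(set(v) for k, v in part["regions"].items() if "R12" in k.split("&"))
)

background = set(annotation.coords.index)
contrast = ContrastResult.read(DE_DIR / "R12_6h.tsv", name="R12:6h")
table = fisher_enrichment(
    synergy_set & background, invert_gene_map(annotation.go), background,
    contrast=contrast,
)
data_io.write_table(table, ENRICH_DIR / "go_synergy_6h.tsv")
n_sig = int(table["significant"].sum()) if len(table) else 0
print(f"GO: {len(table)} terms with >= 1 synergy gene, {n_sig} significant "
      "after Bonferroni (synthetic annotation: enrichment is not expected)")

tf_genes = set(annotation.tf_family)
shares = tf_family_synergy_share(
    pyramid_de & tf_genes, annotation.tf_family, synergy_set
)
data_io.write_table(shares, ENRICH_DIR / "tf_family_share_6h.tsv")
flagged = shares.index[shares["flagged"]].tolist() if len(shares) else []
print(f"TF families with >= 50% synergistic pyramid-DE members: {flagged}")
print(shares.to_string())
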