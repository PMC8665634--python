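"""Expression-profile clustering: z-scored log2FC across the 8 contrasts,
Pearson-distance complete linkage; global cut at k=6 and a k=2 cut of the
6 h synergy set."""

import json

from common import CLUSTER_DIR, DE_DIR, GENOTYPES, SYNERGY_DIR

from ragsynergy import profiles
from ragsynergy.de import ContrastResult

CLUSTER_DIR.mkdir(parents=True, exist_ok=True)

contrasts = {
    f"{g}:{tp}h": ContrastResult.read(DE_DIR / f"{g}_{tp}h.tsv", name=f"{g}:{tp}h")
    for tp in (6, 12)
    for g in GENOTYPES
}
prof = profiles.build_profile_matrix(contrasts)
tree = profiles.hier_cluster(prof)
labels = profiles.cut_clusters(tree, 6)
labels.rename_axis("gene").to_csv(CLUSTER_DIR / "clusters_k6.tsv", sep="\t")
(CLUSTER_DIR / "dendrogram.nwk").write_text(profiles.to_newick(tree))
profiles.plot_heatmap(prof, tree, CLUSTER_DIR / "heatmap.png")
print(f"{len(prof.values)} DE genes clustered; k=6 sizes: "
      f"{labels.value_counts().sort_index().tolist()}")

with open(SYNERGY_DIR / "partition_6h.json") as fh:
    part = json.load(fh)
syn_genes = set(part["regions"].get("R12", []))
if len(syn_genes) >= 2:
    syn_prof = profiles.build_profile_matrix(
        contrasts, de_universe=syn_genes & set(prof.gene_ids)
    )
    syn_tree = profiles.hier_cluster(syn_prof)
    syn_labels = profiles.cut_clusters(syn_tree, 2)
    syn_labels.rename_axis("gene").to_csv(CLUSTER_DIR / "synergy_clusters_k2.tsv", sep="\t")
    sizes = syn_labels.value_counts().sort_index()
    mean_z = {
        int(k): round(float(syn_prof.values.loc[syn_labels == k, "R12:6h"].mean()), 2)
        for k in sizes.index
    }
    print(f"6 h synergy set: k=2 cluster sizes {sizes.tolist()} "
          f"(mean z in pyramid 6 h per cluster: {mean_z})")
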