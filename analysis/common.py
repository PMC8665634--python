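"""Shared paths and synthetic annotation inputs for the analysis scripts.

The drivers run on a synthetic experiment with the study design
(4 genotypes x 2 treatments x 2 timepoints x 3 replicates) and planted
effect classes; annotation maps (coordinates, GO terms, TF families,
homologs, TF interactions) are generated deterministically so the full
workflow — enrichment, locus scan, network — can be exercised end to end.
"""

from pathlib import Path

import numpy as np

from ragsynergy import simdata

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SIM_DIR = RESULTS / "sim"
DE_DIR = RESULTS / "de"
SYNERGY_DIR = RESULTS / "synergy"
CLUSTER_DIR = RESULTS / "clusters"
ENRICH_DIR = RESULTS / "enrichment"
LOCUS_DIR = RESULTS / "locus"
NETWORK_DIR = RESULTS / "network"

SEED = 20240612
N_GENES = 4000
GENOTYPES = ("S", "R1", "R2", "R12")

SIM_CONFIG = simdata.EffectClassConfig(n_genes=N_GENES)
DESIGN = simdata.DesignSpec(seed=SEED)

# synthetic locus: a contiguous block of genes on chromosome 1 that also
# receives a planted constitutive expression shift in R1 carriers would
# require mock-contrast effects; here the scan demonstrates the interval +
# ranking machinery on the DE landscape as simulated
LOCUS = {"name": "RagA", "chrom": "chr1", "start": 900_000, "end": 1_400_000}


def gene_ids(n=N_GENES):
    width = len(str(n))
    return [f"gene_{i:0{width}d}" for i in range(1, n + 1)]


def write_annotation_inputs(out_dir: Path, n=N_GENES, seed=SEED):
    """Deterministic GFF3 + GO/TF/homolog maps + TF edge list."""
    out_dir.mkdir(parents=True, exist_ok=True)
    genes = gene_ids(n)
    rng = np.random.default_rng(seed)
    half = n // 2
    with open(out_dir / "genes.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for i, g in enumerate(genes):
            chrom = "chr1" if i < half else "chr2"
            start = 1_000 + (i % half) * 3_000
            fh.write(f"{chrom}\tsim\tgene\t{start}\t{start + 1_500}\t.\t+\t.\tID={g}\n")
    terms = [f"GO:{i:07d}" for i in range(1, 41)]
    with open(out_dir / "go_map.tsv", "w") as fh:
        for g in genes:
            for t in rng.choice(terms, size=rng.integers(0, 5), replace=False):
                fh.write(f"{g}\t{t}\n")
    families = ["WRKY", "MYB", "NAC", "BHLH", "AP2-EREBP", "BZIP", "ZIM", "TCP"]
    tf_genes = genes[::8]
    with open(out_dir / "tf_map.tsv", "w") as fh:
        for g in tf_genes:
            fh.write(f"{g}\t{rng.choice(families)}\n")
    with open(out_dir / "homolog_map.tsv", "w") as fh:
        for i, g in enumerate(genes):
            fh.write(f"{g}\tAT{i // 2:05d}\n")
    homs = sorted({f"AT{i // 2:05d}" for i, _ in enumerate(tf_genes)})
    with open(out_dir / "tf_edges.tsv", "w") as fh:
        hom_pool = [f"AT{i:05d}" for i in range(0, n // 2, 4)]
        for _ in range(3 * len(hom_pool)):
            a, b = rng.choice(hom_pool, 2, replace=False)
            fh.write(f"{a}\t{b}\t{rng.uniform(0.4, 1.0):.3f}\n")
    return out_dir
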