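"""End-to-end orchestration: simulate or ingest counts, then per-timepoint
filtering/normalization, contrasts, synergy analysis, clustering, optional
enrichment / locus scan / network annotation — with a machine-readable run
manifest for reproducibility checks."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__, de, data_io, enrichment, locus, network, profiles, simdata, synergy

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    # input: either simulate=True (synthetic) or counts+samplesheet paths
    simulate: bool = True
    counts_path: str | None = None
    samplesheet_path: str | None = None
    sim: dict = field(default_factory=dict)  # EffectClassConfig overrides
    design: dict = field(default_factory=dict)  # DesignSpec overrides

    alpha: float = 0.05
    relaxed: float = 0.25
    cpm_threshold: float = 1.0
    min_samples: int | None = None
    prior_df: float = 10.0
    chisq_method: str = "standardized"
    cluster_k_global: int = 6
    cluster_k_synergy: int = 2

    pyramid: str = "R12"
    monogenic: tuple[str, str] = ("R1", "R2")
    susceptible: str = "S"

    # optional annotation-driven stages
    gff3_path: str | None = None
    go_map_path: str | None = None
    tf_map_path: str | None = None
    homolog_map_path: str | None = None
    edge_list_path: str | None = None
    loci: list = field(default_factory=list)  # [{name, chrom, start, end}]

    seed: int = 0
    out_dir: str = "run"

    def validate(self) -> None:
        for name, v in (("alpha", self.alpha), ("relaxed", self.relaxed)):
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if min(self.cluster_k_global, self.cluster_k_synergy) < 1:
            raise ValueError("cluster k must be >= 1")
        if not self.simulate:
            for p in (self.counts_path, self.samplesheet_path):
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"input file not found: {p}")
        for key in ("gff3_path", "go_map_path", "tf_map_path", "homolog_map_path", "edge_list_path"):
            p = getattr(self, key)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{key}: file not found: {p}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "monogenic" in raw:
            raw["monogenic"] = tuple(raw["monogenic"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every configured stage; returns (and writes) the run manifest.

    Outputs land under ``config.out_dir`` with fixed names; a rerun with the
    same config and seed reproduces them bit-identically (manifest records
    sha256 checksums, excluding timings).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_times: dict[str, float] = {}
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            k: v for k, v in vars(config).items() if not k.endswith("_path")
        },
        "outputs": {},
    }

    def stage(name):
        logger.info("stage: %s", name)
        stage_times[name] = time.time()
        return name

    def done(name):
        stage_times[name] = round(time.time() - stage_times[name], 3)

    # ------------------------------------------------------------------ input
    s = stage("input")
    if config.simulate:
        design = simdata.DesignSpec(seed=config.seed, **config.design)
        sim_cfg = simdata.EffectClassConfig(**config.sim)
        truth, matrix = simdata.simulate(sim_cfg, design)
        truth.write(out / "truth.tsv")
        data_io.write_counts(matrix, out / "counts.tsv", out / "samples.csv")
    else:
        matrix = data_io.read_counts(config.counts_path, config.samplesheet_path)
    done(s)

    timepoints = sorted(int(t) for t in matrix.samples["timepoint"].unique())
    genotypes = list(dict.fromkeys(matrix.samples["genotype"]))

    # --------------------------------------------------- per-timepoint DE
    s = stage("differential_expression")
    contrasts_by_tp: dict[int, dict[str, de.ContrastResult]] = {}
    norm_by_tp = {}
    for tp in timepoints:
        filtered, norm, disp = de.timepoint_workflow(
            matrix, tp, config.cpm_threshold, config.min_samples, config.prior_df
        )
        norm_by_tp[tp] = (filtered, norm, disp)
        contrasts = {}
        for g in genotypes:
            res = de.aphid_vs_mock(filtered, norm, disp, g, tp)
            res.write(out / f"contrast_{g}_{tp}h_aphid_vs_mock.tsv")
            contrasts[g] = res
        contrasts_by_tp[tp] = contrasts
    done(s)

    # --------------------------------------------------------------- synergy
    s = stage("synergy")
    partitions, reports = {}, {}
    for tp in timepoints:
        part = synergy.partition_de_sets(
            contrasts_by_tp[tp], config.alpha, config.pyramid, timepoint=tp
        )
        part.write(out / f"partition_{tp}h.json")
        rep = synergy.synergy_report(
            part,
            contrasts_by_tp[tp],
            r1=config.monogenic[0],
            r2=config.monogenic[1],
            alpha=config.alpha,
            relaxed=config.relaxed,
            chisq_method=config.chisq_method,
        )
        rep.write(out / f"synergy_{tp}h.tsv")
        rep.write_aggregate(out / f"additivity_{tp}h.tsv")
        partitions[tp], reports[tp] = part, rep
    if len(timepoints) >= 2:
        t1, t2 = timepoints[0], timepoints[1]
        dyn = synergy.timepoint_overlap(
            partitions[t1], partitions[t2], contrasts_by_tp[t1], contrasts_by_tp[t2]
        )
        dyn.write(out / "dynamics.tsv")
    done(s)

    # ------------------------------------------------------------- clustering
    s = stage("clustering")
    flat_contrasts = {
        f"{g}:{tp}h": c
        for tp in timepoints
        for g, c in contrasts_by_tp[tp].items()
    }
    # contrasts can have different filtered universes per timepoint; cluster
    # on the shared universe
    shared = set.intersection(*(set(c.gene_ids) for c in flat_contrasts.values()))
    trimmed = {
        name: de.ContrastResult(name=name, table=c.table.loc[sorted(shared)])
        for name, c in flat_contrasts.items()
    }
    de_union = set()
    for c in trimmed.values():
        de_union |= c.de_genes(config.alpha)
    if len(de_union) >= 2:
        prof = profiles.build_profile_matrix(trimmed, config.alpha, de_universe=de_union)
        tree = profiles.hier_cluster(prof)
        k = min(config.cluster_k_global, len(tree.gene_ids))
        labels = profiles.cut_clusters(tree, k)
        data_io.write_table(prof.values, out / "profiles.tsv")
        labels.rename_axis("gene").to_csv(out / "clusters.tsv", sep="\t")
        (out / "dendrogram.nwk").write_text(profiles.to_newick(tree))
        profiles.plot_heatmap(prof, tree, out / "heatmap.png")
    done(s)

    # ------------------------------------------------------------- annotation
    annotation = None
    if config.gff3_path:
        s = stage("annotation")
        annotation = data_io.read_annotation(
            config.gff3_path, config.go_map_path, config.tf_map_path,
            config.homolog_map_path,
        )
        done(s)

    if annotation is not None and annotation.go:
        s = stage("enrichment")
        background = set(annotation.coords.index)
        term_map = enrichment.invert_gene_map(annotation.go)
        for tp in timepoints:
            syn_set = partitions[tp].synergy_set & background
            if syn_set:
                table = enrichment.fisher_enrichment(
                    syn_set, term_map, background, config.alpha,
                    contrast=contrasts_by_tp[tp][config.pyramid],
                )
                data_io.write_table(table, out / f"go_enrichment_synergy_{tp}h.tsv")
        done(s)

    if annotation is not None and annotation.tf_family:
        s = stage("tf_families")
        tf_genes = set(annotation.tf_family)
        for tp in timepoints:
            pyr_de_tfs = partitions[tp].genotype_sets[config.pyramid] & tf_genes
            shares = enrichment.tf_family_synergy_share(
                pyr_de_tfs, annotation.tf_family, partitions[tp].synergy_set
            )
            data_io.write_table(shares, out / f"tf_family_share_{tp}h.tsv")
        done(s)

    if annotation is not None and config.loci:
        s = stage("locus_scan")
        for spec in config.loci:
            interval = locus.LocusInterval(
                spec["name"], spec["chrom"], int(spec["start"]), int(spec["end"])
            )
            genes = locus.genes_in_interval(annotation, interval)
            carrier = spec.get("carrier", config.monogenic[0])
            other = [m for m in config.monogenic if m != carrier][0]
            mock_contrasts = {}
            for tp in timepoints:
                filtered, norm, disp = norm_by_tp[tp]
                for name, (ga, gb) in {
                    f"{carrier}vSusc:{tp}h": (carrier, config.susceptible),
                    f"{config.pyramid}vSusc:{tp}h": (config.pyramid, config.susceptible),
                    f"{config.pyramid}v{other}:{tp}h": (config.pyramid, other),
                }.items():
                    mock_contrasts[name] = de.genotype_vs_genotype_mock(
                        filtered, norm, disp, ga, gb, tp
                    )
            summary = locus.locus_de_summary(genes, mock_contrasts, interval, config.alpha)
            ranked = locus.rank_candidates(summary)
            data_io.write_table(
                locus.format_locus_report(summary), out / f"locus_{interval.name}.tsv"
            )
            data_io.write_table(ranked, out / f"locus_{interval.name}_ranked.tsv")
        done(s)

    if annotation is not None and config.edge_list_path and annotation.homolog:
        s = stage("network")
        edges = data_io.read_edge_list(config.edge_list_path)
        tp = timepoints[0]
        pyr_de = partitions[tp].genotype_sets[config.pyramid]
        tf_de = sorted(pyr_de & set(annotation.tf_family)) if annotation.tf_family else sorted(pyr_de)
        nodes = network.collapse_by_homolog(tf_de, annotation.homolog)
        fc = contrasts_by_tp[tp][config.pyramid].table["log2FC"]
        directions = {
            g: ("induced" if fc.get(g, 0) > 0 else "repressed") for g in tf_de
        }
        graph = network.annotate_and_prune(
            nodes, edges, partitions[tp].genotype_sets, directions, config.pyramid
        )
        data_io.write_table(network.node_table(graph), out / "network_nodes.tsv")
        network.write_graph(
            graph, out / "network.graphml", out / "network_edges.tsv"
        )
        done(s)

    # -------------------------------------------------------------- manifest
    for path in sorted(out.iterdir()):
        if path.name == "manifest.json" or not path.is_file():
            continue
        manifest["outputs"][path.name] = _sha256(path)
    manifest["stage_seconds"] = stage_times
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
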