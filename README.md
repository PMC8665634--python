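# ragsynergy

Detecting **synergistic transcriptional responses in resistance-gene
pyramids** from bulk RNA-seq counts.

## The problem

Stacking ("pyramiding") two resistance genes in one crop genotype can
produce defense responses that neither gene triggers alone. The motivating
system is soybean aphid resistance: near-isogenic lines carrying *Rag1*
(chromosome 7), *Rag2* (chromosome 13), both (*Rag1/2*), or neither are
infested with aphids or mock-treated and profiled at 6 and 12 h
(4 genotypes × 2 treatments × 2 timepoints × 3 replicates = 48 libraries).
Two questions drive the analysis:

1. **Synergy.** Which genes respond to aphids *only* in the pyramid? Is
   their response magnitude explained by adding the monogenic responses
   (log2FC<sub>*R1/2*</sub> ≈ log2FC<sub>*R1*</sub> + log2FC<sub>*R2*</sub>,
   the *additive expectation*), or does it depart from additivity?
2. **Candidate genes.** Among genes inside the mapped *Rag* intervals,
   which are constitutively expressed higher in every resistant carrier —
   the behavior expected of the resistance gene itself?

## What the package computes

| Stage | Module | Method |
|---|---|---|
| Synthetic experiments | `ragsynergy.simdata` | NB counts (var = μ + φμ²), lognormal depths, planted effect classes: null, shared, monogenic-only, additive, synergistic |
| I/O | `ragsynergy.data_io` | counts TSV + sample sheet, GFF3, GO/TF/homolog maps, edge lists |
| Differential expression | `ragsynergy.de` | CPM < 1 filter, TMM normalization per timepoint, moment + shrinkage dispersion, exact conditional NB test, BH FDR |
| Synergy | `ragsynergy.synergy` | 4-set Venn partition; strict rule q<sub>pyr</sub> < 0.05 **and** q<sub>R1</sub>, q<sub>R2</sub> > 0.25; additivity χ²: T = Σ(d<sub>obs</sub> − d<sub>exp</sub>)²/(se²<sub>obs</sub>+se²<sub>R1</sub>+se²<sub>R2</sub>) |
| Profiles | `ragsynergy.profiles` | per-gene z-scored log2FC, complete linkage on 1 − Pearson r, k = 6 global / k = 2 synergy cuts |
| Enrichment | `ragsynergy.enrichment` | one-sided Fisher (hypergeometric) + Bonferroni; TF-family ≥ 50%-synergistic rule |
| Locus scan | `ragsynergy.locus` | interval overlap queries, mock genotype-vs-genotype grids, direction-consistency ranking, FC = 2^log2FC |
| TF networks | `ragsynergy.network` | collapse paralogs onto reference homolog nodes (split circles), DE-provenance classes, isolate pruning |
| Orchestration | `ragsynergy.pipeline` / `ragsynergy.cli` | YAML-configured run with a checksummed manifest |

## Worked example

The numbered drivers under `analysis/` run the whole workflow on a
synthetic 4000-gene experiment (planted classes, constant-rate library of
effects at 6 h only) and write tables under `results/`:

```bash
cd analysis
python 01_simulate.py && python 02_differential_expression.py && python 03_synergy.py
```

prints (abridged):

```
6 h: 4000 genes pass the CPM filter, common dispersion 0.092
  R12:6h:aphid-vs-mock: 404 DE genes (q < 0.05)
...
6 h: synergy set 132 genes, strict 122 (92% of testable)
  additivity (full, n=132): T=1419.8, df=132, p=1.39e-214
  additivity (induced, n=76): T=925.6, df=76, p=3.41e-146
planted synergistic recovered in strict set: 102/120
6 h synergy genes silent at 12 h: 132/132
```

Reading this: the Venn partition finds 132 genes DE only in the pyramid at
6 h; 122 survive the strict relaxed-cutoff rule, recovering 102 of the 120
planted synergistic genes. Their observed log2FCs reject the additive
expectation decisively (the planted monogenic effects are zero, so
d<sub>exp</sub> ≈ 0 while |d<sub>obs</sub>| ∈ [1, 3]), and the entire
synergy set is silent at 12 h — the transient early response built into
the generator. Scripts 04–07 add clustering (the synergy set splits into
one induced and one repressed cluster), GO/TF-family enrichment, the locus
scan and the homolog-collapsed TF network.

The locus module also ships the published log2 fold-change table for genes
near the *Rag1*/*Rag2* intervals; converting the strongest *Rag1*
candidate's six log2FCs with `locus.logfc_to_fc` gives the familiar fold
changes 5.6–10.4.

## CLI

Every stage is also available as a subcommand:

```bash
ragsynergy simulate --seed 1 --out run/
ragsynergy de --counts run/counts.tsv --samples run/samples.csv \
    --timepoint 6 --contrast R12:aphid-vs-mock --out r12_6h.tsv
ragsynergy pipeline --config config.yaml
```
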