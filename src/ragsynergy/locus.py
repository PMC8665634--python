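"""Candidate-gene discovery at mapped resistance loci.

Given a mapped interval (e.g. the Rag1 locus on soybean chromosome 7,
Gm07:5,531,331-5,769,789), genes overlapping the interval are pulled from
the annotation, summarized across genotype-vs-genotype mock comparisons
(resistant-carrier vs non-carrier at each timepoint), and ranked: a strong
candidate is significant in many comparisons with a consistent direction
(constitutively higher in every genotype carrying the resistance allele).

A reference table of published log2 fold changes for genes near the Rag1
and Rag2 loci ships with the package (``load_reference_locus_table``) as a
worked example for fold-change reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .data_io import GeneAnnotation
from .de import ContrastResult

#: Mapped locus intervals (assembly v2 coordinates, 1-based inclusive).
RAG1_INTERVAL = ("Rag1", "Gm07", 5_531_331, 5_769_789)


@dataclass(frozen=True)
class LocusInterval:
    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.name}: start > end")


@dataclass
class LocusSummary:
    """Per-gene grid of significant log2FCs across the configured
    genotype comparisons, plus consistency and fold-change columns."""

    interval: LocusInterval
    grid: pd.DataFrame  # genes x comparisons; NaN where not significant
    stats: pd.DataFrame  # n_significant, direction, min_fc, max_fc
    alpha: float


def genes_in_interval(annotation: GeneAnnotation, interval: LocusInterval) -> list[str]:
    """Genes whose span overlaps the interval by >= 1 bp, sorted by start.

    Overlap (not containment): gene models straddling mapped boundaries
    should surface for manual review.  Strand is ignored.
    """
    coords = annotation.coords
    if interval.chrom not in set(coords["chrom"]):
        raise ValueError(f"chromosome {interval.chrom!r} not in annotation")
    on_chrom = coords[coords["chrom"] == interval.chrom]
    hit = (on_chrom["start"] <= interval.end) & (on_chrom["end"] >= interval.start)
    return on_chrom.index[hit][np.argsort(on_chrom.loc[hit, "start"].to_numpy(), kind="stable")].tolist()


def locus_de_summary(
    genes: list[str],
    contrasts: dict[str, ContrastResult],
    interval: LocusInterval,
    alpha: float = 0.05,
) -> LocusSummary:
    """Summarize interval genes across genotype-vs-genotype comparisons.

    Cells hold the log2FC where q < alpha and NaN otherwise ("n.s." in the
    human-readable report); genes significant nowhere are excluded.
    """
    if not contrasts:
        raise ValueError("no contrasts supplied")
    grid = pd.DataFrame(index=pd.Index(genes, name="gene"), columns=list(contrasts))
    for name, c in contrasts.items():
        present = [g for g in genes if g in c.table.index]
        sub = c.table.loc[present]
        sig = sub["q"] < alpha
        grid.loc[present, name] = sub["log2FC"].where(sig)
    grid = grid.astype(float)
    keep = grid.notna().any(axis=1)
    grid = grid.loc[keep]

    rows = []
    for g in grid.index:
        vals = grid.loc[g].dropna()
        signs = set(np.sign(vals))
        direction = (
            "up" if signs == {1.0} else "down" if signs == {-1.0} else "mixed"
        )
        rows.append(
            {
                "gene": g,
                "n_significant": len(vals),
                "direction": direction,
                "min_abs_log2fc": float(np.min(np.abs(vals))),
                "min_fc": float(logfc_to_fc(vals.min())),
                "max_fc": float(logfc_to_fc(vals.max())),
            }
        )
    stats = (
        pd.DataFrame(rows).set_index("gene")
        if rows
        else pd.DataFrame(
            columns=["n_significant", "direction", "min_abs_log2fc", "min_fc", "max_fc"]
        )
    )
    return LocusSummary(interval=interval, grid=grid, stats=stats, alpha=alpha)


def rank_candidates(
    summary: LocusSummary, expected_direction: str = "higher_in_resistant"
) -> pd.DataFrame:
    """Rank interval genes as resistance-gene candidates.

    Tier 1: direction-consistent genes in the expected direction (all
    significant log2FCs positive for ``higher_in_resistant``), ordered by
    (number of significant comparisons desc, minimum |log2FC| desc).
    Tier 2: everything else (opposite or mixed signs), same ordering.
    """
    if expected_direction not in {"higher_in_resistant", "lower_in_resistant"}:
        raise ValueError(f"unknown expected_direction {expected_direction!r}")
    want = "up" if expected_direction == "higher_in_resistant" else "down"
    stats = summary.stats
    if stats.empty:
        return stats.assign(tier=pd.Series(dtype=int), rank=pd.Series(dtype=int))
    out = stats.copy()
    out["tier"] = np.where(out["direction"] == want, 1, 2)
    out = out.sort_values(
        ["tier", "n_significant", "min_abs_log2fc"],
        ascending=[True, False, False],
        kind="stable",
    )
    out["rank"] = range(1, len(out) + 1)
    return out


def logfc_to_fc(d):
    """Fold change 2**d; repressed genes have FC < 1, never negative."""
    return np.power(2.0, np.asarray(d, dtype=float))


def format_locus_report(summary: LocusSummary, decimals: int = 1) -> pd.DataFrame:
    """Human-readable grid: log2FC where significant, "n.s." elsewhere."""
    return summary.grid.round(5).astype(object).where(summary.grid.notna(), "n.s.")


def load_reference_locus_table() -> pd.DataFrame:
    """Published log2FC table for genes near the Rag1/Rag2 loci (mock
    genotype comparisons at 6 and 12 h); blanks are non-significant."""
    path = resources.files("ragsynergy.data") / "rag_locus_log2fc.tsv"
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t")
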