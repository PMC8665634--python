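"""Synergy detection: Venn partition of DE sets, strict classification of
pyramid-unique genes, additivity testing and timepoint dynamics.

"Synergistic genes" are those differentially expressed (q < alpha) only in
the pyramid genotype's aphid-vs-mock contrast — in none of the monogenic or
susceptible contrasts at the same timepoint.  The strict subset further
requires both monogenic q-values to clear a relaxed cutoff (q > 0.25), so a
gene marginally regulated in a monogenic line does not count.  Departure
from the additive expectation (pyramid log2FC = sum of the monogenic
log2FCs) is tested in aggregate with a chi-square statistic, for the full
set and for the induced / repressed sign subsets separately.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .de import ContrastResult


@dataclass
class DESetPartition:
    """Exact Venn decomposition of per-genotype DE sets at one timepoint."""

    timepoint: int
    genotype_sets: dict[str, set]  # genotype -> DE genes (q < alpha)
    regions: dict[frozenset, set]  # membership pattern -> genes (disjoint)
    pyramid: str
    alpha: float

    @property
    def synergy_set(self) -> set:
        return set(self.regions.get(frozenset([self.pyramid]), set()))

    def region(self, *genotypes: str) -> set:
        return set(self.regions.get(frozenset(genotypes), set()))

    def to_json_dict(self) -> dict:
        return {
            "&".join(sorted(k)): sorted(v) for k, v in self.regions.items() if v
        }

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "timepoint": int(self.timepoint),
                    "alpha": float(self.alpha),
                    "pyramid": self.pyramid,
                    "regions": self.to_json_dict(),
                },
                fh,
                indent=2,
                sort_keys=True,
            )


def partition_de_sets(
    contrasts: dict[str, ContrastResult],
    alpha: float = 0.05,
    pyramid: str = "R12",
    timepoint: int | None = None,
) -> DESetPartition:
    """Partition per-genotype DE sets into disjoint Venn regions.

    Every gene DE in at least one genotype lands in exactly one region,
    keyed by the frozenset of genotypes in which it is DE.
    """
    universes = [frozenset(c.gene_ids) for c in contrasts.values()]
    if len(set(universes)) != 1:
        raise ValueError("contrasts have mismatched gene universes")
    if pyramid not in contrasts:
        raise ValueError(f"pyramid genotype {pyramid!r} missing from contrasts")

    genotype_sets = {g: c.de_genes(alpha) for g, c in contrasts.items()}
    regions: dict[frozenset, set] = {}
    for gene in set().union(*genotype_sets.values()):
        pattern = frozenset(g for g, s in genotype_sets.items() if gene in s)
        regions.setdefault(pattern, set()).add(gene)
    return DESetPartition(
        timepoint=timepoint if timepoint is not None else -1,
        genotype_sets=genotype_sets,
        regions=regions,
        pyramid=pyramid,
        alpha=alpha,
    )


def classify_synergy_strict(
    q_pyramid: float,
    q_r1: float,
    q_r2: float,
    alpha: float = 0.05,
    relaxed: float = 0.25,
) -> bool | None:
    """Strict synergy: significant in the pyramid, clearly null in both
    monogenic lines (strict inequalities exactly as the thresholds read).

    Returns None ("untestable") when any q is missing.
    """
    if any(q is None or (isinstance(q, float) and np.isnan(q)) for q in (q_pyramid, q_r1, q_r2)):
        return None
    return (q_pyramid < alpha) and (q_r1 > relaxed) and (q_r2 > relaxed)


def additive_expectation(d_r1, d_r2):
    """Expected pyramid log2FC under additivity: d_R1 + d_R2."""
    return np.asarray(d_r1, dtype=float) + np.asarray(d_r2, dtype=float)


def additivity_chisq(
    d_obs,
    d_exp,
    se_obs=None,
    se_r1=None,
    se_r2=None,
    method: str = "standardized",
    bins: int = 20,
) -> tuple[float, int, float]:
    """Aggregate test of observed pyramid log2FCs against additive values.

    standardized
        T = sum (d_obs - d_exp)^2 / (se_obs^2 + se_R1^2 + se_R2^2), df = n,
        upper-tail chi-square.  SEs of the three contrast estimates are
        treated as independent (different samples).
    binned
        Pearson chi-square comparing the histogram of d_obs against the
        histogram of d_exp over ``bins`` shared equal-width bins.

    Returns (T, df, p).
    """
    d_obs = np.asarray(d_obs, dtype=float)
    d_exp = np.asarray(d_exp, dtype=float)
    if d_obs.size == 0:
        raise ValueError("empty subset")
    if method == "standardized":
        se_obs = np.asarray(se_obs, dtype=float)
        se_r1 = np.asarray(se_r1, dtype=float)
        se_r2 = np.asarray(se_r2, dtype=float)
        if np.any(se_obs <= 0) or np.any(se_r1 <= 0) or np.any(se_r2 <= 0):
            raise ValueError("standard errors must be > 0")
        var = se_obs**2 + se_r1**2 + se_r2**2
        t = float(np.sum((d_obs - d_exp) ** 2 / var))
        df = int(d_obs.size)
    elif method == "binned":
        lo = min(d_obs.min(), d_exp.min())
        hi = max(d_obs.max(), d_exp.max())
        if hi == lo:
            hi = lo + 1e-9
        edges = np.linspace(lo, hi, bins + 1)
        obs_h, _ = np.histogram(d_obs, bins=edges)
        exp_h, _ = np.histogram(d_exp, bins=edges)
        ok = exp_h > 0
        expected = exp_h[ok] * obs_h.sum() / exp_h[ok].sum()
        t = float(np.sum((obs_h[ok] - expected) ** 2 / expected))
        df = int(ok.sum() - 1)
        if df < 1:
            raise ValueError("binned test needs >= 2 occupied expected bins")
    else:
        raise ValueError(f"unknown method {method!r}")
    p = float(stats.chi2.sf(t, df))
    return t, df, p


@dataclass
class SynergyReport:
    """Per-gene synergy table plus aggregate additivity statistics."""

    timepoint: int
    table: pd.DataFrame  # per synergy gene
    aggregate: pd.DataFrame  # rows full/induced/repressed: T, df, p, n
    alpha: float
    relaxed: float
    chisq_method: str

    @property
    def strict_set(self) -> set:
        return set(self.table.index[self.table["strict"] == True])  # noqa: E712

    @property
    def n_strict(self) -> int:
        return len(self.strict_set)

    @property
    def strict_fraction(self) -> float:
        testable = self.table["strict"].notna().sum()
        return self.n_strict / testable if testable else float("nan")

    def write(self, path) -> None:
        self.table.rename_axis("gene").to_csv(path, sep="\t")

    def write_aggregate(self, path) -> None:
        self.aggregate.rename_axis("subset").to_csv(path, sep="\t")


def synergy_report(
    partition: DESetPartition,
    contrasts: dict[str, ContrastResult],
    r1: str = "R1",
    r2: str = "R2",
    alpha: float = 0.05,
    relaxed: float = 0.25,
    chisq_method: str = "standardized",
) -> SynergyReport:
    """Classify the synergy set and run the aggregate additivity tests.

    Genes with observed log2FC exactly 0 belong to neither sign subset and
    are flagged in the ``sign`` column.
    """
    pyramid = partition.pyramid
    genes = sorted(partition.synergy_set)
    t_pyr = contrasts[pyramid].table
    t_r1 = contrasts[r1].table
    t_r2 = contrasts[r2].table

    rows = []
    for g in genes:
        d_obs = t_pyr.at[g, "log2FC"]
        d1, d2 = t_r1.at[g, "log2FC"], t_r2.at[g, "log2FC"]
        d_exp = d1 + d2
        var = t_pyr.at[g, "se"] ** 2 + t_r1.at[g, "se"] ** 2 + t_r2.at[g, "se"] ** 2
        rows.append(
            {
                "gene": g,
                "q_pyramid": t_pyr.at[g, "q"],
                "q_r1": t_r1.at[g, "q"],
                "q_r2": t_r2.at[g, "q"],
                "strict": classify_synergy_strict(
                    t_pyr.at[g, "q"], t_r1.at[g, "q"], t_r2.at[g, "q"], alpha, relaxed
                ),
                "d_obs": d_obs,
                "d_exp": d_exp,
                "std_dev": (d_obs - d_exp) / np.sqrt(var) if var > 0 else np.nan,
                "se_obs": t_pyr.at[g, "se"],
                "se_r1": t_r1.at[g, "se"],
                "se_r2": t_r2.at[g, "se"],
                "sign": "induced" if d_obs > 0 else ("repressed" if d_obs < 0 else "zero"),
            }
        )
    table = (
        pd.DataFrame(rows).set_index("gene")
        if rows
        else pd.DataFrame(
            columns=[
                "q_pyramid", "q_r1", "q_r2", "strict", "d_obs", "d_exp",
                "std_dev", "se_obs", "se_r1", "se_r2", "sign",
            ]
        )
    )

    agg_rows = []
    subsets = {
        "full": table.index if len(table) else pd.Index([]),
        "induced": table.index[table["sign"] == "induced"] if len(table) else pd.Index([]),
        "repressed": table.index[table["sign"] == "repressed"] if len(table) else pd.Index([]),
    }
    for name, idx in subsets.items():
        if len(idx) == 0:
            agg_rows.append({"subset": name, "T": np.nan, "df": 0, "p": np.nan, "n": 0})
            continue
        sub = table.loc[idx]
        t, df, p = additivity_chisq(
            sub["d_obs"], sub["d_exp"], sub["se_obs"], sub["se_r1"], sub["se_r2"],
            method=chisq_method,
        )
        agg_rows.append({"subset": name, "T": t, "df": df, "p": p, "n": len(idx)})
    aggregate = pd.DataFrame(agg_rows).set_index("subset")

    return SynergyReport(
        timepoint=partition.timepoint,
        table=table,
        aggregate=aggregate,
        alpha=alpha,
        relaxed=relaxed,
        chisq_method=chisq_method,
    )


@dataclass
class DynamicsSummary:
    """Overlap of DE sets between two timepoints, per genotype."""

    per_genotype: pd.DataFrame  # n_t1, n_t2, n_overlap, overlap_fraction
    gene_concordance: pd.DataFrame  # genotype, gene, direction in {same, opposite}
    synergy_silent_at_t2: int  # t1 synergy genes not DE anywhere at t2
    synergy_set_size: int

    def write(self, path) -> None:
        self.per_genotype.rename_axis("genotype").to_csv(path, sep="\t")


def timepoint_overlap(
    partition_t1: DESetPartition,
    partition_t2: DESetPartition,
    contrasts_t1: dict[str, ContrastResult],
    contrasts_t2: dict[str, ContrastResult],
) -> DynamicsSummary:
    """Quantify how transient each genotype's response is across timepoints.

    Overlapping genes are labeled same/opposite by the sign of their log2FC
    at each timepoint; also reports how many early synergy genes are not DE
    in any genotype at the later timepoint.
    """
    rows, conc = [], []
    for g, s1 in partition_t1.genotype_sets.items():
        s2 = partition_t2.genotype_sets.get(g, set())
        overlap = s1 & s2
        denom = len(s1 | s2)
        rows.append(
            {
                "genotype": g,
                "n_t1": len(s1),
                "n_t2": len(s2),
                "n_overlap": len(overlap),
                "overlap_fraction": len(overlap) / denom if denom else 0.0,
            }
        )
        t1, t2 = contrasts_t1[g].table, contrasts_t2[g].table
        for gene in sorted(overlap):
            same = np.sign(t1.at[gene, "log2FC"]) == np.sign(t2.at[gene, "log2FC"])
            conc.append(
                {"genotype": g, "gene": gene, "direction": "same" if same else "opposite"}
            )

    de_anywhere_t2 = set().union(*partition_t2.genotype_sets.values()) if partition_t2.genotype_sets else set()
    synergy_t1 = partition_t1.synergy_set
    silent = len(synergy_t1 - de_anywhere_t2)

    return DynamicsSummary(
        per_genotype=pd.DataFrame(rows).set_index("genotype"),
        gene_concordance=pd.DataFrame(conc, columns=["genotype", "gene", "direction"]),
        synergy_silent_at_t2=silent,
        synergy_set_size=len(synergy_t1),
    )
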