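"""Overrepresentation tests: GO biological-process terms and TF families.

One-sided Fisher (hypergeometric upper tail) against an annotated
background, Bonferroni-corrected over the tested terms; plus the TF-family
synergy-share rule that flags families where at least half of the TFs DE in
the pyramid are synergistic genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .de import ContrastResult


def invert_gene_map(gene_to_terms: dict[str, set]) -> dict[str, set]:
    term_to_genes: dict[str, set] = {}
    for gene, terms in gene_to_terms.items():
        for t in terms:
            term_to_genes.setdefault(t, set()).add(gene)
    return term_to_genes


def fisher_enrichment(
    de_set: set,
    term_to_genes: dict[str, set],
    background: set,
    alpha: float = 0.05,
    bonferroni_all_terms: bool = False,
    contrast: ContrastResult | None = None,
    descriptions: dict[str, str] | None = None,
) -> pd.DataFrame:
    """One-sided overrepresentation test per term with Bonferroni control.

    p = P[X >= k], X ~ Hypergeom(N=|background|, K=|term genes|, n=|DE|).
    Only terms hitting >= 1 DE gene are reported; by default the Bonferroni
    multiplier m counts those tested terms (``bonferroni_all_terms`` uses
    every background term instead).  When a ContrastResult is supplied the
    DE genes per term are split into induced / repressed by log2FC sign.
    """
    offenders = de_set - background
    if offenders:
        raise ValueError(f"DE genes outside the background: {sorted(offenders)[:5]}")
    n_bg = len(background)
    n_de = len(de_set)

    rows = []
    tested = []
    for term, genes in sorted(term_to_genes.items()):
        genes_bg = genes & background
        k = len(genes_bg & de_set)
        if k == 0:
            continue
        tested.append(term)
        big_k = len(genes_bg)
        p = float(stats.hypergeom.sf(k - 1, n_bg, big_k, n_de))
        # odds ratio of the 2x2 table (Haldane 0.5 correction on zeros)
        a, b = k, n_de - k
        c, d = big_k - k, n_bg - big_k - (n_de - k)
        if min(a, b, c, d) == 0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        row = {
            "term": term,
            "description": (descriptions or {}).get(term, ""),
            "k_de_with_term": k,
            "K_background_with_term": big_k,
            "n_de": n_de,
            "N_background": n_bg,
            "odds_ratio": (a * d) / (b * c),
            "p": p,
        }
        if contrast is not None:
            fc = contrast.table["log2FC"]
            hits = sorted(genes_bg & de_set)
            row["induced"] = int((fc.loc[hits] > 0).sum())
            row["repressed"] = int((fc.loc[hits] < 0).sum())
        rows.append(row)

    out = pd.DataFrame(rows)
    if out.empty:
        return out
    m = len(term_to_genes) if bonferroni_all_terms else len(tested)
    out["p_bonferroni"] = np.minimum(1.0, out["p"] * m)
    out["significant"] = out["p_bonferroni"] <= alpha
    return out.sort_values(["p_bonferroni", "term"]).set_index("term")


def tf_family_synergy_share(
    pyramid_de_tfs: set,
    tf_family: dict[str, str],
    synergy_set: set,
    flag_threshold: float = 0.5,
) -> pd.DataFrame:
    """Per-family share of pyramid-DE TFs that are synergistic genes.

    TFs without a family label are grouped under "unknown".  A family is
    flagged when its share is >= ``flag_threshold`` (inclusive: "50% or
    more"); flags are computed on exact fractions, rounding is for display
    only.
    """
    rows: dict[str, dict] = {}
    for tf in sorted(pyramid_de_tfs):
        fam = tf_family.get(tf, "unknown")
        entry = rows.setdefault(fam, {"n_pyramid_de": 0, "n_synergistic": 0})
        entry["n_pyramid_de"] += 1
        if tf in synergy_set:
            entry["n_synergistic"] += 1
    out = pd.DataFrame(
        [
            {
                "family": fam,
                "n_pyramid_de": v["n_pyramid_de"],
                "n_synergistic": v["n_synergistic"],
                "share": v["n_synergistic"] / v["n_pyramid_de"],
            }
            for fam, v in sorted(rows.items())
        ]
    )
    if out.empty:
        return pd.DataFrame(
            columns=["n_pyramid_de", "n_synergistic", "share", "flagged"]
        )
    out["flagged"] = out["share"] >= flag_threshold
    return out.sort_values(["share", "family"], ascending=[False, True]).set_index(
        "family"
    )
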