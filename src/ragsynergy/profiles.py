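"""Expression-profile clustering of DE genes across contrasts.

Each gene's log2 fold changes across the aphid-vs-mock contrasts are
z-scored within the gene and genes are clustered with complete linkage on
the Pearson-correlation distance 1 - r.  Rows are pre-sorted by gene ID so
the agglomeration is deterministic and invariant to input row order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .de import ContrastResult


@dataclass
class ProfileMatrix:
    """Genes x contrasts z-scored log2FC matrix.

    Non-constant rows have mean 0 and sample SD 1 (ddof=1); constant rows
    are kept as all-zero and flagged.
    """

    values: pd.DataFrame
    constant: pd.Series  # bool per gene

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index


def zscore_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    arr = df.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    constant = sd[:, 0] <= 1e-12
    z = np.zeros_like(arr)
    ok = ~constant
    z[ok] = (arr[ok] - mean[ok]) / sd[ok]
    return (
        pd.DataFrame(z, index=df.index, columns=df.columns),
        pd.Series(constant, index=df.index, name="constant"),
    )


def build_profile_matrix(
    contrasts: dict[str, ContrastResult],
    alpha: float = 0.05,
    de_universe: set | None = None,
) -> ProfileMatrix:
    """Rows = genes DE (q < alpha) in >= 1 contrast (or a supplied set),
    columns = contrasts, values = per-row z-scored log2FC."""
    universes = {frozenset(c.gene_ids) for c in contrasts.values()}
    if len(universes) != 1:
        raise ValueError("contrasts have mismatched gene universes")
    if de_universe is None:
        de_universe = set()
        for c in contrasts.values():
            de_universe |= c.de_genes(alpha)
    genes = sorted(de_universe)
    missing = set(genes) - set(next(iter(universes)))
    if missing:
        raise ValueError(f"genes outside the contrast universe: {sorted(missing)[:5]}")
    fc = pd.DataFrame(
        {name: c.table.loc[genes, "log2FC"] for name, c in contrasts.items()}
    )
    values, constant = zscore_rows(fc)
    return ProfileMatrix(values=values, constant=constant)


@dataclass
class ClusterResult:
    linkage: np.ndarray  # scipy linkage matrix over sorted non-constant rows
    gene_ids: pd.Index  # leaves, in the sorted order used for clustering
    dropped: list  # constant rows excluded from clustering


def hier_cluster(profile: ProfileMatrix, constant_rows: str = "drop") -> ClusterResult:
    """Complete-linkage agglomeration on 1 - Pearson r between gene rows.

    ``constant_rows``: "drop" excludes flagged all-zero rows (correlation is
    undefined for them) with a warning; "error" raises.
    """
    const = profile.constant
    if const.any():
        if constant_rows == "error":
            raise ValueError(
                f"constant rows present: {profile.values.index[const].tolist()[:5]}"
            )
        warnings.warn(
            f"dropping {int(const.sum())} constant row(s) before clustering",
            stacklevel=2,
        )
    keep = profile.values.index[~const]
    # lexicographic row order makes scipy's tie-breaking deterministic and
    # input-order independent
    keep = pd.Index(sorted(keep))
    if len(keep) < 2:
        raise ValueError("clustering needs >= 2 non-constant rows")
    data = profile.values.loc[keep].to_numpy(dtype=float)
    dist = pdist(data, metric="correlation")  # exactly 1 - Pearson r
    dist = np.clip(dist, 0.0, None)  # guard tiny negative rounding
    z = hierarchy.linkage(dist, method="complete")
    return ClusterResult(
        linkage=z, gene_ids=keep, dropped=profile.values.index[const].tolist()
    )


def cut_clusters(result: ClusterResult, k: int) -> pd.Series:
    """Cut the tree into exactly k clusters (first n-k merges applied).

    Labels are 1..k, numbered by the order of each cluster's first member
    in the leaf ordering.
    """
    n = len(result.gene_ids)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    parent = list(range(2 * n - 1))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n - k):
        a, b = int(result.linkage[i, 0]), int(result.linkage[i, 1])
        new = n + i
        parent[find(a)] = new
        parent[find(b)] = new

    roots: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for leaf in range(n):
        r = find(leaf)
        if r not in roots:
            roots[r] = len(roots) + 1
        labels[leaf] = roots[r]
    return pd.Series(labels, index=result.gene_ids, name="cluster")


def leaf_order(result: ClusterResult) -> list:
    order = hierarchy.leaves_list(result.linkage)
    return [result.gene_ids[i] for i in order]


def to_newick(result: ClusterResult) -> str:
    """Dendrogram as Newick; branch lengths are merge-height differences."""
    n = len(result.gene_ids)
    heights = {i: 0.0 for i in range(n)}
    reps: dict[int, str] = {i: str(result.gene_ids[i]) for i in range(n)}
    for i, (a, b, h, _) in enumerate(result.linkage):
        a, b = int(a), int(b)
        la = max(h - heights[a], 0.0)
        lb = max(h - heights[b], 0.0)
        node = n + i
        reps[node] = f"({reps[a]}:{la:.6g},{reps[b]}:{lb:.6g})"
        heights[node] = h
    return reps[2 * n - 2] + ";"


def plot_heatmap(profile: ProfileMatrix, result: ClusterResult, path) -> None:
    """Diverging heatmap of the profile matrix, rows in dendrogram order."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = leaf_order(result)
    data = profile.values.loc[order]
    fig, ax = plt.subplots(figsize=(6, max(3, len(order) * 0.02)))
    vmax = max(abs(float(data.to_numpy().min())), abs(float(data.to_numpy().max())), 1e-9)
    im = ax.imshow(data.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(data.shape[1]))
    ax.set_xticklabels(data.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    ax.set_ylabel(f"{data.shape[0]} genes")
    fig.colorbar(im, ax=ax, label="z-scored log2FC")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
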