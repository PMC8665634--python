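"""Filtering, TMM normalization, dispersion estimation and per-contrast
negative-binomial differential expression with BH FDR control.

The workflow mirrors the standard count-based DE recipe for this kind of
factorial design: genes with CPM < 1 are dropped, samples are normalized
with trimmed-mean-of-M-values (TMM) factors within each timepoint, a
per-gene NB dispersion phi (variance = mu + phi * mu**2) is estimated by a
pooled method of moments with shrinkage toward the common value, and each
two-group contrast is tested with an exact conditional NB test on
depth-equalized pseudo-counts (Wald fallback at large totals).  Positive
log2 fold changes mean higher expression in the first-named group (aphid,
for aphid-vs-mock contrasts: induced by aphids).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from .data_io import CountMatrix

PHI_FLOOR = 1e-6


@dataclass
class NormalizedCounts:
    matrix: CountMatrix
    factors: pd.Series  # TMM factor per sample, geometric mean 1
    effective_lib_sizes: pd.Series  # library_size * factor

    @property
    def cpm(self) -> pd.DataFrame:
        return cpm(self.matrix.counts, self.effective_lib_sizes)


@dataclass
class DispersionEstimates:
    tagwise: pd.Series  # per-gene phi, floored at PHI_FLOOR
    common: float
    prior_df: float
    residual_df: pd.Series | None = None  # per-gene pooled within-group df

    def variance_df(self) -> pd.Series | None:
        """Nominal df behind each tagwise estimate (residual + prior)."""
        if self.residual_df is None:
            return None
        return self.residual_df + self.prior_df


@dataclass
class ContrastResult:
    """One named two-group contrast: per-gene log2FC, SE, p and BH q."""

    name: str
    table: pd.DataFrame  # gene-indexed: log2FC, se, p, q, mean_cpm, method

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    def de_genes(self, alpha: float = 0.05) -> set:
        return set(self.table.index[self.table["q"] < alpha])

    def write(self, path) -> None:
        self.table.rename_axis("gene").to_csv(path, sep="\t")

    @classmethod
    def read(cls, path, name: str | None = None) -> "ContrastResult":
        table = pd.read_csv(path, sep="\t", index_col="gene")
        return cls(name=name or str(path), table=table)


def cpm(counts: pd.DataFrame, effective_lib_sizes: pd.Series) -> pd.DataFrame:
    """Counts per million against the given (effective) library sizes."""
    libs = effective_lib_sizes.loc[counts.columns].astype(float)
    if (libs <= 0).any():
        raise ValueError("effective library sizes must be > 0")
    return counts.div(libs, axis=1) * 1e6


def filter_low_expression(
    matrix: CountMatrix, cpm_threshold: float = 1.0, min_samples: int | None = None
) -> CountMatrix:
    """Keep genes with CPM >= threshold in at least ``min_samples`` samples.

    CPM is computed on raw column sums (filtering precedes normalization)
    and library sizes are *not* recomputed afterwards.  ``min_samples``
    defaults to the smallest (genotype, treatment, timepoint) group size:
    a DE gene must be expressed in at least one full group.
    """
    if min_samples is None:
        min_samples = int(matrix.group_key().value_counts().min())
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    mat_cpm = cpm(matrix.counts, matrix.library_sizes)
    keep = (mat_cpm >= cpm_threshold).sum(axis=1) >= min_samples
    if not keep.any():
        warnings.warn("low-expression filter removed every gene", stacklevel=2)
    return matrix.subset_genes(matrix.gene_ids[keep])


def _upper_quartile_ref(counts: np.ndarray, libs: np.ndarray) -> int:
    """Reference sample: 75th-percentile CPM closest to the mean of those."""
    uq = np.percentile(counts / libs[None, :] * 1e6, 75, axis=0)
    return int(np.argmin(np.abs(uq - uq.mean())))


def tmm_factors(
    matrix: CountMatrix,
    ref_sample: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Trimmed mean of M-values normalization factors (Robinson-Oshlack).

    For each sample against the reference, genes with a zero count in
    either sample are excluded; M- and A-values are double-trimmed
    (``trim_m`` on each M tail, ``trim_a`` on each A tail) and the factor is
    2**(weighted mean M) with inverse-variance (binomial delta-method)
    weights.  Factors are rescaled to geometric mean 1.
    """
    counts = matrix.counts.to_numpy(dtype=float)
    libs = matrix.library_sizes.to_numpy(dtype=float)
    n_samples = counts.shape[1]
    if n_samples < 2:
        raise ValueError("TMM requires >= 2 samples")

    if ref_sample is None:
        ref_idx = _upper_quartile_ref(counts, libs)
    else:
        ref_idx = matrix.counts.columns.get_loc(ref_sample)
    y_r, n_r = counts[:, ref_idx], libs[ref_idx]

    log_factors = np.zeros(n_samples)
    for k in range(n_samples):
        if k == ref_idx:
            continue
        y_k, n_k = counts[:, k], libs[k]
        ok = (y_k > 0) & (y_r > 0)
        if not ok.any():
            raise ValueError(
                f"no shared nonzero genes between {matrix.counts.columns[k]} "
                "and the TMM reference"
            )
        pk, pr = y_k[ok] / n_k, y_r[ok] / n_r
        m = np.log2(pk / pr)
        a = 0.5 * np.log2(pk * pr)
        w = (n_k - y_k[ok]) / (n_k * y_k[ok]) + (n_r - y_r[ok]) / (n_r * y_r[ok])

        n = m.size
        lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
        lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
        rank_m = stats.rankdata(m)
        rank_a = stats.rankdata(a)
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if keep.any() and w[keep].sum() > 0:
            f = np.sum(w[keep] * m[keep]) / np.sum(w[keep])
        else:
            f = 0.0
        if not np.isfinite(f):
            f = 0.0
        log_factors[k] = f

    log_factors -= log_factors.mean()  # geometric mean 1
    return pd.Series(2.0 ** log_factors, index=matrix.counts.columns, name="tmm")


def normalize(matrix: CountMatrix, **tmm_kwargs) -> NormalizedCounts:
    factors = tmm_factors(matrix, **tmm_kwargs)
    eff = matrix.library_sizes * factors
    return NormalizedCounts(matrix=matrix, factors=factors, effective_lib_sizes=eff)


def _pseudo_counts(counts: np.ndarray, eff_libs: np.ndarray) -> tuple[np.ndarray, float]:
    """Scale every sample's counts to the geometric-mean effective depth."""
    lib_ref = float(np.exp(np.mean(np.log(eff_libs))))
    return counts * (lib_ref / eff_libs)[None, :], lib_ref


def estimate_dispersion(
    matrix: CountMatrix,
    norm: NormalizedCounts,
    prior_df: float = 10.0,
) -> DispersionEstimates:
    """Pooled method-of-moments NB dispersion with shrinkage.

    Counts are first equalized to a common depth; within each replicate
    group (genotype, treatment, timepoint cell) the moment estimate
    (var - mean) / (mean**2 - var/n) is formed and pooled across groups
    with residual-df weights.  The denominator is the unbiased moment
    estimate of mu**2 (the naive mean**2 overestimates mu**2 by var(mean),
    biasing phi low and the resulting tests liberal).  The common
    dispersion pools numerator and denominator separately over all genes
    and groups (ratio of sums), which avoids the upward Jensen bias of
    averaging per-gene ratios; it is floored at 0.  Tagwise values shrink the
    (clipped) gene estimate toward it with weights df : prior_df and are
    floored at ``PHI_FLOOR``.
    """
    groups = matrix.group_key()
    group_sizes = groups.value_counts()
    if (group_sizes < 2).all():
        raise ValueError("dispersion estimation needs >= 2 replicates in some group")

    pseudo, _ = _pseudo_counts(
        matrix.counts.to_numpy(dtype=float),
        norm.effective_lib_sizes.to_numpy(dtype=float),
    )
    n_genes = pseudo.shape[0]
    num = np.zeros(n_genes)
    df_tot = np.zeros(n_genes)
    glob_num = 0.0
    glob_den = 0.0
    for label in group_sizes.index[group_sizes >= 2]:
        cols = np.flatnonzero((groups == label).to_numpy())
        sub = pseudo[:, cols]
        n_i = len(cols)
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        ok = m > 1e-8
        denom = np.maximum(m**2 - v / n_i, 0.1 * m**2)  # keep denominator positive
        phi_i = np.zeros(n_genes)
        phi_i[ok] = (v[ok] - m[ok]) / denom[ok]
        df = n_i - 1
        num += np.where(ok, df * phi_i, 0.0)
        df_tot += np.where(ok, df, 0.0)
        glob_num += float(np.sum(df * (v[ok] - m[ok])))
        glob_den += float(np.sum(df * denom[ok]))

    raw = np.full(n_genes, np.nan)
    has_df = df_tot > 0
    raw[has_df] = num[has_df] / df_tot[has_df]
    gene_est = np.clip(np.nan_to_num(raw, nan=0.0), 0.0, None)

    common = max(glob_num / glob_den, 0.0) if glob_den > 0 else 0.0

    tagwise = (df_tot * gene_est + prior_df * common) / (df_tot + prior_df)
    tagwise = np.maximum(tagwise, PHI_FLOOR)
    return DispersionEstimates(
        tagwise=pd.Series(tagwise, index=matrix.gene_ids, name="phi"),
        common=common,
        prior_df=prior_df,
        residual_df=pd.Series(df_tot, index=matrix.gene_ids, name="residual_df"),
    )


def _exact_nb_pvalue(
    t_a: int, t_b: int, n_a: int, n_b: int, phi: float
) -> float:
    """Two-sided exact conditional p for a split of the pooled total.

    Group totals are NB with means n_i * mu0 and dispersion phi / n_i
    (sum of n_i iid NB(mu0, phi)); conditioning on the total, the p-value
    sums the probabilities of all splits no more likely than the observed
    one.  At phi = 0 this is the binomial split test.
    """
    total = t_a + t_b
    if total == 0:
        return 1.0
    k = np.arange(total + 1)
    if phi < 1e-12:
        logp = stats.binom.logpmf(k, total, n_a / (n_a + n_b))
    else:
        mu0 = total / (n_a + n_b)
        r_a, r_b = n_a / phi, n_b / phi
        p_a = r_a / (r_a + n_a * mu0)
        p_b = r_b / (r_b + n_b * mu0)
        logp = stats.nbinom.logpmf(k, r_a, p_a) + stats.nbinom.logpmf(
            total - k, r_b, p_b
        )
    log_norm = logsumexp(logp)
    log_obs = logp[t_a]
    # ties included: probability <= observed (small relative tolerance)
    reject = logp <= log_obs + 1e-10
    return float(min(1.0, np.exp(logsumexp(logp[reject]) - log_norm)))


def nb_exact_test(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    phi: np.ndarray,
    eff_libs_a: np.ndarray,
    eff_libs_b: np.ndarray,
    prior_count: float = 0.5,
    big_total: int = 10_000,
    var_df=None,
) -> pd.DataFrame:
    """Vector of exact NB tests for one contrast.

    Parameters are per-gene arrays (counts: genes x samples).  Counts are
    scaled to the geometric-mean effective depth ("pseudo-counts") so both
    groups share a common library size; the log2FC uses prior-stabilized
    mean pseudo-CPM (prior in CPM units), and the SE comes from the NB
    delta method on the log scale.  Totals above ``big_total`` switch to a
    Wald z-test (method column records which path was taken).

    ``var_df`` (per-gene, optional): nominal df behind the plug-in
    dispersion.  When given, the reported SE is inflated by
    sqrt(df / (df - 2)), the t-like correction for squaring a deviation
    against an estimated variance; the p-values are unaffected.
    """
    counts_a = np.asarray(counts_a, dtype=float)
    counts_b = np.asarray(counts_b, dtype=float)
    if (counts_a < 0).any() or (counts_b < 0).any():
        raise ValueError("negative counts")
    n_a, n_b = counts_a.shape[1], counts_b.shape[1]
    if min(n_a, n_b) < 1:
        raise ValueError("empty group")
    if min(n_a, n_b) < 2:
        warnings.warn("a contrast group has a single sample", stacklevel=2)

    all_libs = np.concatenate([eff_libs_a, eff_libs_b]).astype(float)
    lib_ref = float(np.exp(np.mean(np.log(all_libs))))
    pseudo_a = counts_a * (lib_ref / np.asarray(eff_libs_a, float))[None, :]
    pseudo_b = counts_b * (lib_ref / np.asarray(eff_libs_b, float))[None, :]

    mean_a = pseudo_a.mean(axis=1)
    mean_b = pseudo_b.mean(axis=1)
    cpm_a = mean_a / lib_ref * 1e6
    cpm_b = mean_b / lib_ref * 1e6
    d = np.log2((cpm_a + prior_count) / (cpm_b + prior_count))

    # delta method: var(log mean) ~ (1/mu + phi) / n, prior-stabilized means
    prior_counts_scale = prior_count * lib_ref / 1e6
    mu_a = mean_a + prior_counts_scale
    mu_b = mean_b + prior_counts_scale
    var_ln = (1.0 / mu_a + phi) / n_a + (1.0 / mu_b + phi) / n_b
    se = np.sqrt(var_ln) / np.log(2.0)
    if var_df is not None:
        k = np.asarray(var_df, dtype=float)
        se = se * np.sqrt(np.where(k > 2, k / (k - 2), 1.0))

    t_a = np.rint(pseudo_a.sum(axis=1)).astype(np.int64)
    t_b = np.rint(pseudo_b.sum(axis=1)).astype(np.int64)
    totals = t_a + t_b

    p = np.ones(len(d))
    method = np.where(totals > big_total, "wald", "exact")
    exact_idx = np.flatnonzero(totals <= big_total)
    for g in exact_idx:
        p[g] = _exact_nb_pvalue(int(t_a[g]), int(t_b[g]), n_a, n_b, float(phi[g]))
    wald_idx = np.flatnonzero(totals > big_total)
    if wald_idx.size:
        z = np.log(mu_a[wald_idx] / mu_b[wald_idx]) / np.sqrt(var_ln[wald_idx])
        p[wald_idx] = 2.0 * stats.norm.sf(np.abs(z))

    return pd.DataFrame(
        {
            "log2FC": d,
            "se": se,
            "p": np.clip(p, 0.0, 1.0),
            "mean_cpm": (cpm_a * n_a + cpm_b * n_b) / (n_a + n_b),
            "method": method,
        }
    )


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def contrast_masks(
    samples: pd.DataFrame,
    timepoint: int,
    genotype_a: str,
    treatment_a: str,
    genotype_b: str,
    treatment_b: str,
) -> tuple[pd.Series, pd.Series]:
    tp = samples["timepoint"] == timepoint
    a = tp & (samples["genotype"] == genotype_a) & (samples["treatment"] == treatment_a)
    b = tp & (samples["genotype"] == genotype_b) & (samples["treatment"] == treatment_b)
    if (a & b).any():
        raise ValueError("contrast groups overlap")
    return a, b


def run_contrast(
    matrix: CountMatrix,
    norm: NormalizedCounts,
    dispersions: DispersionEstimates,
    mask_a: pd.Series,
    mask_b: pd.Series,
    name: str,
    prior_count: float = 0.5,
) -> ContrastResult:
    """Exact NB test over all genes for one two-group contrast + BH FDR."""
    cols_a = matrix.samples.index[mask_a.loc[matrix.samples.index]]
    cols_b = matrix.samples.index[mask_b.loc[matrix.samples.index]]
    if len(cols_a) == 0 or len(cols_b) == 0:
        raise ValueError(f"contrast {name!r} has an empty group")
    var_df = dispersions.variance_df()
    table = nb_exact_test(
        matrix.counts[cols_a].to_numpy(),
        matrix.counts[cols_b].to_numpy(),
        dispersions.tagwise.to_numpy(),
        norm.effective_lib_sizes.loc[cols_a].to_numpy(),
        norm.effective_lib_sizes.loc[cols_b].to_numpy(),
        prior_count=prior_count,
        var_df=None if var_df is None else var_df.to_numpy(),
    )
    table.index = matrix.gene_ids
    table["q"] = bh_fdr(table["p"].to_numpy())
    table = table[["log2FC", "se", "p", "q", "mean_cpm", "method"]]
    return ContrastResult(name=name, table=table)


def timepoint_workflow(
    matrix: CountMatrix,
    timepoint: int,
    cpm_threshold: float = 1.0,
    min_samples: int | None = None,
    prior_df: float = 10.0,
):
    """Filter + normalize + estimate dispersion within one timepoint.

    Normalization and filtering are done independently per timepoint,
    matching the per-timepoint design of the analysis.
    """
    sub = matrix.subset_samples(matrix.samples["timepoint"] == timepoint)
    filtered = filter_low_expression(sub, cpm_threshold, min_samples)
    norm = normalize(filtered)
    disp = estimate_dispersion(filtered, norm, prior_df=prior_df)
    return filtered, norm, disp


def aphid_vs_mock(
    filtered: CountMatrix,
    norm: NormalizedCounts,
    disp: DispersionEstimates,
    genotype: str,
    timepoint: int,
) -> ContrastResult:
    a, b = contrast_masks(
        filtered.samples, timepoint, genotype, "aphid", genotype, "mock"
    )
    return run_contrast(
        filtered, norm, disp, a, b, f"{genotype}:{timepoint}h:aphid-vs-mock"
    )


def genotype_vs_genotype_mock(
    filtered: CountMatrix,
    norm: NormalizedCounts,
    disp: DispersionEstimates,
    genotype_a: str,
    genotype_b: str,
    timepoint: int,
) -> ContrastResult:
    a, b = contrast_masks(
        filtered.samples, timepoint, genotype_a, "mock", genotype_b, "mock"
    )
    return run_contrast(
        filtered, norm, disp, a, b, f"{genotype_a}-vs-{genotype_b}:{timepoint}h:mock"
    )
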