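"""Synthetic count experiments with planted effect classes.

Emulates a factorial aphid-infestation design: 4 near-isogenic genotypes
(susceptible S, monogenic R1 and R2, pyramid R12) x 2 treatments
(mock, aphid) x 2 timepoints (6 h, 12 h) x 3 replicates = 48 libraries.
Counts are negative binomial with variance mu + phi * mu**2 (phi is "the
dispersion" throughout this package); sequencing depths are lognormal.

Planted per-gene effect classes (aphid-vs-mock log2 fold changes):

==============  ==========================================================
null            no treatment effect in any genotype
shared_all      the same effect in all four genotypes (basal response)
r1_only         effect only in the R1 genotype
r2_only         effect only in the R2 genotype
additive        independent effects in R1 and R2; pyramid effect is their
                sum (the additive expectation)
synergistic     effect only in the pyramid; monogenic effects are zero
                (optionally sub-threshold, see ``monogenic_subthreshold``)
==============  ==========================================================

By default effects are planted at 6 h only, mimicking the transient early
pyramid response in which most synergy genes are silent at 12 h.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_io import CountMatrix

CLASS_ORDER = ("null", "shared_all", "r1_only", "r2_only", "additive", "synergistic")

DEFAULT_PROPORTIONS = {
    "null": 0.84,
    "shared_all": 0.04,
    "r1_only": 0.03,
    "r2_only": 0.03,
    "additive": 0.03,
    "synergistic": 0.03,
}


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class DesignSpec:
    """Factorial experiment layout and depth model.

    ``replicate_overrides`` maps (genotype, treatment, timepoint) cells to a
    replicate count, supporting unbalanced designs such as dropping one mock
    and one aphid pyramid library at 6 h (leaving two replicates).
    """

    genotypes: tuple[str, ...] = ("S", "R1", "R2", "R12")
    treatments: tuple[str, ...] = ("mock", "aphid")
    timepoints: tuple[int, ...] = (6, 12)
    replicates_per_cell: int = 3
    replicate_overrides: dict = field(default_factory=dict)
    library_size_log_mean: float = 16.8  # exp(16.8) ~ 2e7 reads
    library_size_log_sd: float = 0.2
    seed: int = 0

    def n_replicates(self, genotype: str, treatment: str, timepoint: int) -> int:
        n = self.replicate_overrides.get(
            (genotype, treatment, timepoint), self.replicates_per_cell
        )
        if n < 2:
            raise ConfigurationError("every design cell needs >= 2 replicates")
        return n

    def cells(self):
        for g in self.genotypes:
            for trt in self.treatments:
                for tp in self.timepoints:
                    yield g, trt, tp

    @property
    def n_samples(self) -> int:
        return sum(self.n_replicates(*cell) for cell in self.cells())

    def sample_sheet(self) -> pd.DataFrame:
        rows = []
        for g, trt, tp in self.cells():
            for r in range(1, self.n_replicates(g, trt, tp) + 1):
                rows.append(
                    {
                        "sample": f"{g}_{trt}_{tp}h_r{r}",
                        "genotype": g,
                        "treatment": trt,
                        "timepoint": tp,
                        "replicate": r,
                    }
                )
        return pd.DataFrame(rows).set_index("sample")


@dataclass(frozen=True)
class EffectClassConfig:
    """Gene-level generative parameters.

    effect_magnitude : (low, high)
        |log2FC| drawn uniformly from this interval.
    sign_fraction_induced : float
        probability that a planted effect is positive (aphid-induced).
    dispersion_mean, dispersion_shape :
        per-gene phi ~ Gamma(shape, scale=mean/shape); mean 0.1 is typical
        of between-replicate biological variability in plant RNA-seq.
        ``dispersion_shape=None`` plants the constant phi = dispersion_mean
        for every gene (the homogeneous-dispersion calibration setting).
    baseline_mean : (low, high)
        expected mock counts at the reference depth, uniform.
    effect_timepoints :
        timepoints at which planted effects are active (default 6 h only).
    monogenic_subthreshold : float
        if > 0, synergistic genes get small monogenic effects with
        |log2FC| <= this value instead of exactly zero, to probe the
        relaxed-cutoff rule.
    """

    n_genes: int = 5000
    proportions: dict = field(default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    effect_magnitude: tuple[float, float] = (1.0, 3.0)
    sign_fraction_induced: float = 0.5
    dispersion_mean: float = 0.1
    dispersion_shape: float | None = 4.0
    baseline_mean: tuple[float, float] = (50.0, 500.0)
    effect_timepoints: tuple[int, ...] = (6,)
    monogenic_subthreshold: float = 0.0

    def validate(self) -> None:
        unknown = set(self.proportions) - set(CLASS_ORDER)
        if unknown:
            raise ConfigurationError(f"unknown effect classes: {sorted(unknown)}")
        props = [self.proportions.get(c, 0.0) for c in CLASS_ORDER]
        if any(p < 0 for p in props):
            raise ConfigurationError("negative class proportion")
        if abs(sum(props) - 1.0) > 1e-9:
            raise ConfigurationError(f"proportions sum to {sum(props)}, not 1")
        n_active = sum(1 for p in props if p > 0)
        if self.n_genes < n_active:
            raise ConfigurationError("n_genes smaller than number of active classes")
        if self.dispersion_mean < 0 or self.baseline_mean[0] <= 0:
            raise ConfigurationError("dispersions must be >= 0, baselines > 0")


@dataclass
class SimTruth:
    """Ground truth: class label, per-(genotype, timepoint) aphid-vs-mock
    log2FC, baseline mean and dispersion for every gene."""

    classes: pd.Series  # gene -> class label
    log2fc: pd.DataFrame  # genes x "<genotype>:<timepoint>" columns
    baseline_mean: pd.Series
    dispersion: pd.Series

    @property
    def gene_ids(self) -> pd.Index:
        return self.classes.index

    def fc_column(self, genotype: str, timepoint: int) -> pd.Series:
        return self.log2fc[f"{genotype}:{timepoint}"]

    def genes_of_class(self, label: str) -> pd.Index:
        return self.classes.index[self.classes == label]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "class": self.classes,
                "baseline_mean": self.baseline_mean,
                "dispersion": self.dispersion,
            }
        )
        return pd.concat([df, self.log2fc.add_prefix("log2fc_")], axis=1)

    def write(self, path) -> None:
        self.to_frame().rename_axis("gene").to_csv(path, sep="\t")

    @classmethod
    def read(cls, path) -> "SimTruth":
        # keep_default_na: the class label "null" must not parse as NaN
        df = pd.read_csv(
            path, sep="\t", index_col="gene", keep_default_na=False, na_values=[""]
        )
        fc_cols = [c for c in df.columns if c.startswith("log2fc_")]
        log2fc = df[fc_cols].rename(columns=lambda c: c[len("log2fc_"):])
        return cls(
            classes=df["class"],
            log2fc=log2fc,
            baseline_mean=df["baseline_mean"],
            dispersion=df["dispersion"],
        )


def largest_remainder_counts(n: int, proportions: dict) -> dict:
    """Apportion n genes to classes by the largest-remainder method.

    Ties in fractional remainders are broken by CLASS_ORDER position so the
    apportionment is deterministic.
    """
    labels = [c for c in CLASS_ORDER if proportions.get(c, 0.0) > 0]
    quotas = np.array([n * proportions[c] for c in labels])
    base = np.floor(quotas).astype(int)
    short = n - int(base.sum())
    remainders = quotas - base
    order = sorted(range(len(labels)), key=lambda i: (-remainders[i], i))
    for i in order[:short]:
        base[i] += 1
    return dict(zip(labels, base.tolist()))


def plant_effect_classes(config: EffectClassConfig, design: DesignSpec) -> SimTruth:
    """Assign classes and draw true per-gene parameters (seeded by design)."""
    config.validate()
    rng = np.random.default_rng(design.seed)
    counts = largest_remainder_counts(config.n_genes, config.proportions)

    labels = np.concatenate(
        [np.repeat(c, counts[c]) for c in CLASS_ORDER if c in counts]
    )
    width = len(str(config.n_genes))
    genes = pd.Index(
        [f"gene_{i:0{width}d}" for i in range(1, config.n_genes + 1)], name="gene"
    )
    classes = pd.Series(labels, index=genes, name="class")

    lo, hi = config.effect_magnitude
    baseline = pd.Series(
        rng.uniform(config.baseline_mean[0], config.baseline_mean[1], config.n_genes),
        index=genes,
        name="baseline_mean",
    )
    if config.dispersion_shape is None:
        phi = np.full(config.n_genes, config.dispersion_mean)
    else:
        scale = config.dispersion_mean / config.dispersion_shape
        phi = rng.gamma(config.dispersion_shape, scale, config.n_genes)
    dispersion = pd.Series(phi, index=genes, name="dispersion")

    def draw_effect(size):
        mag = rng.uniform(lo, hi, size)
        sign = np.where(rng.random(size) < config.sign_fraction_induced, 1.0, -1.0)
        return mag * sign

    cols = [f"{g}:{tp}" for g in design.genotypes for tp in design.timepoints]
    log2fc = pd.DataFrame(0.0, index=genes, columns=cols)
    g_s, g_r1, g_r2, g_r12 = design.genotypes[:4]

    for tp in config.effect_timepoints:
        if tp not in design.timepoints:
            raise ConfigurationError(f"effect timepoint {tp} not in the design")
        is_cls = {c: (classes == c).to_numpy() for c in CLASS_ORDER}

        n = int(is_cls["shared_all"].sum())
        eff = draw_effect(n)
        for g in design.genotypes:
            log2fc.loc[is_cls["shared_all"], f"{g}:{tp}"] = eff

        log2fc.loc[is_cls["r1_only"], f"{g_r1}:{tp}"] = draw_effect(
            int(is_cls["r1_only"].sum())
        )
        log2fc.loc[is_cls["r2_only"], f"{g_r2}:{tp}"] = draw_effect(
            int(is_cls["r2_only"].sum())
        )

        n = int(is_cls["additive"].sum())
        # one sign per gene for both monogenic components so the pyramid sum
        # stays well away from zero
        sign = np.where(rng.random(n) < config.sign_fraction_induced, 1.0, -1.0)
        d1 = rng.uniform(lo, hi, n) * sign
        d2 = rng.uniform(lo, hi, n) * sign
        log2fc.loc[is_cls["additive"], f"{g_r1}:{tp}"] = d1
        log2fc.loc[is_cls["additive"], f"{g_r2}:{tp}"] = d2
        log2fc.loc[is_cls["additive"], f"{g_r12}:{tp}"] = d1 + d2

        n = int(is_cls["synergistic"].sum())
        log2fc.loc[is_cls["synergistic"], f"{g_r12}:{tp}"] = draw_effect(n)
        if config.monogenic_subthreshold > 0:
            sub = config.monogenic_subthreshold
            log2fc.loc[is_cls["synergistic"], f"{g_r1}:{tp}"] = rng.uniform(-sub, sub, n)
            log2fc.loc[is_cls["synergistic"], f"{g_r2}:{tp}"] = rng.uniform(-sub, sub, n)

    return SimTruth(
        classes=classes, log2fc=log2fc, baseline_mean=baseline, dispersion=dispersion
    )


def simulate_experiment(truth: SimTruth, design: DesignSpec) -> CountMatrix:
    """Draw NB counts y ~ NB(mean = depth * baseline * 2^effect, phi).

    Depths are lognormal multipliers relative to the reference depth
    exp(library_size_log_mean); the generator is bit-reproducible for a
    fixed (truth, design, seed).
    """
    sheet = design.sample_sheet()
    # distinct stream from plant_effect_classes (which uses seed directly)
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 1]))

    n_samples = len(sheet)
    depth_mult = np.exp(
        rng.normal(0.0, design.library_size_log_sd, n_samples)
    )  # L_s / L_ref

    base = truth.baseline_mean.to_numpy()[:, None]  # (G, 1)
    phi = truth.dispersion.to_numpy()
    effect = np.zeros((len(truth.gene_ids), n_samples))
    for j, (sample, row) in enumerate(sheet.iterrows()):
        if row["treatment"] == "aphid":
            effect[:, j] = truth.fc_column(row["genotype"], row["timepoint"]).to_numpy()
    mu = base * depth_mult[None, :] * np.power(2.0, effect)

    counts = np.empty(mu.shape, dtype=np.int64)
    poisson_like = phi < 1e-12
    if poisson_like.any():
        counts[poisson_like] = rng.poisson(mu[poisson_like])
    nb = ~poisson_like
    if nb.any():
        r = (1.0 / phi[nb])[:, None]
        p = r / (r + mu[nb])
        counts[nb] = rng.negative_binomial(np.broadcast_to(r, p.shape), p)

    df = pd.DataFrame(counts, index=truth.gene_ids, columns=sheet.index)
    return CountMatrix(counts=df, samples=sheet.reset_index().set_index("sample"))


def all_null_config(n_genes: int = 2000, **kwargs) -> EffectClassConfig:
    """Convenience: every gene null (for calibration checks)."""
    return EffectClassConfig(
        n_genes=n_genes, proportions={"null": 1.0}, **kwargs
    )


def simulate(config: EffectClassConfig, design: DesignSpec):
    """Plant classes and draw counts in one call; returns (truth, counts)."""
    truth = plant_effect_classes(config, design)
    return truth, simulate_experiment(truth, design)


def with_seed(design: DesignSpec, seed: int) -> DesignSpec:
    return replace(design, seed=int(seed))
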