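"""Venn partitioning, strict synergy classification, additivity testing."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ragsynergy import synergy
from ragsynergy.de import ContrastResult
from ragsynergy.synergy import (
    additive_expectation,
    additivity_chisq,
    classify_synergy_strict,
    partition_de_sets,
    synergy_report,
    timepoint_overlap,
)


def contrasts_from_sets(universe, de_sets, log2fc=None):
    """Build minimal ContrastResults where membership fixes q below/above 0.05."""
    out = {}
    for name, s in de_sets.items():
        genes = sorted(universe)
        q = [0.01 if g in s else 0.8 for g in genes]
        d = [log2fc.get(name, {}).get(g, 1.0) for g in genes] if log2fc else [1.0] * len(genes)
        table = pd.DataFrame(
            {
                "log2FC": d,
                "se": 0.5,
                "p": q,
                "q": q,
                "mean_cpm": 10.0,
                "method": "exact",
            },
            index=pd.Index(genes, name="gene"),
        )
        out[name] = ContrastResult(name=name, table=table)
    return out


class TestPartition:
    def test_worked_example(self):
        universe = set("abcd")
        contrasts = contrasts_from_sets(
            universe,
            {"S": set(), "R1": {"a", "b"}, "R2": {"b", "c"}, "R12": {"b", "d"}},
        )
        part = partition_de_sets(contrasts, timepoint=6)
        assert part.synergy_set == {"d"}
        assert part.region("R1", "R2", "R12") == {"b"}
        assert part.region("R1") == {"a"}

    def test_all_empty(self):
        contrasts = contrasts_from_sets(
            set("ab"), {g: set() for g in ["S", "R1", "R2", "R12"]}
        )
        part = partition_de_sets(contrasts, timepoint=6)
        assert part.regions == {}
        assert part.synergy_set == set()

    def test_matches_membership_pattern_enumeration(self):
        # brute-force oracle: each gene's pattern computed independently
        rng = np.random.default_rng(0)
        universe = {f"g{i}" for i in range(200)}
        sets = {
            g: set(rng.choice(sorted(universe), size=rng.integers(0, 80), replace=False))
            for g in ["S", "R1", "R2", "R12"]
        }
        part = partition_de_sets(contrasts_from_sets(universe, sets), timepoint=6)

        regions = list(part.regions.values())
        for i, r1 in enumerate(regions):
            for r2 in regions[i + 1:]:
                assert not (r1 & r2)
        assert set().union(*regions) == set().union(*sets.values())
        for gene in set().union(*sets.values()):
            pattern = frozenset(g for g, s in sets.items() if gene in s)
            assert gene in part.regions[pattern]

    def test_mismatched_universe_rejected(self):
        a = contrasts_from_sets({"x"}, {"S": set()})["S"]
        b = contrasts_from_sets({"y"}, {"R12": set()})["R12"]
        with pytest.raises(ValueError, match="universe"):
            partition_de_sets({"S": a, "R12": b}, timepoint=6)


class TestStrictClassification:
    @pytest.mark.parametrize(
        "qs,expected",
        [
            ((0.01, 0.30, 0.26), True),
            ((0.01, 0.20, 0.90), False),  # R1 in the 0.05-0.25 gray zone
            ((0.049, 0.251, 0.251), True),  # strict inequalities at boundary
            ((0.05, 0.30, 0.30), False),  # q_pyramid not < 0.05
            ((0.01, 0.25, 0.30), False),  # q_R1 not > 0.25
        ],
    )
    def test_rule(self, qs, expected):
        assert classify_synergy_strict(*qs) is expected

    def test_missing_q_is_untestable(self):
        assert classify_synergy_strict(0.01, float("nan"), 0.3) is None

    def test_relaxing_cutoff_shrinks_strict_set(self):
        rng = np.random.default_rng(1)
        qs = rng.random((300, 3)) * [0.05, 1.0, 1.0]
        for relaxed_lo, relaxed_hi in [(0.1, 0.25), (0.25, 0.5)]:
            lo = {
                i for i, (qp, q1, q2) in enumerate(qs)
                if classify_synergy_strict(qp, q1, q2, relaxed=relaxed_lo)
            }
            hi = {
                i for i, (qp, q1, q2) in enumerate(qs)
                if classify_synergy_strict(qp, q1, q2, relaxed=relaxed_hi)
            }
            assert hi <= lo


class TestAdditivity:
    def test_additive_expectation(self):
        assert additive_expectation(0.5, 0.7) == pytest.approx(1.2)
        assert additive_expectation(-1.0, 1.0) == 0.0
        assert additive_expectation(0.0, 0.0) == 0.0

    def test_perfect_additivity_gives_t_zero(self):
        d = np.array([1.0, -2.0, 0.5])
        t, df, p = additivity_chisq(d, d, *(np.full(3, 0.3),) * 3)
        assert t == 0.0 and df == 3 and p == 1.0

    def test_closed_form_worked_example(self):
        # 50 genes, deviation 2, each of three SEs 0.5: T = 50*4/0.75
        n = 50
        t, df, p = additivity_chisq(
            np.full(n, 2.0), np.zeros(n), *(np.full(n, 0.5),) * 3
        )
        assert t == pytest.approx(n * 4.0 / 0.75)
        assert t == pytest.approx(266.66, rel=1e-3)
        assert df == n
        assert p == pytest.approx(stats.chi2.sf(266.6667, 50))
        assert p < 1e-20

    def test_calibration_under_correct_ses(self):
        # T/df -> 1 under the additive null with correctly specified SEs
        rng = np.random.default_rng(3)
        n = 2000
        se1, se2, seo = 0.3, 0.4, 0.5
        d1 = rng.normal(0, 1, n)
        d2 = rng.normal(0, 1, n)
        d_obs = (d1 + d2) + rng.normal(0, np.sqrt(se1**2 + se2**2 + seo**2), n)
        t, df, p = additivity_chisq(
            d_obs, d1 + d2, np.full(n, seo), np.full(n, se1), np.full(n, se2)
        )
        assert abs(t / df - 1) < 0.1

    def test_binned_method(self):
        rng = np.random.default_rng(4)
        same = rng.normal(0, 1, 500)
        t, df, p = additivity_chisq(same, same.copy(), method="binned")
        assert t == 0.0 and p == 1.0
        shifted = same + 3.0
        t2, df2, p2 = additivity_chisq(shifted, same, method="binned")
        assert p2 < 0.001

    def test_zero_se_rejected(self):
        with pytest.raises(ValueError, match="standard errors"):
            additivity_chisq([1.0], [0.0], [0.0], [0.5], [0.5])

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            additivity_chisq([], [], [], [], [])


class TestSynergyReport:
    def test_sign_subsets_partition_nonzero_genes(self):
        universe = {f"g{i}" for i in range(6)}
        syn = {"g0", "g1", "g2"}
        fc = {"R12": {"g0": 2.0, "g1": -1.0, "g2": 0.0}}
        contrasts = contrasts_from_sets(
            universe,
            {"S": set(), "R1": set(), "R2": set(), "R12": syn},
            log2fc=fc,
        )
        part = partition_de_sets(contrasts, timepoint=6)
        rep = synergy_report(part, contrasts)
        assert set(rep.table.index) == syn
        signs = rep.table["sign"]
        assert signs["g0"] == "induced"
        assert signs["g1"] == "repressed"
        assert signs["g2"] == "zero"
        assert rep.aggregate.loc["induced", "n"] == 1
        assert rep.aggregate.loc["repressed", "n"] == 1
        assert rep.aggregate.loc["full", "n"] == 3

    def test_recovers_planted_synergy(self, small_contrasts_6h):
        truth, contrasts = small_contrasts_6h
        part = partition_de_sets(contrasts, timepoint=6)
        rep = synergy_report(part, contrasts)
        true_syn = set(truth.genes_of_class("synergistic"))
        strict = rep.strict_set
        assert len(strict & true_syn) / len(true_syn) >= 0.7
        assert len(strict & true_syn) / len(strict) >= 0.75
        # additive genes rarely slip into the strict set
        additive = set(truth.genes_of_class("additive"))
        assert len(strict & additive) <= 0.1 * len(additive)


class TestTimepointOverlap:
    def _two_partitions(self):
        universe = set("abcde")
        sets1 = {"S": set(), "R1": set(), "R2": set(), "R12": {"a", "b"}}
        sets2 = {"S": set(), "R1": set(), "R2": set(), "R12": {"b", "c"}}
        fc1 = {"R12": {"b": 2.0}}
        fc2 = {"R12": {"b": -1.0}}
        c1 = contrasts_from_sets(universe, sets1, log2fc=fc1)
        c2 = contrasts_from_sets(universe, sets2, log2fc=fc2)
        p1 = partition_de_sets(c1, timepoint=6)
        p2 = partition_de_sets(c2, timepoint=12)
        return p1, p2, c1, c2

    def test_overlap_counts_and_direction(self):
        p1, p2, c1, c2 = self._two_partitions()
        dyn = timepoint_overlap(p1, p2, c1, c2)
        row = dyn.per_genotype.loc["R12"]
        assert (row["n_t1"], row["n_t2"], row["n_overlap"]) == (2, 2, 1)
        conc = dyn.gene_concordance
        assert conc.loc[conc["gene"] == "b", "direction"].item() == "opposite"

    def test_synergy_silent_at_later_timepoint(self):
        p1, p2, c1, c2 = self._two_partitions()
        dyn = timepoint_overlap(p1, p2, c1, c2)
        # synergy set at 6 h = {a, b}; only "a" is not DE anywhere at 12 h
        assert dyn.synergy_set_size == 2
        assert dyn.synergy_silent_at_t2 == 1

    def test_disjoint_sets_have_no_labels(self):
        universe = set("ab")
        c1 = contrasts_from_sets(universe, {"R12": {"a"}})
        c2 = contrasts_from_sets(universe, {"R12": {"b"}})
        dyn = timepoint_overlap(
            partition_de_sets(c1, timepoint=6),
            partition_de_sets(c2, timepoint=12),
            c1,
            c2,
        )
        assert dyn.per_genotype.loc["R12", "n_overlap"] == 0
        assert dyn.gene_concordance.empty
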