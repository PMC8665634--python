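"""DE engine: CPM, filtering, TMM, dispersion, exact test, BH, contrasts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ragsynergy import de, simdata
from ragsynergy.de import (
    bh_fdr,
    cpm,
    estimate_dispersion,
    filter_low_expression,
    nb_exact_test,
    normalize,
    run_contrast,
    tmm_factors,
)
from conftest import make_count_matrix


class TestCpm:
    def test_arithmetic(self):
        counts = pd.DataFrame({"s1": [100, 0]}, index=["g1", "g2"])
        libs = pd.Series({"s1": 1000.0})
        out = cpm(counts, libs)
        assert out.at["g1", "s1"] == 100_000
        assert out.at["g2", "s1"] == 0

    def test_scale_invariance(self):
        counts = pd.DataFrame({"s1": [5, 10], "s2": [3, 7]}, index=["g1", "g2"])
        libs = pd.Series({"s1": 100.0, "s2": 50.0})
        doubled = cpm(counts * 2, libs * 2)
        pd.testing.assert_frame_equal(doubled, cpm(counts, libs))

    def test_zero_library_rejected(self):
        counts = pd.DataFrame({"s1": [1]}, index=["g1"])
        with pytest.raises(ValueError):
            cpm(counts, pd.Series({"s1": 0.0}))


class TestFilterLowExpression:
    def _matrix(self, rows):
        arr = np.array(rows)
        return make_count_matrix(
            arr, ["S"] * arr.shape[1], ["mock"] * arr.shape[1]
        )

    def test_all_zero_gene_removed_and_expressed_kept(self):
        # library sizes ~ 1e6 so gene g2's CPM is comfortably >= 1
        base = np.full((1, 3), 1_000_000)
        cm = make_count_matrix(
            np.vstack([base, [[0, 0, 0]], [[5, 5, 5]]]),
            ["S", "S", "S"], ["mock", "mock", "mock"],
        )
        out = filter_low_expression(cm, min_samples=3)
        assert "g2" not in out.gene_ids and "g3" in out.gene_ids

    def test_cpm_exactly_one_is_kept(self):
        # rule is "CPM < 1 eliminated": a gene at exactly 1.0 survives
        col = np.array([[999_999], [1]])
        cm = make_count_matrix(col, ["S"], ["mock"])
        assert cm.library_sizes.iloc[0] == 1_000_000
        out = filter_low_expression(cm, min_samples=1)
        assert "g2" in out.gene_ids

    def test_library_sizes_not_recomputed(self, small_experiment):
        _, cm = small_experiment
        out = filter_low_expression(cm, min_samples=3)
        pd.testing.assert_series_equal(out.library_sizes, cm.library_sizes)


class TestTmm:
    def test_identical_samples_give_unit_factors(self):
        col = np.array([10, 200, 3000, 40, 500, 60])
        cm = make_count_matrix(
            np.column_stack([col, col, col]), ["S"] * 3, ["mock"] * 3
        )
        assert np.allclose(tmm_factors(cm).to_numpy(), 1.0)

    def test_pure_depth_difference_absorbed(self):
        col = np.array([10, 200, 3000, 40, 500, 60])
        cm = make_count_matrix(
            np.column_stack([col, 2 * col]), ["S"] * 2, ["mock", "aphid"]
        )
        assert np.allclose(tmm_factors(cm).to_numpy(), 1.0)

    def test_factors_match_hand_computed_trimmed_mean(self):
        # 30-gene matrix with one high-abundance spike in sample B;
        # oracle executes the weighted-trimmed-mean formula step by step
        rng = np.random.default_rng(3)
        base = rng.integers(50, 500, 30)
        a = base.copy()
        b = base.copy()
        b[0] = 20_000  # composition spike
        cm = make_count_matrix(
            np.column_stack([a, b]), ["S", "S"], ["mock", "aphid"]
        )
        got = tmm_factors(cm, ref_sample="s1")

        n_a, n_b = a.sum(), b.sum()
        pk, pr = b / n_b, a / n_a
        m = np.log2(pk / pr)
        av = 0.5 * np.log2(pk * pr)
        w = (n_b - b) / (n_b * b) + (n_a - a) / (n_a * a)
        n = len(m)
        rank_m, rank_a = stats.rankdata(m), stats.rankdata(av)
        lo_m, hi_m = np.floor(n * 0.3) + 1, n - np.floor(n * 0.3)
        lo_a, hi_a = np.floor(n * 0.05) + 1, n - np.floor(n * 0.05)
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        log_f_b = np.sum(w[keep] * m[keep]) / np.sum(w[keep])
        expected = 2 ** np.array([-log_f_b / 2, log_f_b / 2])
        assert np.allclose(got.to_numpy(), expected, rtol=1e-10)

    def test_geometric_mean_is_one(self, small_experiment):
        _, cm = small_experiment
        sub = cm.subset_samples(cm.samples["timepoint"] == 6)
        f = tmm_factors(filter_low_expression(sub))
        assert abs(np.mean(np.log(f.to_numpy()))) < 1e-9


class TestEstimateDispersion:
    def _norm_matrix(self, counts, groups):
        cm = make_count_matrix(counts, groups, ["mock"] * counts.shape[1])
        return cm, normalize(cm)

    def test_poisson_counts_give_near_zero_dispersion(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(500, size=(400, 12))
        cm, norm = self._norm_matrix(counts, ["A"] * 6 + ["B"] * 6)
        disp = estimate_dispersion(cm, norm)
        assert 0 <= disp.tagwise.median() <= 0.02

    def test_nb_phi_recovered_at_50_replicates(self):
        rng = np.random.default_rng(1)
        phi, mu = 0.1, 300
        r = 1 / phi
        counts = rng.negative_binomial(r, r / (r + mu), size=(500, 50))
        cm, norm = self._norm_matrix(counts, ["A"] * 50)
        disp = estimate_dispersion(cm, norm)
        assert 0.08 <= disp.common <= 0.12

    def test_identical_replicates_shrink_to_prior(self):
        col = np.array([100, 200, 300, 400])
        counts = np.column_stack([col] * 4)
        cm, norm = self._norm_matrix(counts, ["A", "A", "B", "B"])
        disp = estimate_dispersion(cm, norm, prior_df=10.0)
        # zero within-group variance: gene estimate 0, common 0, floored
        assert disp.common == 0.0
        assert (disp.tagwise == de.PHI_FLOOR).all()

    def test_all_singleton_groups_rejected(self):
        counts = np.array([[10, 20], [30, 40]])
        cm, norm = self._norm_matrix(counts, ["A", "B"])
        with pytest.raises(ValueError):
            estimate_dispersion(cm, norm)


class TestNbExactTest:
    def test_equal_groups_give_p_one_and_zero_fc(self):
        y = np.array([[10, 20, 30]])
        libs = np.full(3, 1e6)
        out = nb_exact_test(y, y.copy(), np.array([0.1]), libs, libs)
        assert out.at[0, "p"] == 1.0
        assert out.at[0, "log2FC"] == 0.0

    def test_phi_zero_matches_binomial_split_test(self):
        # independent oracle: scipy's exact binomial test on the split
        rng = np.random.default_rng(2)
        libs3 = np.full(3, 1e6)
        libs2 = np.full(2, 1e6)
        for _ in range(30):
            ya = rng.integers(0, 40, (1, 3))
            yb = rng.integers(0, 40, (1, 2))
            out = nb_exact_test(ya, yb, np.array([0.0]), libs3, libs2)
            t_a, t_b = int(ya.sum()), int(yb.sum())
            ref = stats.binomtest(t_a, t_a + t_b, 3 / 5, alternative="two-sided").pvalue
            assert out.at[0, "p"] == pytest.approx(ref, abs=1e-9)

    def test_sign_convention_and_prior(self):
        # mean CPM 40 (aphid) vs 10 (mock), prior 0.5 -> log2(40.5/10.5)
        libs = np.full(3, 1e6)
        ya = np.full((1, 3), 40)
        yb = np.full((1, 3), 10)
        out = nb_exact_test(ya, yb, np.array([0.1]), libs, libs)
        assert out.at[0, "log2FC"] == pytest.approx(np.log2(40.5 / 10.5), rel=1e-9)
        assert out.at[0, "log2FC"] > 0  # positive = induced in first group

    def test_group_swap_symmetry(self):
        rng = np.random.default_rng(5)
        ya = rng.integers(0, 200, (20, 3))
        yb = rng.integers(0, 200, (20, 3))
        phi = np.full(20, 0.1)
        libs = np.full(3, 1e6)
        ab = nb_exact_test(ya, yb, phi, libs, libs)
        ba = nb_exact_test(yb, ya, phi, libs, libs)
        assert np.allclose(ab["p"], ba["p"], atol=1e-12)
        assert np.allclose(ab["log2FC"], -ba["log2FC"], atol=1e-12)

    def test_wald_fallback_at_large_totals(self):
        libs = np.full(3, 1e6)
        ya = np.full((1, 3), 3000)
        yb = np.full((1, 3), 2000)
        out = nb_exact_test(ya, yb, np.array([0.05]), libs, libs)
        assert out.at[0, "method"] == "wald"
        assert 0 < out.at[0, "p"] < 1

    def test_negative_counts_rejected(self):
        libs = np.full(2, 1e6)
        with pytest.raises(ValueError):
            nb_exact_test(
                np.array([[-1, 2]]), np.array([[1, 2]]), np.array([0.1]), libs, libs
            )


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_hand_executed_step_up(self):
        got = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert (bh_fdr([1.0, 1.0, 1.0]) == 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=1000))
    def test_matches_brute_force_step_up(self, pvals):
        # oracle: q_i = min over j with p_(j) >= p_(i) of p_(j) * n / rank_j
        p = np.asarray(pvals)
        n = len(p)
        order = np.argsort(p, kind="stable")
        q_sorted = p[order] * n / np.arange(1, n + 1)
        q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
        expected = np.empty(n)
        expected[order] = np.minimum(q_sorted, 1.0)
        assert np.allclose(bh_fdr(p), expected, atol=1e-12)

    def test_q_geq_p_and_order_preserving(self):
        rng = np.random.default_rng(0)
        p = rng.random(500)
        q = bh_fdr(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestRunContrast:
    def test_power_on_planted_effect(self):
        # log2FC = 3, mean 100, phi = 0.1, n = 3: detected at q < 0.05
        detected = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            n_genes = 200
            mu = np.full(n_genes, 100.0)
            r = 1 / 0.1
            mock = rng.negative_binomial(r, r / (r + mu[:, None]), (n_genes, 3))
            mu_a = mu.copy()
            mu_a[0] *= 8  # 2**3
            aphid = rng.negative_binomial(r, r / (r + mu_a[:, None]), (n_genes, 3))
            cm = make_count_matrix(
                np.hstack([aphid, mock]),
                ["S"] * 6,
                ["aphid"] * 3 + ["mock"] * 3,
            )
            norm = normalize(cm)
            disp = estimate_dispersion(cm, norm)
            a = cm.samples["treatment"] == "aphid"
            b = cm.samples["treatment"] == "mock"
            res = run_contrast(cm, norm, disp, a, b, "t")
            if res.table["q"].iloc[0] < 0.05:
                detected += 1
        assert detected >= 0.95 * n_seeds

    def test_self_contrast_gives_uniformish_p(self):
        design = simdata.DesignSpec(seed=8, timepoints=(6,), replicates_per_cell=4)
        cfg = simdata.EffectClassConfig(
            n_genes=800, proportions={"null": 1.0}, dispersion_shape=None
        )
        _, cm = simdata.simulate(cfg, design)
        norm = normalize(cm)
        disp = estimate_dispersion(cm, norm)
        cell = (cm.samples["genotype"] == "S") & (cm.samples["treatment"] == "mock")
        reps = cm.samples["replicate"]
        a = cell & (reps <= 2)
        b = cell & (reps > 2)
        res = run_contrast(cm, norm, disp, a, b, "self")
        assert abs(res.table["p"].mean() - 0.5) < 0.05
        assert (res.table["q"] < 0.05).mean() <= 0.01

    def test_null_contrast_controls_fdr(self, small_contrasts_6h):
        # susceptible genotype carries only the shared-response genes;
        # null genes must essentially never be called
        truth, contrasts = small_contrasts_6h
        null_genes = [
            g for g in truth.genes_of_class("null") if g in contrasts["S"].gene_ids
        ]
        qs = contrasts["S"].table.loc[null_genes, "q"]
        assert (qs < 0.05).mean() <= 0.05

    def test_contrast_round_trip(self, tmp_path, small_contrasts_6h):
        _, contrasts = small_contrasts_6h
        res = contrasts["R12"]
        res.write(tmp_path / "c.tsv")
        back = de.ContrastResult.read(tmp_path / "c.tsv", name=res.name)
        pd.testing.assert_frame_equal(back.table, res.table)

    def test_empty_group_rejected(self, small_experiment):
        _, cm = small_experiment
        norm = normalize(cm)
        disp = estimate_dispersion(cm, norm)
        a = cm.samples["genotype"] == "S"
        b = cm.samples["genotype"] == "nonexistent"
        with pytest.raises(ValueError, match="empty group"):
            run_contrast(cm, norm, disp, a, b, "bad")
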