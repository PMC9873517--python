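"""Group-inference statistics: adjusted tests, demographics, FDR, NBS, correlations."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hofcnet import (
    ConnectivityMatrix,
    adjusted_group_test,
    chi_square_2x2,
    fdr_bh,
    mann_whitney,
    nbs,
    partial_spearman,
    summary_t_test,
)


class TestAdjustedGroupTest:
    def test_identical_values(self):
        gc = adjusted_group_test(np.ones(8), np.array(["A"] * 4 + ["B"] * 4))
        assert gc.t_stat == 0.0 and gc.p_value == 1.0

    def test_toy_data_matches_pooled_t(self):
        gc = adjusted_group_test(
            np.array([1.0, 2, 3, 4, 5, 6]), np.array(["A"] * 3 + ["B"] * 3)
        )
        assert abs(gc.t_stat) == pytest.approx(3.674, abs=5e-4)
        assert gc.direction == 1  # group B larger

    def test_reduces_to_pooled_t_without_covariates(self):
        rng = np.random.default_rng(0)
        vals = rng.standard_normal(30)
        groups = np.array(["A"] * 14 + ["B"] * 16)
        gc = adjusted_group_test(vals, groups)
        t_ref, p_ref = sps.ttest_ind(vals[14:], vals[:14])
        assert gc.t_stat == pytest.approx(t_ref, abs=1e-10)
        assert gc.p_value == pytest.approx(p_ref, abs=1e-10)

    def test_covariate_adjustment_removes_confound(self):
        rng = np.random.default_rng(1)
        age = rng.uniform(50, 80, 60)
        groups = np.array(["A"] * 30 + ["B"] * 30)
        vals = 0.1 * age + rng.normal(0, 0.05, 60)  # age effect only
        cov = pd.DataFrame({"age": age})
        gc_raw = adjusted_group_test(vals, groups)
        gc_adj = adjusted_group_test(vals, groups, cov)
        assert abs(gc_adj.t_stat) < abs(gc_raw.t_stat) + 2  # sanity
        assert gc_adj.p_value > 0.01

    def test_collinear_covariate_fails_naming_column(self):
        groups = np.array(["A"] * 5 + ["B"] * 5)
        cov = pd.DataFrame({"indicator": (groups == "B").astype(float)})
        with pytest.raises(ValueError, match="collinear.*indicator"):
            adjusted_group_test(np.arange(10.0), groups, cov)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="3 subjects"):
            adjusted_group_test(np.arange(4.0), np.array(["A", "A", "B", "B"]))


class TestSummaryTTest:
    def test_equal_means(self):
        t, p = summary_t_test(5.0, 1.0, 10, 5.0, 2.0, 12)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_cohort_age_row(self):
        """Printed age summaries give t = 0.54 (p = 0.59)."""
        t, p = summary_t_test(61.63, 6.39, 60, 60.69, 11.71, 51)
        assert round(t, 2) == 0.54
        assert round(p, 2) == 0.59

    def test_matches_raw_data_with_constructed_summaries(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            n_a, n_b = int(rng.integers(5, 30)), int(rng.integers(5, 30))
            a = rng.standard_normal(n_a)
            b = rng.standard_normal(n_b)
            # rescale to exact target summaries
            ma, sa = float(rng.uniform(-5, 5)), float(rng.uniform(0.5, 3))
            mb, sb = float(rng.uniform(-5, 5)), float(rng.uniform(0.5, 3))
            a = (a - a.mean()) / a.std(ddof=1) * sa + ma
            b = (b - b.mean()) / b.std(ddof=1) * sb + mb
            t_raw, p_raw = sps.ttest_ind(a, b)
            t, p = summary_t_test(ma, sa, n_a, mb, sb, n_b)
            assert t == pytest.approx(t_raw, abs=1e-8)
            assert p == pytest.approx(p_raw, abs=1e-8)


class TestChiSquare:
    def test_proportional_table_is_zero(self):
        chi2, p = chi_square_2x2(10, 10, 20, 20)
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_cohort_sex_row(self):
        """Printed sex counts give chi-square = 0.069."""
        chi2, _ = chi_square_2x2(35, 25, 31, 20)
        assert round(chi2, 3) == 0.069

    def test_matches_expected_count_formula(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a, b, c, d = rng.integers(1, 50, size=4)
            chi2, _ = chi_square_2x2(a, b, c, d)
            obs = np.array([[a, b], [c, d]], float)
            expect = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
            assert chi2 == pytest.approx(((obs - expect) ** 2 / expect).sum(), abs=1e-10)

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            chi_square_2x2(0, 0, 5, 5)


class TestMannWhitney:
    def test_identical_samples(self):
        _, p = mann_whitney([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_fully_separated(self):
        u, _ = mann_whitney([10, 11, 12], [1, 2, 3])
        assert u == 9.0  # U of the first sample; second sample has U = 0
        u2, _ = mann_whitney([1, 2, 3], [10, 11, 12])
        assert u2 == 0.0

    def test_exact_p_matches_enumeration_with_ties(self):
        """Small-sample p equals full enumeration of group assignments."""
        x = np.array([1.0, 2.0, 2.0, 5.0])
        y = np.array([2.0, 3.0, 4.0, 4.0])
        u_obs, p = mann_whitney(x, y)
        pooled = np.concatenate([x, y])
        mu = x.size * y.size / 2.0

        def ustat(vals_x, vals_y):
            ranks = sps.rankdata(np.concatenate([vals_x, vals_y]))
            return ranks[: len(vals_x)].sum() - len(vals_x) * (len(vals_x) + 1) / 2

        count, total = 0, 0
        for pick in combinations(range(8), 4):
            mask = np.zeros(8, bool)
            mask[list(pick)] = True
            total += 1
            if abs(ustat(pooled[mask], pooled[~mask]) - mu) >= abs(u_obs - mu) - 1e-12:
                count += 1
        assert p == pytest.approx(count / total)

    def test_large_sample_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 25)
        y = rng.normal(0.5, 1, 30)
        u, p = mann_whitney(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic", use_continuity=False)
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)


class TestFdr:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(fdr_bh([0.03]), [0.03])

    def test_stepup_by_hand(self):
        np.testing.assert_allclose(fdr_bh([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_all_ones(self):
        np.testing.assert_allclose(fdr_bh([1.0, 1.0, 1.0]), 1.0)

    def test_adjusted_at_least_raw_and_rejections_match_classic_bh(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0, 1, 40)
        adj = fdr_bh(p)
        assert np.all(adj >= p - 1e-15)
        q = 0.1
        # classic step-up: largest k with p_(k) <= k/m * q
        order = np.argsort(p)
        m = p.size
        k_max = 0
        for k in range(1, m + 1):
            if p[order[k - 1]] <= k / m * q:
                k_max = k
        classic = np.zeros(m, bool)
        classic[order[:k_max]] = True
        np.testing.assert_array_equal(adj <= q, classic)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.2])


def _matrices_from_features(y, labels):
    """Each row of y is one subject's upper-triangle edge vector."""
    n = len(labels)
    iu, ju = np.triu_indices(n, k=1)
    mats = []
    for row in y:
        m = np.zeros((n, n))
        m[iu, ju] = row
        mats.append(ConnectivityMatrix(m + m.T, "low", labels))
    return mats


class TestNbs:
    def _toy_cohort(self, seed=0, shift=0.0, n_per=12, n_nodes=8):
        rng = np.random.default_rng(seed)
        n_edges = n_nodes * (n_nodes - 1) // 2
        ya = rng.normal(0.3, 0.1, (n_per, n_edges))
        yb = rng.normal(0.3, 0.1, (n_per, n_edges))
        yb[:, :3] += shift  # edges (0,1), (0,2), (0,3): a connected star
        labels = [f"r{i}" for i in range(n_nodes)]
        return (np.clip(ya, -1, 1), np.clip(yb, -1, 1), labels)

    def test_no_suprathreshold_edges_gives_empty_result(self):
        ya, yb, labels = self._toy_cohort(seed=1)
        res = nbs(_matrices_from_features(ya, labels), _matrices_from_features(yb, labels),
                  primary_alpha=1e-12, n_perm=100, seed=0)
        assert res.components == [] and res.edges == []

    def test_strong_planted_star_is_significant(self):
        ya, yb, labels = self._toy_cohort(seed=2, shift=0.3)
        res = nbs(_matrices_from_features(ya, labels), _matrices_from_features(yb, labels),
                  primary_alpha=0.01, n_perm=200, seed=0)
        sig = res.significant()
        assert sig
        planted = {(0, 1), (0, 2), (0, 3)}
        assert planted <= {tuple(sorted(e)) for e in sig[0]["edges"]}

    def test_corrected_p_floor(self):
        ya, yb, labels = self._toy_cohort(seed=3, shift=0.5)
        res = nbs(_matrices_from_features(ya, labels), _matrices_from_features(yb, labels),
                  primary_alpha=0.01, n_perm=150, seed=0)
        for c in res.components:
            assert c["corrected_p"] >= 1.0 / 151

    def test_edgewise_t_matches_statsmodels_with_covariates(self):
        """The vectorized edge test equals the per-edge OLS group t."""
        ya, yb, labels = self._toy_cohort(seed=4, shift=0.1)
        rng = np.random.default_rng(6)
        cov = pd.DataFrame({
            "age": rng.uniform(50, 80, 24),
            "sex": rng.integers(0, 2, 24).astype(float),
        })
        res = nbs(_matrices_from_features(ya, labels), _matrices_from_features(yb, labels),
                  covariates=cov, primary_alpha=0.05, n_perm=100, seed=0)
        groups = np.array(["A"] * 12 + ["B"] * 12)
        stacked = np.vstack([ya, yb])
        for e in [0, 5, 17, 27]:
            gc = adjusted_group_test(stacked[:, e], groups, cov)
            assert res.t_values[e] == pytest.approx(gc.t_stat, abs=1e-8)

    def test_mismatched_labels_rejected(self):
        ya, yb, labels = self._toy_cohort(seed=5)
        mats_a = _matrices_from_features(ya, labels)
        other = [f"x{i}" for i in range(len(labels))]
        mats_b = _matrices_from_features(yb, other)
        with pytest.raises(ValueError, match="region labels"):
            nbs(mats_a, mats_b, n_perm=100)

    def test_intensity_statistic_runs(self):
        ya, yb, labels = self._toy_cohort(seed=7, shift=0.3)
        res = nbs(_matrices_from_features(ya, labels), _matrices_from_features(yb, labels),
                  primary_alpha=0.01, n_perm=120, seed=0, statistic="intensity")
        assert res.components and res.components[0]["size"] > 0


class TestPartialSpearman:
    def test_monotone_relation(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        cr = partial_spearman(x, np.exp(x))
        assert cr.rho == pytest.approx(1.0)

    def test_equals_plain_spearman_without_covariates(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(25)
        y = 0.5 * x + rng.standard_normal(25)
        cr = partial_spearman(x, y)
        rho_ref, p_ref = sps.spearmanr(x, y)
        assert cr.rho == pytest.approx(rho_ref, abs=1e-12)
        assert cr.p_value == pytest.approx(p_ref, abs=1e-6)

    def test_covariate_driven_association_vanishes_after_adjustment(self):
        rng = np.random.default_rng(8)
        rhos = []
        for _ in range(100):
            z = rng.standard_normal(100)
            x = z + 0.3 * rng.standard_normal(100)
            y = z + 0.3 * rng.standard_normal(100)
            cr = partial_spearman(x, y, pd.DataFrame({"z": z}))
            rhos.append(cr.rho)
        assert abs(np.mean(rhos)) < 0.1

    def test_matches_pingouin_partial_correlation(self):
        """Cross-check against an independent partial-Spearman implementation."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(9)
        df = pd.DataFrame({
            "x": rng.standard_normal(40),
            "y": rng.standard_normal(40),
            "age": rng.uniform(50, 80, 40),
            "edu": rng.uniform(6, 20, 40),
        })
        df["y"] += 0.4 * df["x"]
        cr = partial_spearman(df.x, df.y, df[["age", "edu"]])
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["age", "edu"],
                                    method="spearman")
        assert cr.rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert cr.p_value == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-6)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            partial_spearman(np.ones(10), np.arange(10.0))
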