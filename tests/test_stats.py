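"""The statistical battery: Mann-Whitney, ROC, logistic regression,
normality screen, and molecular strata."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats as sps

from aptwq import (
    hosmer_lemeshow,
    logistic_fit,
    mann_whitney,
    nagelkerke_r2,
    omnibus_test,
    roc_curve,
    shapiro_wilk,
    subgroup_means,
)
from aptwq.errors import SeparationError


def cohort_columns(final_cohort):
    df = final_cohort.df
    hgg = df[df["group"] == "HGG"]
    lgg = df[df["group"] == "LGG"]
    return df, hgg, lgg


class TestMannWhitney:
    def test_reference_cohort_u_values(self, final_cohort):
        _, hgg, lgg = cohort_columns(final_cohort)
        expected = {"aptw_mean": 10.0, "aptw_max": 5.0, "aptw_min": 22.0, "aptw_range": 19.0}
        for col, u in expected.items():
            r = mann_whitney(hgg[col], lgg[col])
            assert r.u_statistic == u, col

    def test_reference_cohort_mean_ranks(self, final_cohort):
        # the rank structure behind the U values, at display precision
        _, hgg, lgg = cohort_columns(final_cohort)
        r = mann_whitney(hgg["aptw_mean"], lgg["aptw_mean"])
        assert round(r.mean_rank_a, 2) == 13.88
        assert round(r.mean_rank_b, 2) == 5.17

    def test_identical_tied_groups(self):
        r = mann_whitney([1, 2, 3], [1, 2, 3])
        assert r.u_statistic == 4.5
        assert r.p_exact == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exact_p_matches_scipy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=8), rng.normal(0.7, size=7)
        ours = mann_whitney(a, b)
        ref = sps.mannwhitneyu(a, b, method="exact", alternative="two-sided")
        assert ours.p_exact == pytest.approx(ref.pvalue, abs=1e-12)

    def test_exact_close_to_continuity_corrected_asymptotic(self):
        # with the continuity correction the normal approximation tracks
        # the exact permutation p within 0.02 already at n1, n2 >= 8
        rng = np.random.default_rng(11)
        for _ in range(10):
            a = rng.normal(size=9)
            b = rng.normal(0.5, size=8)
            r = mann_whitney(a, b, continuity=True)
            assert abs(r.p_exact - r.p_asymptotic) < 0.02

    def test_mean_ranks_average_to_grand_mean(self, rng):
        a, b = rng.normal(size=12), rng.normal(size=5)
        r = mann_whitney(a, b)
        grand = (r.mean_rank_a * r.n_a + r.mean_rank_b * r.n_b) / (r.n_a + r.n_b)
        assert grand == pytest.approx((r.n_a + r.n_b + 1) / 2)


class TestRoc:
    def test_perfect_separation(self):
        r = roc_curve([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1], positive=1)
        assert r.auc == 1.0
        assert r.youden == pytest.approx(1.0)
        assert 3 < r.optimal_cutoff < 10

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([1, 2, 3], [1, 1, 1], positive=1)

    def test_auc_u_rank_identity_on_tiefree_data(self, rng):
        # AUC equals 1 - U_neg/(n1*n2) exactly when no cross-group ties
        scores = rng.normal(size=18)
        y = np.array([1] * 10 + [0] * 8)
        r = roc_curve(scores, y, positive=1)
        mw = mann_whitney(scores[y == 1], scores[y == 0])
        assert r.auc == pytest.approx(mw.u_a / (10 * 8), abs=1e-15)

    def test_cutoff_is_midpoint_of_adjacent_scores(self):
        r = roc_curve([1.0, 2.0, 4.0, 5.0], [0, 0, 1, 1], positive=1)
        assert r.optimal_cutoff == pytest.approx(3.0)
        assert r.sensitivity == 1.0 and r.specificity == 1.0

    def test_j_tie_broken_toward_higher_specificity(self):
        # both interior thresholds reach J = 0.5; the higher one (better
        # specificity) must win
        scores = [1.0, 2.0, 3.0, 4.0]
        labels = [0, 1, 0, 1]
        r = roc_curve(scores, labels, positive=1)
        assert r.optimal_cutoff == pytest.approx(3.5)
        assert r.specificity == 1.0

    def test_monotone_coordinates(self, final_cohort):
        df, _, _ = cohort_columns(final_cohort)
        r = roc_curve(df["aptw_mean"], df["group"], positive="HGG")
        coords = r.coordinates.sort_values("threshold")
        assert (np.diff(coords["sensitivity"]) <= 1e-12).all()
        assert (np.diff(coords["specificity"]) >= -1e-12).all()


class TestLogistic:
    def test_matches_statsmodels_on_reference_cohort(self, final_cohort):
        df, _, _ = cohort_columns(final_cohort)
        X = df[["aptw_mean", "aptw_max", "aptw_range"]].to_numpy()
        y = (df["group"] == "HGG").astype(float).to_numpy()
        ours = logistic_fit(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0, method="newton")
        assert ours.params == pytest.approx(ref.params, rel=1e-5, abs=1e-6)
        assert ours.llf == pytest.approx(ref.llf, abs=1e-8)
        assert ours.converged and not ours.separation

    def test_matches_grid_search_oracle_on_tiny_data(self):
        X = np.array([[0.1], [0.4], [0.9], [1.3], [1.8], [2.4]])
        y = np.array([0, 0, 1, 0, 1, 1], dtype=float)
        ours = logistic_fit(X, y)
        # brute-force likelihood surface on a fine grid
        b0s = np.arange(-6, 6, 0.01)
        b1s = np.arange(-6, 6, 0.01)
        B0, B1 = np.meshgrid(b0s, b1s, indexing="ij")
        eta = B0[..., None] + B1[..., None] * X.ravel()
        ll = (y * eta - np.log1p(np.exp(eta))).sum(axis=-1)
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        assert ours.intercept == pytest.approx(b0s[i], abs=0.01)
        assert ours.params[1] == pytest.approx(b1s[j], abs=0.01)

    def test_intercept_only_fits_prevalence(self):
        y = np.array([1, 1, 0, 0, 0], dtype=float)
        model = logistic_fit(np.empty((5, 0)), y)
        assert model.fitted == pytest.approx(np.full(5, 0.4), abs=1e-6)

    def test_constant_predictor_is_degenerate(self):
        with pytest.raises(SeparationError):
            logistic_fit(np.ones((6, 1)), np.array([0, 1, 0, 1, 0, 1.0]))

    def test_separation_flagged_not_silent(self):
        X = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]])
        y = np.array([0, 0, 0, 1, 1, 1], dtype=float)
        with pytest.warns(UserWarning, match="separation"):
            model = logistic_fit(X, y)
        assert model.separation

    def test_model_ll_at_least_null_ll(self, rng):
        X = rng.normal(size=(30, 2))
        y = (rng.random(30) < 0.5).astype(float)
        model = logistic_fit(X, y)
        assert model.llf >= model.llnull - 1e-10


class TestDiagnostics:
    def test_nagelkerke_null_is_zero(self):
        y = np.array([1, 0, 1, 0, 1, 0], dtype=float)
        model = logistic_fit(np.empty((6, 0)), y)
        assert nagelkerke_r2(model) == pytest.approx(0.0, abs=1e-10)

    def test_nagelkerke_approaches_one_for_separable_data(self):
        X = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]])
        y = np.array([0, 0, 0, 1, 1, 1], dtype=float)
        with pytest.warns(UserWarning):
            model = logistic_fit(X, y)
        assert nagelkerke_r2(model) > 0.95

    def test_omnibus_on_reference_cohort(self, final_cohort):
        df, _, _ = cohort_columns(final_cohort)
        X = df[["aptw_mean", "aptw_max", "aptw_range"]].to_numpy()
        y = (df["group"] == "HGG").astype(float).to_numpy()
        model = logistic_fit(X, y)
        chi2, dof, p = omnibus_test(model)
        assert dof == 3
        assert p < 0.002

    def test_hosmer_lemeshow_reduces_groups_with_warning(self):
        X = np.array([[0.0], [0.0], [1.0], [1.0], [2.0], [2.0], [3.0], [3.0]])
        y = np.array([0, 0, 0, 1, 0, 1, 1, 1], dtype=float)
        model = logistic_fit(X, y)
        with pytest.warns(UserWarning, match="reduced"):
            chi2, dof, p = hosmer_lemeshow(model, groups=10)
        assert dof >= 1
        assert 0 <= p <= 1


class TestShapiroWilk:
    def test_normal_samples_rarely_rejected(self):
        hits = 0
        for seed in range(200):
            v = np.random.default_rng(seed).normal(size=50)
            _, p = shapiro_wilk(v)
            hits += p > 0.05
        assert hits >= 180  # >= 90% of seeds

    def test_skewed_sample_rejected(self):
        v = np.random.default_rng(4).exponential(size=50)
        _, p = shapiro_wilk(v)
        assert p < 0.05

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])
        with pytest.raises(ValueError):
            shapiro_wilk(np.full(10, 3.3))


class TestSubgroupMeans:
    def test_mgmt_strata_on_reference_cohort(self, final_cohort):
        tab = subgroup_means(final_cohort, "mgmt", "mean")
        assert tab.loc["methylated", "n"] == 10
        assert tab.loc["methylated", "mean"] == pytest.approx(2.375, abs=1e-9)
        assert tab.loc["non-methylated", "n"] == 3
        assert tab.loc["non-methylated", "mean"] == pytest.approx(1.9167, abs=1e-3)
        assert bool(tab.loc["non-methylated", "insufficient_for_testing"])
        assert tab.attrs["n_unknown_dropped"] == 9

    def test_idh_strata_on_reference_cohort(self, final_cohort):
        tab = subgroup_means(final_cohort, "idh", "mean")
        assert tab.loc["wildtype", "n"] == 13
        assert tab.loc["wildtype", "mean"] == pytest.approx(2.2592, abs=1e-3)
        assert tab.loc["mutant", "n"] == 7
        assert tab.loc["mutant", "mean"] == pytest.approx(2.3014, abs=1e-3)

    def test_empty_stratum_reports_missing(self, final_cohort):
        sub = final_cohort.subset(final_cohort.df["mgmt_status"] == "methylated")
        tab = subgroup_means(sub, "mgmt", "mean")
        assert tab.loc["non-methylated", "n"] == 0
        assert np.isnan(tab.loc["non-methylated", "mean"])

    def test_unknown_stratifier_rejected(self, final_cohort):
        with pytest.raises(ValueError):
            subgroup_means(final_cohort, "braf")
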