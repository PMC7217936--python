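"""Cohort statistics against brute-force and enumeration oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from phasermt.stats import (
    analyze_cohort,
    friedman_test,
    jzs_bayes_factor,
    mann_whitney_u,
    paired_t_with_bayes,
    pairwise_bonferroni,
    pearson_r,
    phase_metric,
    prevalence,
    render_report,
    shapiro_gate,
    similarity_split,
    wilcoxon_signed_rank,
)


class TestPhaseMetric:
    def test_reference_median_rmts(self):
        # RMT medians 55.55 / 53.70 / 54.85 %MSO
        assert phase_metric(55.55, 53.70, 54.85) == pytest.approx(
            1.85 / 54.85, abs=1e-12
        )

    def test_no_effect_gives_zero(self):
        assert phase_metric(54.0, 54.0, 61.0) == 0.0

    def test_sign_convention(self):
        assert phase_metric(54.0, 56.0, 50.0) == pytest.approx(-0.04)

    def test_zero_rand_rejected(self):
        with pytest.raises(ValueError):
            phase_metric(55.0, 54.0, 0.0)


def _friedman_bruteforce(x):
    """Statistic from first principles: average ranks + tie correction."""
    n, k = x.shape
    ranks = np.array([sps.rankdata(row) for row in x])
    rj = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * (rj**2).sum() - 3 * n * (k + 1)
    ties = sum(
        (c**3 - c) for row in x for c in np.unique(row, return_counts=True)[1]
    )
    c = 1 - ties / (n * k * (k**2 - 1))
    return stat / c if c > 0 else 0.0


class TestFriedman:
    def test_identical_columns_null(self):
        x = np.tile([[3.0], [5.0], [9.0]], (1, 3))
        stat, p = friedman_test(x)
        assert stat == 0.0 and p == 1.0

    def test_strictly_ordered_maximal(self):
        x = np.tile([1.0, 2.0, 3.0], (10, 1))
        stat, _ = friedman_test(x)
        assert stat == pytest.approx(20.0, abs=1e-10)

    def test_matches_bruteforce_on_small_matrix(self, rng):
        x = rng.normal(size=(4, 3))
        stat, _ = friedman_test(x)
        assert stat == pytest.approx(_friedman_bruteforce(x), abs=1e-10)

    def test_matches_scipy(self, rng):
        x = rng.normal(size=(12, 3))
        stat, p = friedman_test(x)
        ref = sps.friedmanchisquare(*x.T)
        assert stat == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_missing_cells_rejected(self):
        x = np.array([[1.0, np.nan, 2.0], [3.0, 1.0, 2.0]])
        with pytest.raises(ValueError):
            friedman_test(x)


class TestWilcoxon:
    def test_constant_shift_is_extreme(self):
        x = np.arange(20, dtype=float)
        z, p = wilcoxon_signed_rank(x, x + 5.0)
        assert z < -3.5 and p < 0.001

    def test_antisymmetric_differences_null(self):
        x = np.zeros(6)
        y = np.array([-3.0, -2.0, -1.0, 1.0, 2.0, 3.0])
        z, p = wilcoxon_signed_rank(x, y)
        assert abs(z) < 1e-9 and p > 0.9

    def test_exact_p_matches_enumeration(self, rng):
        x = rng.normal(size=8)
        y = x + rng.normal(0.5, 1.0, size=8)
        d = x - y
        _, p = wilcoxon_signed_rank(x, y)
        # enumerate all 2^8 sign assignments of |d| ranks
        ranks = sps.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        mean_w = len(d) * (len(d) + 1) / 4
        count = 0
        for signs in itertools.product([0, 1], repeat=8):
            w = ranks[np.array(signs, dtype=bool)].sum()
            if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12:
                count += 1
        assert p == pytest.approx(count / 2**8, abs=1e-12)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank(np.ones(5), np.ones(5))


class TestMannWhitney:
    def test_exact_p_matches_enumeration(self, rng):
        x = rng.normal(size=4)
        y = rng.normal(1.0, 1.0, size=5)
        u_obs, p = mann_whitney_u(x, y)
        pooled = np.concatenate([x, y])
        m = len(x)
        us = []
        for combo in itertools.combinations(range(len(pooled)), m):
            grp = pooled[list(combo)]
            u = sum((a > b) for a in grp for b in np.delete(pooled, list(combo)))
            us.append(u)
        us = np.asarray(us, dtype=float)
        mean_u = m * (len(pooled) - m) / 2
        p_ref = np.mean(np.abs(us - mean_u) >= abs(u_obs - mean_u) - 1e-12)
        assert p == pytest.approx(p_ref, abs=1e-10)

    def test_type_i_error_rate(self):
        rejections = 0
        n_rep = 1000
        for rep in range(n_rep):
            rng = np.random.default_rng(rep)
            _, p = mann_whitney_u(rng.normal(size=10), rng.normal(size=41))
            rejections += p < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07


class TestBonferroni:
    def test_rounded_criterion(self):
        assert pairwise_bonferroni([0.016, 0.017, 0.5]) == [True, False, False]


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10, dtype=float)
        r, p = pearson_r(x, 2 * x + 1)
        assert r == pytest.approx(1.0) and p < 1e-9

    def test_constructed_orthogonality(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        y = np.array([1.0, -1.0, 0.0, -1.0, 1.0])  # even function of x
        r, _ = pearson_r(x, y)
        assert abs(r) < 1e-12

    def test_simulation_oracle(self):
        rho = 0.45
        n = 51
        rs = []
        for rep in range(300):
            rng = np.random.default_rng(rep)
            cov = [[1, rho], [rho, 1]]
            xy = rng.multivariate_normal([0, 0], cov, size=n)
            rs.append(pearson_r(xy[:, 0], xy[:, 1])[0])
        expected = rho * (1 - (1 - rho**2) / (2 * n))  # small-sample bias
        se = (1 - rho**2) / np.sqrt(n) / np.sqrt(300)
        assert abs(np.mean(rs) - expected) < 3 * se

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r(np.ones(5), np.arange(5.0))


class TestPairedTBayes:
    def test_overwhelming_evidence(self, rng):
        x = rng.normal(size=20)
        res = paired_t_with_bayes(x + 10.0, x + rng.normal(0, 0.01, 20))
        assert res.bf10 > 100.0

    def test_null_data_favours_null(self, rng):
        x = rng.normal(size=40)
        res = paired_t_with_bayes(x, x + rng.normal(0, 1.0, 40))
        assert res.df == 39
        # JZS BF under a true null is typically well below 1

    def test_bf_matches_quadrature_reference(self):
        t, n = -1.124, 51
        bf = jzs_bayes_factor(t, n)
        # independent high-resolution trapezoid quadrature in log-g
        r = np.sqrt(2) / 2
        nu = n - 1
        u = np.linspace(-12.0, 12.0, 200_001)
        g = np.exp(u)
        integrand = (
            (1 + n * g * r**2) ** -0.5
            * (1 + t**2 / ((1 + n * g * r**2) * nu)) ** (-(nu + 1) / 2)
            * (2 * np.pi) ** -0.5
            * g**-1.5
            * np.exp(-1 / (2 * g))
            * g  # Jacobian of u = log g
        )
        m1 = np.trapezoid(integrand, u)
        ref = m1 / (1 + t**2 / nu) ** (-(nu + 1) / 2)
        assert bf == pytest.approx(ref, rel=1e-4)

    def test_bf_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        for t, n in [(2.3, 30), (-1.124, 51), (0.2, 12)]:
            ref = float(pingouin.bayesfactor_ttest(t, n, paired=True))
            assert jzs_bayes_factor(t, n) == pytest.approx(ref, rel=1e-3)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            paired_t_with_bayes(np.arange(5.0), np.arange(5.0))


def _subject_df(rng, n=40, effect=1.85, bilateral_frac=1.0):
    rows = []
    for i in range(n):
        bilateral = rng.uniform() < bilateral_frac
        row = {"subject": i}
        for hemi in ("dominant", "non_dominant"):
            rand = rng.normal(55, 6)
            d = effect if (bilateral or hemi == "dominant") else -effect
            row[f"rmt_rand_{hemi}"] = rand
            row[f"rmt_neg_{hemi}"] = rand - d / 2 + rng.normal(0, 0.3)
            row[f"rmt_pos_{hemi}"] = rand + d / 2 + rng.normal(0, 0.3)
            row[f"p_pos_gt_neg_{hemi}"] = (
                0.99 if row[f"rmt_pos_{hemi}"] > row[f"rmt_neg_{hemi}"] else 0.01
            )
            row[f"snr_db_{hemi}"] = rng.uniform(5, 20)
            row[f"peak_freq_{hemi}"] = rng.uniform(9, 12)
        rows.append(row)
    return pd.DataFrame(rows)


class TestPrevalence:
    def test_full_bilateral_effect(self, rng):
        df = _subject_df(rng, n=20, bilateral_frac=1.0)
        out = prevalence(df)
        assert out["neg_lt_pos_both_frac"] == 1.0

    def test_ties_do_not_count(self):
        df = pd.DataFrame([{
            "rmt_neg_dominant": 55.0, "rmt_pos_dominant": 55.0,
            "rmt_neg_non_dominant": 54.0, "rmt_pos_non_dominant": 56.0,
            "p_pos_gt_neg_dominant": 0.5, "p_pos_gt_neg_non_dominant": 0.9,
        }])
        out = prevalence(df)
        assert out["neg_lt_pos_dominant"] == 0
        assert out["neg_lt_pos_non_dominant"] == 1
        assert out["neg_lt_pos_both"] == 0

    def test_recovers_constructed_fraction(self):
        rng = np.random.default_rng(0)
        df = _subject_df(rng, n=400, bilateral_frac=0.73)
        out = prevalence(df)
        se = np.sqrt(0.73 * 0.27 / 400)
        assert abs(out["neg_lt_pos_both_frac"] - 0.73) < 3 * se


class TestSimilaritySplit:
    def test_concordant_probabilities_similar(self, rng):
        df = _subject_df(rng, n=10)
        df["p_pos_gt_neg_dominant"] = 0.9
        df["p_pos_gt_neg_non_dominant"] = 0.9
        out = similarity_split(df)
        assert out["n_dissimilar"] == 0

    def test_straddling_probabilities_dissimilar(self, rng):
        df = _subject_df(rng, n=10)
        df["p_pos_gt_neg_dominant"] = 0.9
        df["p_pos_gt_neg_non_dominant"] = [0.1] * 5 + [0.9] * 5
        out = similarity_split(df)
        assert out["n_dissimilar"] == 5
        assert np.isfinite(out["u_rmt"]) and 0 <= out["p_rmt"] <= 1


class TestShapiroGate:
    def test_normal_data_routes_parametric(self):
        hits = sum(
            not shapiro_gate(np.random.default_rng(s).normal(size=50))["nonparametric"]
            for s in range(100)
        )
        assert hits >= 85  # ~95% expected at the 5% level

    def test_skewed_data_routes_nonparametric(self):
        hits = sum(
            shapiro_gate(np.random.default_rng(s).exponential(size=50))["nonparametric"]
            for s in range(100)
        )
        assert hits >= 90

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            shapiro_gate(np.full(10, 3.0))


class TestAnalyzeCohort:
    def test_strong_effect_cohort(self, rng):
        df = _subject_df(rng, n=40, effect=1.85)
        res = analyze_cohort(df)
        for hemi in ("dominant", "non_dominant"):
            assert res.friedman[hemi]["p"] < 0.001
            assert res.pairwise[hemi]["neg_vs_pos"]["significant"]
            assert res.phase_summary[hemi]["mean"] > 0
        assert res.prevalence["n_subjects"] == 40
        report = render_report(res)
        assert "Friedman" in report and "PHASE" in report

    def test_familywise_error_under_null(self):
        """Bonferroni-corrected pairwise procedure keeps familywise error
        at or below ~5% on null cohorts."""
        fw = 0
        n_rep = 300
        for rep in range(n_rep):
            rng = np.random.default_rng(rep)
            x = rng.normal(55, 6, size=(12, 3))
            ps = []
            for a, b in ((0, 1), (0, 2), (1, 2)):
                _, p = wilcoxon_signed_rank(x[:, a], x[:, b])
                ps.append(p)
            fw += any(pairwise_bonferroni(ps))
        assert fw / n_rep <= 0.07
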