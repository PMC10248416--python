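"""Group comparison, chi-square, logistic combination, ROC/Youden, DeLong and
the binormal analytic AUC, each checked against an independent oracle."""
import numpy as np
import pytest
from scipy import stats as sps

from vetcdiff.exceptions import DegenerateDataError, DomainError
from vetcdiff.stats import (
    binormal_auc,
    chi_square_categorical,
    delong_test,
    fit_logistic,
    operating_point,
    roc_analysis,
    select_and_compare,
)


class TestSelectAndCompare:
    def test_identical_samples_p_one(self):
        r = select_and_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.p_value == pytest.approx(1.0)

    def test_normal_data_selects_t_test(self, rng):
        r = select_and_compare(rng.normal(0, 1, 50), rng.normal(0.2, 1, 50))
        assert r.test_used == "t_test"

    def test_lognormal_selects_mann_whitney(self, rng):
        """Shapiro rejects log-normal data at n = 46 nearly always."""
        selected = [
            select_and_compare(rng.lognormal(0, 1, 46),
                               rng.normal(1.6, 1, 40)).test_used
            for _ in range(20)
        ]
        assert selected.count("mann_whitney") >= 19

    def test_null_type_one_error(self, rng):
        """p < 0.05 in ~5% of null replications (both groups identical
        normals; 1000 desk-scale reps)."""
        hits = sum(
            select_and_compare(rng.normal(0, 1, 46),
                               rng.normal(0, 1, 40)).p_value < 0.05
            for _ in range(1000)
        )
        assert 0.03 <= hits / 1000 <= 0.07

    def test_too_small_groups(self):
        with pytest.raises(DomainError):
            select_and_compare([1.0, 2.0], [1.0, 2.0, 3.0])


class TestChiSquare:
    def test_proportional_table_p_one(self):
        stat, p, _ = chi_square_categorical([[10, 20], [5, 10]])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_yates_applied_when_expected_small(self):
        # margins 9/9 over n=18: every expected count is 4.5 < 5
        stat_c, p_c, corr = chi_square_categorical([[1, 8], [8, 1]])
        assert corr
        stat_u, _, _, _ = sps.chi2_contingency([[1, 8], [8, 1]],
                                               correction=False)
        assert stat_c < stat_u  # Yates shrinks the statistic

    def test_zero_margin_degenerate(self):
        with pytest.raises(DegenerateDataError):
            chi_square_categorical([[0, 0], [5, 7]])


class TestLogistic:
    def test_separation_flagged(self, rng):
        x = rng.normal(0, 1, (100, 1))
        y = (x[:, 0] > 0).astype(int)
        m = fit_logistic(x, y)
        assert m.separation
        assert not m.converged

    def test_null_coefficient_near_zero(self, rng):
        x = rng.normal(0, 1, (2000, 1))
        y = rng.integers(0, 2, 2000)
        m = fit_logistic(x, y)
        se_approx = 2 / np.sqrt(2000)
        assert abs(m.coefficients[0]) < 3 * se_approx
        assert m.score_norm < 1e-6

    def test_effect_directions_from_cohort_distributions(self):
        """DKI_K and CTRW_alpha simulated from the published group
        distributions both get positive logistic weights."""
        rng = np.random.default_rng(11)
        k = np.r_[rng.normal(0.55, 0.08, 46), rng.normal(0.61, 0.09, 40)]
        a = np.r_[rng.normal(0.87, 0.07, 46), rng.normal(0.91, 0.04, 40)]
        y = np.r_[np.zeros(46), np.ones(40)]
        m = fit_logistic(np.column_stack([k, a]), y,
                         names=["DKI_K", "CTRW_alpha"])
        assert m.converged
        assert m.coefficients[0] > 0 and m.coefficients[1] > 0

    def test_probability_monotone_in_score(self, rng):
        x = rng.normal(0, 1, (200, 1))
        y = (rng.random(200) < 1 / (1 + np.exp(-x[:, 0]))).astype(int)
        m = fit_logistic(x, y)
        order = np.argsort(x[:, 0])
        assert np.all(np.diff(m.probabilities[order]) >= 0)


class TestRoc:
    def test_perfect_ranking(self):
        r = roc_analysis([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert r.auc == 1.0
        assert r.youden_index == pytest.approx(1.0)

    def test_all_ties_auc_half(self):
        r = roc_analysis(np.ones(20), np.r_[np.zeros(10), np.ones(10)])
        assert r.auc == pytest.approx(0.5)

    def test_auc_equals_brute_force_u(self, rng):
        """AUC == pairwise comparison count / (n_pos·n_neg), ties = 1/2."""
        for n in (20, 80, 200):
            s = np.round(rng.normal(0, 1, n), 1)
            y = (rng.random(n) < 0.45).astype(int)
            s[y == 1] += rng.normal(0.5, 0.5, int(y.sum()))
            s = np.round(s, 1)
            r = roc_analysis(s, y)
            pos, neg = s[y == 1], s[y == 0]
            brute = np.mean((pos[:, None] > neg[None, :]) +
                            0.5 * (pos[:, None] == neg[None, :]))
            assert r.auc == pytest.approx(brute, abs=1e-12)

    def test_youden_and_accuracy_identities(self, rng):
        s = rng.normal(0, 1, 86)
        y = np.r_[np.zeros(46), np.ones(40)]
        s[y == 1] += 0.6
        r = roc_analysis(s, y)
        assert r.youden_index == pytest.approx(
            r.sens_at_cutoff + r.spec_at_cutoff - 1, abs=1e-12)
        assert r.accuracy_at_cutoff == pytest.approx(
            (r.sens_at_cutoff * 40 + r.spec_at_cutoff * 46) / 86, abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        s = rng.normal(0, 1, 100)
        y = (rng.random(100) < 0.4).astype(int)
        s[y == 1] += 0.8
        r1 = roc_analysis(s, y)
        r2 = roc_analysis(np.exp(2 * s), y)
        assert r2.auc == pytest.approx(r1.auc, abs=1e-12)
        assert r2.youden_index == pytest.approx(r1.youden_index, abs=1e-12)

    def test_published_operating_points(self):
        """The reported operating points satisfy the Youden and accuracy
        identities: e.g. sens 77.5%, spec 54.3% -> youden 0.318, acc 65.1%."""
        youden, acc = operating_point(0.775, 0.543, 40, 46)
        assert round(youden, 3) == 0.318
        assert round(100 * acc, 1) == 65.1

    def test_one_class_raises(self):
        with pytest.raises(DomainError):
            roc_analysis([1, 2, 3], [1, 1, 1])


class TestDeLong:
    def test_identical_scores(self, rng):
        s = rng.normal(0, 1, 60)
        y = (rng.random(60) < 0.5).astype(int)
        s[y == 1] += 0.5
        d = delong_test(s, s, y)
        assert d.auc_difference == 0.0
        assert d.p_value == 1.0
        assert d.degenerate

    def test_matches_bootstrap_on_fixed_cohort(self):
        """Paired-bootstrap p-value for the AUC difference agrees with the
        DeLong p within 0.03 on a fixed simulated cohort."""
        rng = np.random.default_rng(17)
        n = 120
        y = np.r_[np.zeros(60), np.ones(60)].astype(int)
        base = rng.normal(0, 1, n) + 0.7 * y
        sa = base + rng.normal(0, 0.6, n)
        sb = base + rng.normal(0, 0.9, n)
        d = delong_test(sa, sb, y)
        diffs = []
        idx_all = np.arange(n)
        for _ in range(4000):
            idx = rng.choice(idx_all, n, replace=True)
            if len(np.unique(y[idx])) < 2:
                continue
            ra = roc_analysis(sa[idx], y[idx])
            rb = roc_analysis(sb[idx], y[idx])
            diffs.append(ra.auc - rb.auc)
        diffs = np.asarray(diffs)
        # two-sided bootstrap p for H0: difference = 0
        p_boot = 2 * min((diffs <= 0).mean(), (diffs >= 0).mean())
        assert d.p_value == pytest.approx(p_boot, abs=0.03)

    def test_variance_positive_for_distinct_scores(self, rng):
        y = (rng.random(100) < 0.5).astype(int)
        sa = rng.normal(0, 1, 100) + 0.4 * y
        sb = rng.normal(0, 1, 100) + 0.4 * y
        d = delong_test(sa, sb, y)
        assert d.variance > 0
        assert 0 <= d.p_value <= 1


class TestBinormalAuc:
    def test_equal_means_half(self):
        assert binormal_auc(1.0, 0.5, 1.0, 0.7) == pytest.approx(0.5)

    def test_published_kurtosis_distributions(self):
        """Φ(0.06/√(0.08²+0.09²)) ≈ 0.691, the analytic counterpart of the
        reported DKI_K AUC 0.678."""
        assert binormal_auc(0.55, 0.08, 0.61, 0.09) == pytest.approx(0.691,
                                                                     abs=5e-4)

    def test_zero_sd_limit(self):
        assert binormal_auc(0.0, 0.0, 1.0, 0.0) == 1.0

    def test_agrees_with_empirical_auc(self, rng):
        """Monte-Carlo AUC of 10⁶ simulated pairs within 0.002."""
        neg = rng.normal(0.55, 0.08, 10 ** 6)
        pos = rng.normal(0.61, 0.09, 10 ** 6)
        emp = np.mean(pos > neg)
        assert binormal_auc(0.55, 0.08, 0.61, 0.09) == pytest.approx(emp,
                                                                     abs=0.002)
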