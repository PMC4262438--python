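"""Prevalence estimates and group comparisons on error flags."""

import numpy as np
import pytest
from scipy import special

from reportcheck import (compare_groups, conditional_gross_given_error,
                         estimate_article_rate, estimate_p_level_rate)
from reportcheck.prevalence import SeparationWarning


def logit_wald_ci(k, n):
    """Textbook closed form: logit +- 1.96 / sqrt(n p (1-p)), back-transformed."""
    p = k / n
    se = 1.0 / np.sqrt(n * p * (1 - p))
    lo = special.expit(special.logit(p) - 1.959963984540054 * se)
    hi = special.expit(special.logit(p) + 1.959963984540054 * se)
    return lo, hi


class TestArticleRate:
    def test_probability_equals_sample_proportion(self):
        flags = [True] * 63 + [False] * 37
        est = estimate_article_rate(flags)
        assert est.probability == pytest.approx(0.630, abs=1e-9)
        assert est.model == "simple_logit" and est.n == 100

    def test_ci_matches_closed_form_logit_wald(self):
        flags = [True] * 271 + [False] * 159   # 271 / 430 = 63.0%
        est = estimate_article_rate(flags)
        lo, hi = logit_wald_ci(271, 430)
        assert est.probability == pytest.approx(271 / 430, abs=1e-9)
        assert est.ci_lo == pytest.approx(lo, abs=1e-6)
        assert est.ci_hi == pytest.approx(hi, abs=1e-6)

    def test_separation_returns_degenerate_ci_with_warning(self):
        with pytest.warns(SeparationWarning):
            est = estimate_article_rate([False] * 50)
        assert est.probability == 0.0
        assert est.ci_lo == est.ci_hi == 0.0

    def test_proportion_identity_over_random_draws(self, rng):
        for _ in range(10):
            n = int(rng.integers(10, 400))
            k = int(rng.integers(1, n))
            flags = [True] * k + [False] * (n - k)
            assert estimate_article_rate(flags).probability == pytest.approx(k / n, abs=1e-8)


class TestPLevelRate:
    def test_collapses_to_pooled_rate_without_heterogeneity(self, rng):
        gid = np.repeat(np.arange(200), 10)
        y = rng.random(2000) < 0.10
        est = estimate_p_level_rate(y, gid)
        assert est.model == "multilevel_logit"
        assert est.random_intercept_sd < 0.3
        assert est.probability == pytest.approx(y.mean(), abs=0.01)

    def test_single_report_per_article_matches_article_rate(self, rng):
        y = rng.random(400) < 0.3
        simple = estimate_article_rate(y)
        multi = estimate_p_level_rate(y, np.arange(400))
        assert multi.probability == pytest.approx(simple.probability, abs=0.01)

    def test_reports_marginal_probability(self, rng):
        gid = np.repeat(np.arange(150), 12)
        u = rng.normal(0, 1.2, 150)
        y = rng.random(len(gid)) < special.expit(-2.2 + u[gid])
        est = estimate_p_level_rate(y, gid)
        # With heterogeneity, the population-averaged rate exceeds the
        # typical-article rate on the low side of one half.
        assert est.marginal > est.probability


class TestCompareGroups:
    def test_detects_large_group_difference(self, rng):
        n_per = 500
        gid = np.concatenate([np.arange(50).repeat(10), (50 + np.arange(50)).repeat(10)])
        labels = np.array(["lo"] * n_per + ["hi"] * n_per)
        y = np.concatenate([rng.random(n_per) < 0.05, rng.random(n_per) < 0.25])
        comp = compare_groups(y, gid, labels, n_planned_tests=6)
        assert comp.df == 1
        assert comp.p_value < comp.alpha_corrected
        assert comp.alpha_corrected == pytest.approx(0.05 / 6)
        assert comp.group_probabilities["hi"] > comp.group_probabilities["lo"]

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([True, False], [1, 2], ["a", "a"])

    def test_type_one_error_control_under_null(self, rng):
        """Omnibus LR test holds its nominal level on null data."""
        rejections = 0
        n_rep = 120
        for _ in range(n_rep):
            gid = np.arange(40).repeat(6)
            labels = np.where(gid < 20, "a", "b")
            y = rng.random(240) < 0.15
            comp = compare_groups(y, gid, labels)
            rejections += comp.p_value < 0.05
        # Nominal 5%: binomial(120, .05) three-sigma band.
        assert rejections <= 14


class TestConditionalGross:
    def test_invariant_breach_rejected(self):
        with pytest.raises(ValueError, match="invariant"):
            conditional_gross_given_error([False], [True], [1], ["a"])

    def test_no_errors_is_explicit_diagnostic(self):
        with pytest.raises(ValueError, match="empty subset"):
            conditional_gross_given_error([False, False], [False, False],
                                          [1, 2], ["a", "b"])

    def test_extreme_contrast_detected(self, rng):
        # All errors gross in one group, none in the other.
        n = 400
        gid = np.concatenate([np.arange(40).repeat(10), (40 + np.arange(40)).repeat(10)])
        labels = np.array(["g1"] * n + ["g2"] * n)
        err = rng.random(2 * n) < 0.5
        gross = err & (labels == "g1")
        comp = conditional_gross_given_error(err, gross, gid, labels)
        assert comp.p_value < 0.05 / 6

    def test_identical_gross_fraction_not_flagged(self, rng):
        n = 600
        gid = np.concatenate([np.arange(60).repeat(10), (60 + np.arange(60)).repeat(10)])
        labels = np.array(["g1"] * n + ["g2"] * n)
        err = rng.random(2 * n) < 0.5
        gross = err & (rng.random(2 * n) < 0.3)
        comp = conditional_gross_given_error(err, gross, gid, labels)
        assert comp.p_value > 0.05 / 6
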