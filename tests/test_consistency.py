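"""Consistency classification: regions, rescue, gross errors, oracle parity."""

import numpy as np
import pytest

from reportcheck import (classify, p_interval_from_stat, reported_p_region,
                         scan_text)
from .oracles import bruteforce_classify, random_reports
from .test_recompute import make_report


def classified(text, **overrides):
    report = scan_text(text, "a")[0]
    for key, val in overrides.items():
        setattr(report, key, val)
    return classify(report, p_interval_from_stat(report))


class TestReportedPRegion:
    def test_eq_rounding_band(self):
        region = reported_p_region("eq", 0.03, 2)
        assert (region.lo, region.hi) == (pytest.approx(0.025), pytest.approx(0.035))
        assert not region.lo_open and not region.hi_open

    def test_lt_is_strict(self):
        region = reported_p_region("lt", 0.05, 2)
        assert (region.lo, region.hi) == (0.0, 0.05)
        assert region.hi_open

    def test_gt_and_ns(self):
        gt = reported_p_region("gt", 0.05, 2)
        assert gt.lo_open and gt.lo == 0.05 and gt.hi == 1.0
        ns = reported_p_region("ns", None)
        assert ns.lo_open and ns.lo == 0.05 and ns.hi == 1.0

    def test_p_equals_zero_print(self):
        """"p = .000" claims only that p rounds to zero at three decimals."""
        region = reported_p_region("eq", 0.0, 3)
        assert (region.lo, region.hi) == (0.0, 0.0005)
        assert region.hi_open
        # Brute-force cross-check: v is in the region iff it prints as .000
        # (grid offset off the exact rounding tie at .0005).
        for v in np.arange(0.000025, 0.002, 0.00005):
            assert region.overlaps(v, v) == (round(v, 3) == 0.0)

    def test_rejects_p_outside_unit_interval(self):
        with pytest.raises(ValueError):
            reported_p_region("eq", 1.3, 2)
        with pytest.raises(ValueError):
            reported_p_region("eq", None, 2)


class TestClassify:
    def test_flagrant_mismatch_is_gross(self):
        # Reported significant below .03; recomputed ~ .47: decision flips.
        res = classified("F(1, 20) = 0.54, p < .03")
        assert res.error and res.gross_error

    def test_close_agreement_is_consistent(self):
        res = classified("F(1, 20) = 9.5, p < .006")
        assert res.consistent and not res.error and not res.gross_error

    def test_exact_identity_case(self):
        res = classified("t(20) = 0.00, p = 1.00")
        assert res.consistent

    def test_one_tailed_rescue(self):
        # Two-tailed p for t(28) = 1.80 is ~ .082; halved it falls in the
        # .04 rounding band, so the one-tailed flag rescues the report.
        res = classified("t(28) = 1.80, p = .04", one_tailed=True)
        assert res.consistent and res.one_tailed_applied
        res2 = classified("t(28) = 1.80, p = .04", one_tailed=False)
        assert res2.error and not res2.one_tailed_applied

    def test_rescue_not_applied_to_one_sided_families(self):
        res = classified("F(1, 20) = 0.54, p = .24", one_tailed=True)
        assert res.error and not res.one_tailed_applied

    def test_p_at_threshold_with_unknown_wording_never_gross(self):
        # Recomputed ~ .47, reported exactly .05: an error, but whether the
        # authors claimed significance is undeterminable without wording.
        res = classified("F(1, 20) = 0.54, p = .05")
        assert res.report.sig_wording == "unknown"
        assert res.error and not res.gross_error

    def test_p_at_threshold_with_wording_can_be_gross(self):
        res = classified("The effect was significant, F(1, 20) = 0.54, p = .05.")
        assert res.report.sig_wording == "significant"
        assert res.error and res.gross_error

    def test_gross_requires_entire_interval_across_threshold(self):
        # Statistic rounding straddling alpha must not manufacture a gross
        # error: t(30) = 2.04 at one decimal spans p ~ .03-.08.
        report = make_report("t", 2.0, 30, stat_dec=1)
        report.p_comparator, report.p_reported, report.p_decimals = "eq", 0.50, 2
        res = classify(report, p_interval_from_stat(report))
        assert res.error and not res.gross_error

    def test_alpha_is_configurable(self):
        report = scan_text("F(1, 20) = 0.54, p < .03", "a")[0]
        iv = p_interval_from_stat(report)
        res_10 = classify(report, iv, alpha=0.47)
        # At alpha = .47 the recomputed interval straddles alpha: not gross.
        assert res_10.error and not res_10.gross_error

    def test_gross_implies_error_on_random_stream(self):
        for report in random_reports(400, seed=21):
            res = classify(report, p_interval_from_stat(report))
            assert res.error == (not res.consistent)
            assert not res.gross_error or res.error
            assert not res.one_tailed_applied or report.one_tailed

    def test_agrees_with_bruteforce_oracle(self):
        """Interval logic vs dense grid enumeration, 300 randomized reports."""
        for report in random_reports(300, seed=77):
            res = classify(report, p_interval_from_stat(report))
            expected = bruteforce_classify(report)
            assert (res.consistent, res.error, res.gross_error) == expected, report

    def test_determinism(self):
        report = scan_text("t(28) = 1.80, p = .04", "a")[0]
        iv = p_interval_from_stat(report)
        rows = {tuple(classify(report, iv).to_row().items()) for _ in range(5)}
        assert len(rows) == 1
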