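"""Extraction grammar: APA dialects, context heuristics, validation."""

import pytest

from reportcheck import (Validation, detect_sidedness, detect_sig_wording,
                         scan_text, validate_report)


class TestScanText:
    def test_intro_snippet_yields_three_f_reports(self, intro_snippet):
        reports = scan_text(intro_snippet, "intro")
        assert len(reports) == 3
        assert [r.test_family for r in reports] == ["F", "F", "F"]
        assert all(r.df1 == 1 and r.df2 == 20 for r in reports)
        assert [r.stat_value for r in reports] == [9.5, 0.54, 6.8]
        assert all(r.p_comparator == "lt" for r in reports)
        assert [r.p_reported for r in reports] == [0.006, 0.03, 0.02]

    def test_empty_document(self):
        assert list(scan_text("", "empty")) == []

    @pytest.mark.parametrize("text,family,df1,df2,stat,p_comp,p", [
        ("t(28) = 1.80, p = .04", "t", 28, None, 1.80, "eq", 0.04),
        ("t(24.3) = 2.10, p < 0.05", "t", 24.3, None, 2.10, "lt", 0.05),
        ("F(1,20) = 9.5, p<.006", "F", 1, 20, 9.5, "lt", 0.006),
        ("χ²(3) = 11.27, p = .010", "chi2", 3, None, 11.27, "eq", 0.010),
        ("chi2(2, N = 170) = 8.1, p = .017", "chi2", 2, None, 8.1, "eq", 0.017),
        ("chi-square(4) = 9.49, p > .05", "chi2", 4, None, 9.49, "gt", 0.05),
        ("Wald χ2(1) = 4.0, p = .046", "chi2", 1, None, 4.0, "eq", 0.046),
        ("Wald Z = 2.01, p = .044", "Z", None, None, 2.01, "eq", 0.044),
        ("r(58) = −.27, p = .04", "r", 58, None, -0.27, "eq", 0.04),
        ("r(58) = -0.27, p = .04", "r", 58, None, -0.27, "eq", 0.04),
        ("Z = 1.96, p = .05", "Z", None, None, 1.96, "eq", 0.05),
        ("t(30) = −1.2, p > .05", "t", 30, None, -1.2, "gt", 0.05),
    ])
    def test_dialects(self, text, family, df1, df2, stat, p_comp, p):
        reports = scan_text(f"We found {text} in study 1.", "a")
        assert len(reports) == 1
        r = reports[0]
        assert r.test_family == family
        assert r.df1 == df1 and r.df2 == df2
        assert r.stat_value == pytest.approx(stat)
        assert r.p_comparator == p_comp
        assert r.p_reported == pytest.approx(p)

    @pytest.mark.parametrize("text,p_dec,stat_dec", [
        ("t(28) = 1.80, p = .04", 2, 2),
        ("t(28) = 1.8, p = .040", 3, 1),
        ("F(2, 40) = 3, p = .0600", 4, 0),
    ])
    def test_printed_decimals_recorded(self, text, p_dec, stat_dec):
        r = scan_text(text, "a")[0]
        assert r.p_decimals == p_dec
        assert r.stat_decimals == stat_dec

    def test_ns_forms(self):
        for tok in ["ns", "n.s."]:
            r = scan_text(f"t(30) = 1.2, {tok}", "a")[0]
            assert r.p_comparator == "ns"
            assert r.p_reported is None

    def test_chi2_sample_size_annotation_stored(self):
        r = scan_text("χ2(2, N = 170) = 8.1, p = .017", "a")[0]
        assert r.sample_n == 170

    def test_effect_size_between_stat_and_p_is_skipped(self):
        text = "A main effect emerged, F(1, 46) = 8.41, ηp2 = .16, p = .006."
        result = scan_text(text, "a")
        assert list(result) == []
        assert len(result.skipped) == 1
        assert result.skipped[0].reason == "tokens_between_stat_and_p"

    def test_bare_wald_is_skipped(self):
        result = scan_text("The coefficient was reliable, Wald = 5.2, p = .02.", "a")
        assert list(result) == []
        assert any(s.reason == "bare_wald" for s in result.skipped)

    def test_document_order_and_idempotence(self, intro_snippet):
        first = scan_text(intro_snippet, "x")
        second = scan_text(intro_snippet, "x")
        starts = [r.span_start for r in first]
        assert starts == sorted(starts) and len(set(starts)) == len(starts)
        assert [r.to_row() for r in first] == [r.to_row() for r in second]

    def test_empty_article_id_rejected(self):
        with pytest.raises(ValueError):
            scan_text("t(10) = 1.0, p = .33", "")


class TestSidedness:
    def test_adjacent_keyword(self):
        text = "The difference held, t(28) = 1.80, p = .04 (one-tailed), as predicted."
        r = scan_text(text, "a")[0]
        assert r.one_tailed is True

    def test_absent_keyword(self):
        r = scan_text("We observed t(28) = 1.80, p = .04 in study 2.", "a")[0]
        assert r.one_tailed is False

    @pytest.mark.parametrize("gap,expected", [(199, True), (200, True), (201, False)])
    def test_window_boundary(self, gap, expected):
        prefix = "We observed t(28) = 1.80, p = .04"
        text = prefix + "x" * gap + "directional"
        r = scan_text(text, "a", annotate=False)[0]
        assert detect_sidedness(text, r, window=200) is expected

    @pytest.mark.parametrize("kw", ["one-tailed", "One-Sided", "directional", "one tailed"])
    def test_keyword_variants(self, kw):
        text = f"A {kw} test gave t(28) = 1.80, p = .04."
        assert scan_text(text, "a")[0].one_tailed is True


class TestSigWording:
    @pytest.mark.parametrize("text,expected", [
        ("The effect was significant, F(1, 46) = 4.20, p = .05.", "significant"),
        ("The difference was not significant, t(30) = 1.2, p = .24.", "nonsignificant"),
        ("We observed t(30) = 1.2, p = .24.", "unknown"),
        ("The groups did not differ significantly, t(30) = 1.2, p = .24.", "significant"),
        ("There was no significant difference, t(30) = 1.2, p = .24.", "nonsignificant"),
    ])
    def test_wording(self, text, expected):
        assert scan_text(text, "a")[0].sig_wording == expected

    def test_wording_is_sentence_local(self):
        text = ("The first effect was significant. "
                "We then observed t(30) = 1.2, p = .24 in the follow-up.")
        assert scan_text(text, "a")[0].sig_wording == "unknown"


class TestValidation:
    def test_p_above_one_excluded(self):
        r = scan_text("t(30) = 1.2, p = 1.3", "a")[0]
        assert validate_report(r) is Validation.INVALID_P_ABOVE_ONE

    def test_power_of_ten_notation_unsupported(self):
        r = scan_text("t(48) = 5.1, p = 3.2 × 10−5 for this contrast.", "a")[0]
        assert validate_report(r) is Validation.UNSUPPORTED_NOTATION

    def test_plain_report_valid(self):
        r = scan_text("t(30) = 1.2, p = .24", "a")[0]
        assert validate_report(r) is Validation.VALID

    def test_out_of_support_statistics_rejected(self):
        r = scan_text("F(1, 20) = −0.54, p < .03", "a")[0]
        assert validate_report(r) is Validation.UNSUPPORTED_NOTATION
        r = scan_text("r(20) = 1.27, p < .03", "a")[0]
        assert validate_report(r) is Validation.UNSUPPORTED_NOTATION
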