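"""Extraction of APA-style NHST results from article text.

The APA Publication Manual prescribes a compact, machine-readable format for
null-hypothesis significance tests, e.g. ``t(28) = 2.20, p = .036`` or
``F(1, 20) = 9.5, p < .006``.  This module scans plain text for such results
and parses each into a :class:`StatReport`, together with context heuristics:
whether the surrounding text marks the test as one-tailed, and whether the
sentence describes the result as significant.

Supported test families are Student *t*, *F*, chi-square, Pearson *r* and
standard-normal *Z*.  "Wald chi2(df) = x" is read as a chi-square statistic and
"Wald Z = x" as a Z statistic; a bare "Wald = x" carries no distributional
information and is skipped with a diagnostic.  Results where extra tokens such
as effect sizes sit between the test statistic and the p-value (e.g.
``F(1, 46) = 8.41, eta2 = .16, p = .006``) are not parseable under the grammar
and are recorded as skipped candidates rather than matched.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, List, Optional

__all__ = [
    "StatReport",
    "SkippedCandidate",
    "ScanResult",
    "Validation",
    "scan_text",
    "detect_sidedness",
    "detect_sig_wording",
    "validate_report",
    "REPORT_COLUMNS",
]

REPORT_COLUMNS = [
    "article_id", "study_id", "family", "df1", "df2", "n",
    "stat_comp", "stat", "stat_dec", "p_comp", "p", "p_dec",
    "one_tailed", "sig_wording", "span_start", "span_end", "raw",
]

_CMP_MAP = {"=": "eq", "<": "lt", ">": "gt"}

# A number, with or without integer part ("0.54", ".54", "12").
_NUM = r"(?:\d+\.\d+|\.\d+|\d+)"
# ASCII hyphen or Unicode minus sign.
_SNUM = r"[−\-]?" + _NUM

_FAMILY = (
    r"(?:"
    r"(?P<fam_t>\bt)\s*\(\s*(?P<t_df>\d+(?:\.\d+)?)\s*\)"
    r"|(?P<fam_F>\bF)\s*\(\s*(?P<f_df1>\d+(?:\.\d+)?)\s*,\s*(?P<f_df2>\d+(?:\.\d+)?)\s*\)"
    r"|(?:Wald\s+)?(?P<fam_c>(?:[χΧ]\s?(?:2|²))|[Cc]hi2|[Cc]hi-squared?)"
    r"\s*\(\s*(?P<c_df>\d+(?:\.\d+)?)\s*(?:,\s*N\s*=\s*(?P<c_n>\d+)\s*)?\)"
    r"|(?P<fam_r>\br)\s*\(\s*(?P<r_df>\d+(?:\.\d+)?)\s*\)"
    r"|(?:Wald\s+)?(?P<fam_Z>\bZ\b)"
    r")"
)

_STAT_PART = r"\s*(?P<stat_comp>[=<>])\s*(?P<stat>" + _SNUM + r")"

# Power-of-ten notation after a p-value ("3.2 × 10−5", "1e-4") is captured
# into the span so that validation can reject it, mirroring the documented
# inability to read "p times 10 to the power of".
_POW10 = r"(?:\s*[×x\*]\s*10(?:\s*\^?\s*[−\-]?\d+)?|[eE][−\-]?\d+)"

_P_PART = (
    r"\s*,\s*(?:(?P<ns>ns\b|n\.s\.)"
    r"|p\s*(?P<p_comp>[=<>])\s*(?P<p>" + _NUM + r")(?P<pow10>" + _POW10 + r")?)"
)

_RESULT_RE = re.compile(_FAMILY + _STAT_PART + _P_PART)

# Looser pattern used only to diagnose candidates that the grammar rejects.
_CANDIDATE_RE = re.compile(_FAMILY + _STAT_PART + r"\s*,")
_BARE_WALD_RE = re.compile(r"\bWald\s*[=<>]\s*" + _SNUM)
_NEARBY_P_RE = re.compile(r"\bp\s*[=<>]")

_SIDEDNESS_RE = re.compile(r"one[-\s]?tailed|one[-\s]?sided|directional", re.IGNORECASE)
_NEGATED_SIG_RE = re.compile(
    r"\b(?:not\s+significant|non-significant|nonsignificant|no\s+significant)", re.IGNORECASE
)
_SIG_RE = re.compile(r"\bsignificant(?:ly)?\b", re.IGNORECASE)
_SENTENCE_SPLIT_RE = re.compile(r"[.!?](?=\s)")
_POW10_RAW_RE = re.compile(r"(?:[×x\*]\s*10|\d[eE][−\-]?\d)")


class Validation(Enum):
    """Outcome of pre-checking a parsed report before recomputation."""

    VALID = "valid"
    INVALID_P_ABOVE_ONE = "invalid_p_above_one"
    UNSUPPORTED_NOTATION = "unsupported_notation"


@dataclass
class StatReport:
    """One APA-formatted test result extracted from an article.

    ``stat_decimals`` / ``p_decimals`` record the printed precision, which
    drives the rounding-interval logic downstream.  Comparators use the codes
    ``eq``/``lt``/``gt`` (and ``ns`` for p reported only as non-significant).
    """

    article_id: str
    test_family: str            # 't' | 'F' | 'chi2' | 'r' | 'Z'
    stat_comparator: str        # 'eq' | 'lt' | 'gt'
    stat_value: float
    stat_decimals: int
    p_comparator: str           # 'eq' | 'lt' | 'gt' | 'ns'
    span_start: int
    span_end: int
    raw: str
    study_id: Optional[str] = None
    df1: Optional[float] = None
    df2: Optional[float] = None
    sample_n: Optional[int] = None
    p_reported: Optional[float] = None
    p_decimals: int = 0
    one_tailed: bool = False
    sig_wording: str = "unknown"  # 'significant' | 'nonsignificant' | 'unknown'

    def to_row(self) -> dict:
        """Serialize to the flat column layout used in per-result tables."""
        return {
            "article_id": self.article_id,
            "study_id": self.study_id,
            "family": self.test_family,
            "df1": self.df1,
            "df2": self.df2,
            "n": self.sample_n,
            "stat_comp": self.stat_comparator,
            "stat": self.stat_value,
            "stat_dec": self.stat_decimals,
            "p_comp": self.p_comparator,
            "p": self.p_reported,
            "p_dec": self.p_decimals,
            "one_tailed": self.one_tailed,
            "sig_wording": self.sig_wording,
            "span_start": self.span_start,
            "span_end": self.span_end,
            "raw": self.raw,
        }

    def copy(self, **changes) -> "StatReport":
        return replace(self, **changes)


@dataclass(frozen=True)
class SkippedCandidate:
    """A near-miss the scanner refused to parse, kept for diagnostics."""

    offset: int
    raw: str
    reason: str  # 'tokens_between_stat_and_p' | 'no_p_value' | 'bare_wald'


class ScanResult(List[StatReport]):
    """Ordered reports from one document plus skipped-candidate diagnostics."""

    def __init__(self, reports: Iterable[StatReport] = (), skipped: Iterable[SkippedCandidate] = ()):
        super().__init__(reports)
        self.skipped: List[SkippedCandidate] = list(skipped)


def _decimals(token: str) -> int:
    return len(token.split(".", 1)[1]) if "." in token else 0


def _to_float(token: str) -> float:
    return float(token.replace("−", "-"))


def _parse_match(m: re.Match, article_id: str) -> StatReport:
    if m.group("fam_t"):
        family, df1, df2 = "t", float(m.group("t_df")), None
    elif m.group("fam_F"):
        family, df1, df2 = "F", float(m.group("f_df1")), float(m.group("f_df2"))
    elif m.group("fam_c"):
        family, df1, df2 = "chi2", float(m.group("c_df")), None
    elif m.group("fam_r"):
        family, df1, df2 = "r", float(m.group("r_df")), None
    else:
        family, df1, df2 = "Z", None, None

    sample_n = int(m.group("c_n")) if m.groupdict().get("c_n") else None
    stat_tok = m.group("stat")
    if m.group("ns"):
        p_comp, p_val, p_dec = "ns", None, 0
    else:
        p_comp = _CMP_MAP[m.group("p_comp")]
        p_val = float(m.group("p"))
        p_dec = _decimals(m.group("p"))
    return StatReport(
        article_id=article_id,
        test_family=family,
        df1=df1,
        df2=df2,
        sample_n=sample_n,
        stat_comparator=_CMP_MAP[m.group("stat_comp")],
        stat_value=_to_float(stat_tok),
        stat_decimals=_decimals(stat_tok),
        p_comparator=p_comp,
        p_reported=p_val,
        p_decimals=p_dec,
        span_start=m.start(),
        span_end=m.end(),
        raw=m.group(0),
    )


def scan_text(text: str, article_id: str, *, sidedness_window: int = 200,
              annotate: bool = True) -> ScanResult:
    """Scan a plain-text document for APA-formatted test results.

    Returns a :class:`ScanResult` — a list of :class:`StatReport` in document
    order, with ``.skipped`` holding the near-miss candidates the grammar
    rejected (effect sizes interposed before the p-value, bare Wald
    statistics, missing p-values).  When ``annotate`` is true, the sidedness
    and significance-wording heuristics are applied to each report.
    """
    if not article_id:
        raise ValueError("article_id must be non-empty")
    reports = [_parse_match(m, article_id) for m in _RESULT_RE.finditer(text)]
    taken = [(r.span_start, r.span_end) for r in reports]

    skipped: List[SkippedCandidate] = []
    for m in _CANDIDATE_RE.finditer(text):
        if any(a <= m.start() < b for a, b in taken):
            continue
        lookahead = text[m.end():m.end() + 120]
        reason = "tokens_between_stat_and_p" if _NEARBY_P_RE.search(lookahead) else "no_p_value"
        skipped.append(SkippedCandidate(m.start(), m.group(0), reason))
    for m in _BARE_WALD_RE.finditer(text):
        skipped.append(SkippedCandidate(m.start(), m.group(0), "bare_wald"))
    skipped.sort(key=lambda s: s.offset)

    if annotate:
        for r in reports:
            r.one_tailed = detect_sidedness(text, r, window=sidedness_window)
            r.sig_wording = detect_sig_wording(text, r)
    return ScanResult(reports, skipped)


def detect_sidedness(text: str, report: StatReport, window: int = 200) -> bool:
    """True if a sidedness keyword occurs within ``window`` characters.

    Keywords are "one-tailed", "one-sided" and "directional" (case-insensitive,
    hyphen or space).  Distance is the gap between the keyword and the report's
    span; a keyword overlapping the span counts as distance zero.
    """
    for m in _SIDEDNESS_RE.finditer(text):
        if m.start() >= report.span_end:
            dist = m.start() - report.span_end
        elif m.end() <= report.span_start:
            dist = report.span_start - m.end()
        else:
            dist = 0
        if dist <= window:
            return True
    return False


def detect_sig_wording(text: str, report: StatReport) -> str:
    """Classify the wording of the sentence containing the result.

    The sentence is the stretch between terminal punctuation marks followed by
    whitespace.  A negation-qualified phrase ("not significant",
    "non-significant", "no significant") wins over a bare "significant".
    """
    start, end = 0, len(text)
    for m in _SENTENCE_SPLIT_RE.finditer(text):
        if m.end() <= report.span_start:
            start = m.end()
        elif m.start() >= report.span_start:
            end = m.start()
            break
    sentence = text[start:end]
    if _NEGATED_SIG_RE.search(sentence):
        return "nonsignificant"
    if _SIG_RE.search(sentence):
        return "significant"
    return "unknown"


def validate_report(report: StatReport) -> Validation:
    """Pre-check a parsed report before it enters recomputation.

    Rejects p-values written in power-of-ten notation (unreadable under the
    grammar, and historically the source of p-values apparently above 1),
    p-values above 1, and statistics outside the support of their null
    distribution (negative F or chi-square, |r| > 1).
    """
    if _POW10_RAW_RE.search(report.raw):
        return Validation.UNSUPPORTED_NOTATION
    if report.p_reported is not None and report.p_reported > 1:
        return Validation.INVALID_P_ABOVE_ONE
    if report.test_family in ("F", "chi2") and report.stat_value < 0:
        return Validation.UNSUPPORTED_NOTATION
    if report.test_family == "r" and abs(report.stat_value) > 1:
        return Validation.UNSUPPORTED_NOTATION
    return Validation.VALID
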