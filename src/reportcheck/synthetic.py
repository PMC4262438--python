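"""Synthetic article corpus with a known planted error structure.

Real journal corpora are copyrighted, so the pipeline is exercised on
generated articles: prose with embedded APA-formatted results whose
consistency status is known by construction.  Each article draws a report
count from an over-dispersed (negative binomial) distribution around its
journal's mean, a per-article error propensity offset (Gaussian on the
log-odds scale, giving the nested heterogeneity a multilevel model should
recover), and per-report test families, degrees of freedom and statistics.

Planted inconsistencies are placed at least two reported-p rounding
half-widths away from the admissible region, so the checker's verdicts match
the planted truth exactly rather than probabilistically; planted gross errors
additionally require the recomputed interval to clear the significance
threshold on one side so that the decision flip is unambiguous.  Defaults
mirror the observed study conditions: six journals with mean retrieved
p-values per article between ~8 and ~30, an overall per-p error rate of
10.6% of which 7.55% are gross (0.8/10.6), and unit between-article SD on the
log odds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import special, stats

from .grammar import StatReport, scan_text
from .recompute import computed_p, p_interval_from_stat, rounding_half_width

__all__ = ["JournalProfile", "SyntheticSpec", "SyntheticCorpus", "generate", "emit_apa"]

_CMP_SYMBOL = {"eq": "=", "lt": "<", "gt": ">"}

# Margins (in units of p) used when planting errors.  The recomputed interval
# must clear alpha by these margins before an error can be planted on a given
# side; reported values are then drawn from windows that keep the planted
# claim >= 2 rounding half-widths away from the recomputed interval.
_ALPHA = 0.05
_LOW_CLEAR = 0.035   # interval entirely below alpha: p_hi <= this
_HIGH_CLEAR = 0.07   # interval entirely above alpha: p_lo >= this
_P_DECIMALS_PLANTED = 3


@dataclass(frozen=True)
class JournalProfile:
    """One journal label with its mean reports per article and article share."""

    name: str
    mean_reports: float
    weight: float = 1.0


# Per-journal means and article counts patterned on a six-journal
# psychology sample (means from ~8 to ~30 retrieved p-values per article).
DEFAULT_JOURNALS: Tuple[JournalProfile, ...] = (
    JournalProfile("JAP", 8.10, 42),
    JournalProfile("JCCP", 12.43, 67),
    JournalProfile("JCN", 16.08, 107),
    JournalProfile("JCPP", 11.38, 39),
    JournalProfile("JPSP", 30.21, 133),
    JournalProfile("PP", 17.83, 42),
)

DEFAULT_FAMILY_MIX: Dict[str, float] = {
    "F": 0.40, "t": 0.35, "chi2": 0.12, "r": 0.10, "Z": 0.03,
}


@dataclass
class SyntheticSpec:
    """Parameters of the planted-error corpus generator.

    ``error_rate`` is the base probability that a reported p is perturbed into
    inconsistency; ``gross_fraction`` the share of those forced across the
    significance boundary; ``article_effect_sd`` the SD of the per-article
    Gaussian offset on the error log-odds.
    """

    n_articles: int = 430
    journals: Tuple[JournalProfile, ...] = DEFAULT_JOURNALS
    reports_per_article_dispersion: float = 3.0  # NB shape; var = m + m^2/k
    family_mix: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FAMILY_MIX))
    error_rate: float = 0.106
    gross_fraction: float = 0.0755
    article_effect_sd: float = 1.0
    one_tailed_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_articles < 1:
            raise ValueError("n_articles must be >= 1")
        if not self.journals:
            raise ValueError("need at least one journal profile")
        for p in (self.error_rate, self.gross_fraction, self.one_tailed_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0, 1]: {p}")
        if self.article_effect_sd < 0:
            raise ValueError("article_effect_sd must be >= 0")
        if self.reports_per_article_dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        total = sum(self.family_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"family_mix must sum to 1, got {total}")
        unknown = set(self.family_mix) - {"t", "F", "chi2", "r", "Z"}
        if unknown:
            raise ValueError(f"unknown families in mix: {unknown}")


@dataclass
class SyntheticCorpus:
    """Generated texts plus the planted ground truth."""

    texts: Dict[str, str]
    truth: pd.DataFrame        # article_id, journal, report_index, family, is_error, is_gross, one_tailed
    reports: List[StatReport]  # structured reports aligned with truth rows
    articles: pd.DataFrame     # article_id, journal, n_reports


# --------------------------------------------------------------------------
# Rendering

def _fmt_stat(family: str, value: float, decimals: int) -> str:
    s = f"{abs(value):.{decimals}f}"
    if family == "r":
        s = s.lstrip("0") if s.startswith("0.") else s
    if value < 0:
        s = "-" + s
    return s


def _fmt_p(value: float, decimals: int) -> str:
    s = f"{value:.{decimals}f}"
    return s[1:] if s.startswith("0.") else s


def emit_apa(report: StatReport) -> str:
    """Render a report in canonical APA text; inverse of the scanner.

    ``scan_text(emit_apa(r), ...)`` recovers every field of ``r`` (up to the
    one-tailed/sig-wording context flags, which live outside the result span).
    """
    fam = report.test_family
    stat = _fmt_stat(fam, report.stat_value, report.stat_decimals)
    comp = _CMP_SYMBOL[report.stat_comparator]
    if fam == "t":
        head = f"t({_fmt_df(report.df1)}) {comp} {stat}"
    elif fam == "F":
        head = f"F({_fmt_df(report.df1)}, {_fmt_df(report.df2)}) {comp} {stat}"
    elif fam == "chi2":
        inner = _fmt_df(report.df1)
        if report.sample_n is not None:
            inner += f", N = {report.sample_n}"
        head = f"χ2({inner}) {comp} {stat}"
    elif fam == "r":
        head = f"r({_fmt_df(report.df1)}) {comp} {stat}"
    elif fam == "Z":
        head = f"Z {comp} {stat}"
    else:
        raise ValueError(f"unknown family {fam!r}")
    if report.p_comparator == "ns":
        tail = "ns"
    else:
        tail = f"p {_CMP_SYMBOL[report.p_comparator]} {_fmt_p(report.p_reported, report.p_decimals)}"
    return f"{head}, {tail}"


def _fmt_df(df: float) -> str:
    return f"{df:g}"


_TEMPLATES = [
    "The main effect of factor {i} was reliable, {apa}.",
    "Analysis of outcome {i} yielded {apa}.",
    "The planned contrast for condition {i} gave {apa}.",
    "For measure {i}, the model term reached {apa}.",
    "The interaction involving predictor {i} produced {apa}.",
]
_SIG_TEMPLATE = "The effect of factor {i} was significant, {apa}."
_NONSIG_TEMPLATE = "The effect of factor {i} was not significant, {apa}."
_FILLER = (
    "Participants completed the task under standard laboratory conditions. "
    "Descriptive statistics are reported in the supplementary materials."
)
# Long neutral padding placed around sentences that carry a one-tailed marker,
# so that the marker cannot fall within the sidedness window of a neighbouring
# result (default window: 200 characters).
_PAD = (
    "Stimulus presentation and response collection were controlled by the "
    "experimental software, and trials with recording artifacts were removed "
    "before aggregation. Order of blocks was counterbalanced across "
    "participants, and all dependent measures were screened for outliers "
    "using the preregistered criteria."
)


# --------------------------------------------------------------------------
# Report sampling

def _draw_family(rng: np.random.Generator, mix: Dict[str, float]) -> str:
    fams = list(mix)
    probs = np.array([mix[f] for f in fams])
    return fams[rng.choice(len(fams), p=probs / probs.sum())]


def _draw_df(rng: np.random.Generator, family: str):
    if family == "t":
        return float(rng.integers(5, 200)), None, None
    if family == "F":
        return float(rng.integers(1, 7)), float(rng.integers(10, 300)), None
    if family == "chi2":
        n = int(rng.integers(30, 500)) if rng.random() < 0.5 else None
        return float(rng.integers(1, 11)), None, n
    if family == "r":
        return float(rng.integers(10, 200)), None, None
    return None, None, None  # Z


def _stat_from_target_p(family: str, p: float, df1, df2) -> float:
    """Invert the tail probability: the statistic whose p equals ``p``."""
    if family == "t":
        return float(stats.t.isf(p / 2.0, df1))
    if family == "F":
        return float(stats.f.isf(p, df1, df2))
    if family == "chi2":
        return float(stats.chi2.isf(p, df1))
    if family == "Z":
        return float(stats.norm.isf(p / 2.0))
    # r: invert via the t transform
    t_val = stats.t.isf(p / 2.0, df1)
    return float(t_val / np.sqrt(df1 + t_val * t_val))


def _draw_target_p(rng: np.random.Generator) -> float:
    """Plausible true p: log-uniform, favouring small values as journals do."""
    return float(10.0 ** rng.uniform(-3.7, -0.05))


def _sample_statistic(rng, family, df1, df2, *, interval_predicate=None,
                      max_tries: int = 400):
    """Draw a rounded statistic (2 decimals) whose recomputed interval
    satisfies ``interval_predicate`` (if given)."""
    for _ in range(max_tries):
        p_target = _draw_target_p(rng)
        raw = _stat_from_target_p(family, p_target, df1, df2)
        value = round(raw, 2)
        if family == "r":
            value = min(value, 0.99)
        if family in ("F", "chi2") and value <= 0:
            continue
        probe = StatReport(
            article_id="_", test_family=family, stat_comparator="eq",
            stat_value=value, stat_decimals=2, p_comparator="eq",
            span_start=0, span_end=0, raw="", df1=df1, df2=df2,
        )
        interval = p_interval_from_stat(probe)
        if interval_predicate is None or interval_predicate(interval):
            return value, interval
    raise RuntimeError(
        f"could not draw a statistic satisfying the constraint for {family}")


def _interval_clears_alpha(interval) -> bool:
    return interval.p_hi <= _LOW_CLEAR or interval.p_lo >= _HIGH_CLEAR


def _plant_inconsistent_p(rng, interval, *, force_flip: bool) -> float:
    """Pick a reported p (3 decimals) that is unambiguously inconsistent.

    The recomputed interval clears alpha on one side (precondition).  A
    flipped report goes on the opposite side of alpha; a same-side report
    stays on the interval's side but outside its neighbourhood.  All windows
    keep >= 2 half-widths between the claim's rounding band and the interval.
    """
    h = rounding_half_width(_P_DECIMALS_PLANTED)
    low_side = interval.p_hi <= _LOW_CLEAR  # recomputed is significant
    if force_flip:
        lo, hi = (0.055, 0.99) if low_side else (0.001, 0.045)
    else:
        if low_side:
            lo, hi = interval.p_hi + 3 * h, 0.045
        else:
            # prefer the window below the interval when it is wide enough
            below = (0.055, interval.p_lo - 3 * h)
            above = (interval.p_hi + 3 * h, 0.99)
            lo, hi = below if (below[1] - below[0]) > 0.004 else above
            if hi <= lo:
                lo, hi = below
    value = round(float(rng.uniform(lo, hi)), _P_DECIMALS_PLANTED)
    return float(np.clip(value, lo, hi if hi >= lo else lo))


def _consistent_p_fields(rng, interval, one_tailed: bool):
    """Reported-p fields (comparator, value, decimals) that remain consistent."""
    p_eff = interval.p_mid / 2.0 if one_tailed else interval.p_mid
    if p_eff < 0.001:
        return "lt", 0.001, 3
    u = rng.random()
    if u < 0.06 and interval.p_lo > 0.06:
        return "ns", None, 0
    if u < 0.12 and interval.p_lo > 0.06:
        return "gt", 0.05, 2
    decimals = 3 if rng.random() < 0.5 else 2
    value = round(p_eff, decimals)
    if value <= 0.0:
        # Too small for the chosen precision; three decimals keep the claim
        # inside the recomputed interval (p_eff >= 0.001 here).
        decimals, value = 3, round(p_eff, 3)
    if value >= 1.0:
        value = 1.0
    return "eq", float(value), decimals


# --------------------------------------------------------------------------
# Generation

def generate(spec: SyntheticSpec) -> SyntheticCorpus:
    """Generate article texts and the aligned planted-truth table.

    Deterministic for a fixed ``spec.seed``: identical specs give
    byte-identical texts and truth tables.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    base_logit = special.logit(spec.error_rate) if 0 < spec.error_rate < 1 else None

    weights = np.array([j.weight for j in spec.journals], dtype=float)
    weights /= weights.sum()
    k = spec.reports_per_article_dispersion

    texts: Dict[str, str] = {}
    truth_rows: List[dict] = []
    article_rows: List[dict] = []
    all_reports: List[StatReport] = []

    for a in range(spec.n_articles):
        article_id = f"art{a:04d}"
        journal = spec.journals[rng.choice(len(spec.journals), p=weights)]
        mean = journal.mean_reports
        # negative binomial with mean m, shape k: p = k / (k + m)
        n_reports = max(int(rng.negative_binomial(k, k / (k + mean))), 1)
        offset = rng.normal(0.0, spec.article_effect_sd) if spec.article_effect_sd > 0 else 0.0

        if spec.error_rate <= 0.0:
            p_err = 0.0
        elif spec.error_rate >= 1.0:
            p_err = 1.0
        else:
            p_err = float(special.expit(base_logit + offset))

        sentences: List[str] = []
        for j in range(n_reports):
            is_error = bool(rng.random() < p_err)
            is_gross = bool(is_error and rng.random() < spec.gross_fraction)
            report, one_tailed = _make_report(rng, spec, article_id, is_error, is_gross)
            truth_rows.append({
                "article_id": article_id,
                "journal": journal.name,
                "report_index": j,
                "family": report.test_family,
                "is_error": is_error,
                "is_gross": is_gross,
                "one_tailed": one_tailed,
            })
            all_reports.append(report)
            if one_tailed:
                sentences.append(_PAD)
                sentences.append(_render_sentence(rng, report, j))
                sentences.append(_PAD)
            else:
                sentences.append(_render_sentence(rng, report, j))
                if rng.random() < 0.3:
                    sentences.append(_FILLER)
        texts[article_id] = " ".join(sentences)
        article_rows.append({
            "article_id": article_id, "journal": journal.name, "n_reports": n_reports,
        })

    truth = pd.DataFrame(
        truth_rows,
        columns=["article_id", "journal", "report_index", "family",
                 "is_error", "is_gross", "one_tailed"],
    )
    articles = pd.DataFrame(article_rows, columns=["article_id", "journal", "n_reports"])
    return SyntheticCorpus(texts=texts, truth=truth, reports=all_reports,
                           articles=articles)


def _make_report(rng, spec, article_id, is_error, is_gross):
    """One structured report with the requested planted status."""
    family = _draw_family(rng, spec.family_mix)
    df1, df2, sample_n = _draw_df(rng, family)
    one_tailed = False

    if is_error:
        value, interval = _sample_statistic(
            rng, family, df1, df2, interval_predicate=_interval_clears_alpha)
        p_rep = _plant_inconsistent_p(rng, interval, force_flip=is_gross)
        p_comp, p_dec = "eq", _P_DECIMALS_PLANTED
    else:
        one_tailed = (family in ("t", "r", "Z")
                      and rng.random() < spec.one_tailed_rate)
        value, interval = _sample_statistic(rng, family, df1, df2)
        p_comp, p_rep, p_dec = _consistent_p_fields(rng, interval, one_tailed)

    signed = value
    if family in ("t", "r", "Z") and rng.random() < 0.5:
        signed = -value
    return StatReport(
        article_id=article_id,
        test_family=family,
        df1=df1,
        df2=df2,
        sample_n=sample_n,
        stat_comparator="eq",
        stat_value=signed,
        stat_decimals=2,
        p_comparator=p_comp,
        p_reported=p_rep,
        p_decimals=p_dec,
        one_tailed=one_tailed,
        span_start=0,
        span_end=0,
        raw="",
    ), one_tailed


def _render_sentence(rng, report: StatReport, index: int) -> str:
    apa = emit_apa(report)
    if report.one_tailed:
        apa += " (one-tailed)"
    u = rng.random()
    claim_sig = (report.p_comparator in ("eq", "lt")
                 and report.p_reported is not None and report.p_reported < _ALPHA)
    if u < 0.15 and claim_sig:
        template = _SIG_TEMPLATE
    elif u < 0.25 and not claim_sig:
        template = _NONSIG_TEMPLATE
    else:
        template = _TEMPLATES[int(rng.integers(len(_TEMPLATES)))]
    return template.format(i=index + 1, apa=apa)


def roundtrip_reports(corpus: SyntheticCorpus) -> List[StatReport]:
    """Re-extract every planted report from the rendered texts, in truth order."""
    out: List[StatReport] = []
    for article_id in corpus.articles["article_id"]:
        out.extend(scan_text(corpus.texts[article_id], article_id))
    return out
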