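"""Independent oracles used by the test suite.

Two deliberately slow but transparent reference implementations:

* tail probabilities by numerical integration of density formulas written out
  from gamma/beta functions (no use of scipy.stats distribution objects), and
* a brute-force consistency oracle that enumerates a dense grid of candidate
  true statistic values inside the printed statistic's rounding interval,
  computes the p-value at each, and checks membership in the reported-p
  region pointwise — no interval arithmetic.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import integrate

from reportcheck import StatReport, computed_p, reported_p_region, reported_significance
from reportcheck.recompute import rounding_half_width

_SYMMETRIC = {"t", "r", "Z"}


# ---------------------------------------------------------------------------
# Density-integration oracle for tail probabilities

def _t_pdf(x, df):
    logc = (math.lgamma((df + 1) / 2.0) - math.lgamma(df / 2.0)
            - 0.5 * math.log(df * math.pi))
    return math.exp(logc - (df + 1) / 2.0 * math.log1p(x * x / df))

def _f_pdf(x, d1, d2):
    if x <= 0:
        return 0.0
    logc = (math.lgamma((d1 + d2) / 2.0) - math.lgamma(d1 / 2.0)
            - math.lgamma(d2 / 2.0) + (d1 / 2.0) * math.log(d1 / d2))
    return math.exp(logc + (d1 / 2.0 - 1.0) * math.log(x)
                    - (d1 + d2) / 2.0 * math.log1p(d1 * x / d2))

def _chi2_pdf(x, df):
    if x <= 0:
        return 0.0
    logc = -(df / 2.0) * math.log(2.0) - math.lgamma(df / 2.0)
    return math.exp(logc + (df / 2.0 - 1.0) * math.log(x) - x / 2.0)

def _norm_pdf(x):
    return math.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)


def oracle_p(family: str, stat: float, df1=None, df2=None,
             epsabs: float = 1e-13) -> float:
    """Tail probability by direct quadrature of the density."""
    if family == "t":
        val, _ = integrate.quad(_t_pdf, abs(stat), np.inf, args=(df1,),
                                epsabs=epsabs, epsrel=1e-12)
        return min(2.0 * val, 1.0)
    if family == "F":
        val, _ = integrate.quad(_f_pdf, stat, np.inf, args=(df1, df2),
                                epsabs=epsabs, epsrel=1e-12)
        return min(val, 1.0)
    if family == "chi2":
        val, _ = integrate.quad(_chi2_pdf, stat, np.inf, args=(df1,),
                                epsabs=epsabs, epsrel=1e-12)
        return min(val, 1.0)
    if family == "Z":
        val, _ = integrate.quad(_norm_pdf, abs(stat), np.inf,
                                epsabs=epsabs, epsrel=1e-12)
        return min(2.0 * val, 1.0)
    if family == "r":
        a = abs(stat)
        if a >= 1.0:
            return 0.0
        t_equiv = a * math.sqrt(df1 / (1.0 - a * a))
        return oracle_p("t", t_equiv, df1, epsabs=epsabs)
    raise ValueError(family)


# ---------------------------------------------------------------------------
# Brute-force grid oracle for the classifier

def _vector_p(family, grid, df1, df2):
    """computed_p over a grid (vectorised for tractable enumeration)."""
    from scipy import stats
    if family == "t":
        return np.clip(2.0 * stats.t.sf(np.abs(grid), df1), 0.0, 1.0)
    if family == "F":
        return np.clip(stats.f.sf(grid, df1, df2), 0.0, 1.0)
    if family == "chi2":
        return np.clip(stats.chi2.sf(grid, df1), 0.0, 1.0)
    if family == "Z":
        return np.clip(2.0 * stats.norm.sf(np.abs(grid)), 0.0, 1.0)
    if family == "r":
        a = np.minimum(np.abs(grid), 1.0)
        with np.errstate(divide="ignore"):
            t_equiv = a * np.sqrt(df1 / np.maximum(1.0 - a * a, 1e-300))
        p = np.clip(2.0 * stats.t.sf(t_equiv, df1), 0.0, 1.0)
        return np.where(a >= 1.0, 0.0, p)
    raise ValueError(family)


def _region_contains(region, p):
    below = p < region.hi if region.hi_open else p <= region.hi
    above = p > region.lo if region.lo_open else p >= region.lo
    return below & above


def bruteforce_classify(report: StatReport, alpha: float = 0.05):
    """(consistent, error, gross) by dense enumeration of the rounding interval."""
    h = rounding_half_width(report.stat_decimals)
    mag = abs(report.stat_value)
    lo, hi = max(mag - h, 0.0), mag + h
    if report.test_family == "r":
        lo, hi = min(lo, 1.0), min(hi, 1.0)
    step = 10.0 ** (-(report.stat_decimals + 3))
    grid = np.arange(lo, hi + step / 2.0, step)
    grid = np.clip(grid, lo, hi)
    ps = _vector_p(report.test_family, grid, report.df1, report.df2)
    region = reported_p_region(report.p_comparator, report.p_reported,
                               report.p_decimals, alpha=alpha)
    consistent = bool(_region_contains(region, ps).any())
    if (not consistent and report.one_tailed
            and report.test_family in _SYMMETRIC):
        consistent = bool(_region_contains(region, ps / 2.0).any())
    error = not consistent
    gross = False
    if error:
        claim = reported_significance(report, alpha=alpha)
        if claim is True and bool((ps > alpha).all()):
            gross = True
        elif claim is False and bool((ps < alpha).all()):
            gross = True
    return consistent, error, gross


# ---------------------------------------------------------------------------
# Randomized report stream shared by the oracle-equivalence checks

def random_reports(n: int, seed: int):
    """Reports spanning consistent, mildly and grossly inconsistent claims."""
    from reportcheck.synthetic import (_draw_df, _draw_family, _draw_target_p,
                                       _stat_from_target_p, DEFAULT_FAMILY_MIX)
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        family = _draw_family(rng, DEFAULT_FAMILY_MIX)
        df1, df2, sample_n = _draw_df(rng, family)
        stat = round(_stat_from_target_p(family, _draw_target_p(rng), df1, df2), 2)
        if family == "r":
            stat = min(stat, 0.99)
        if family in ("F", "chi2"):
            stat = max(stat, 0.01)
        u = rng.random()
        if u < 0.25:   # arbitrary reported p: mostly inconsistent
            p_comp, p_val, p_dec = "eq", round(float(rng.uniform(0.001, 0.99)), 3), 3
        elif u < 0.35:
            p_comp, p_val, p_dec = "lt", float(rng.choice([0.05, 0.01, 0.001])), 2
        elif u < 0.42:
            p_comp, p_val, p_dec = "gt", 0.05, 2
        elif u < 0.47:
            p_comp, p_val, p_dec = "ns", None, 0
        else:          # reported near the recomputed value: mostly consistent
            p_mid = computed_p(family, stat, df1, df2)
            p_dec = int(rng.choice([2, 3]))
            p_val = round(p_mid + rng.normal(0.0, 0.002), p_dec)
            p_val = float(min(max(p_val, 0.0), 1.0))
            p_comp = "eq"
        out.append(StatReport(
            article_id="rand", test_family=family, df1=df1, df2=df2,
            sample_n=sample_n, stat_comparator="eq", stat_value=float(stat),
            stat_decimals=2, p_comparator=p_comp, p_reported=p_val,
            p_decimals=p_dec,
            one_tailed=bool(rng.random() < 0.15 and family in ("t", "r", "Z")),
            sig_wording=str(rng.choice(["unknown", "significant", "nonsignificant"])),
            span_start=0, span_end=0, raw="",
        ))
    return out
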