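"""Recompute p-values from test statistics and propagate rounding bounds.

A printed statistic such as ``0.54`` stands for any true value in
[0.535, 0.545); the p-value implied by the statistic is therefore not a point
but an interval.  :func:`computed_p` gives the tail probability at a point;
:func:`p_interval_from_stat` evaluates it at both rounding endpoints of the
printed statistic to bound the recomputed p.

Conventions: t, r and Z are two-tailed (APA default); F and chi-square are
upper-tailed by construction.  r is converted to a t statistic with
t = r * sqrt(df / (1 - r^2)) on df degrees of freedom (df = n - 2).
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .grammar import StatReport

__all__ = ["PInterval", "computed_p", "p_interval_from_stat", "rounding_half_width"]


@dataclass(frozen=True)
class PInterval:
    """Bounds on the recomputed p induced by rounding of the printed statistic.

    ``p_mid`` is the p-value at the statistic exactly as printed;
    ``p_lo``/``p_hi`` are the values at the far/near rounding endpoints
    (p is non-increasing in the statistic's magnitude for every family).
    """

    p_lo: float
    p_hi: float
    p_mid: float

    def __post_init__(self):
        if not (0.0 <= self.p_lo <= self.p_mid <= self.p_hi <= 1.0):
            raise ValueError(
                f"invalid interval: p_lo={self.p_lo}, p_mid={self.p_mid}, p_hi={self.p_hi}"
            )

    @property
    def width(self) -> float:
        return self.p_hi - self.p_lo

    def halved(self) -> "PInterval":
        """The interval under a one-tailed reading (symmetric families only)."""
        return PInterval(self.p_lo / 2.0, self.p_hi / 2.0, self.p_mid / 2.0)


def computed_p(family: str, stat: float, df1: float | None = None,
               df2: float | None = None) -> float:
    """Tail probability of the named null distribution at ``stat``.

    t: two-tailed Student t on df1.  F: upper tail of F(df1, df2).
    chi2: upper tail of chi-square(df1).  Z: two-tailed standard normal.
    r: transformed to t and evaluated two-tailed.
    """
    if family == "t":
        _require_df(df1)
        p = 2.0 * stats.t.sf(abs(stat), df1)
    elif family == "F":
        _require_df(df1)
        _require_df(df2)
        if stat < 0:
            raise ValueError("F statistic must be non-negative")
        p = stats.f.sf(stat, df1, df2)
    elif family == "chi2":
        _require_df(df1)
        if stat < 0:
            raise ValueError("chi-square statistic must be non-negative")
        p = stats.chi2.sf(stat, df1)
    elif family == "Z":
        p = 2.0 * stats.norm.sf(abs(stat))
    elif family == "r":
        _require_df(df1)
        a = abs(stat)
        if a > 1:
            raise ValueError("|r| must not exceed 1")
        if a == 1.0:
            return 0.0
        t_equiv = a * (df1 / (1.0 - a * a)) ** 0.5
        p = 2.0 * stats.t.sf(t_equiv, df1)
    else:
        raise ValueError(f"unknown test family: {family!r}")
    return min(max(float(p), 0.0), 1.0)


def rounding_half_width(decimals: int) -> float:
    """Half-width of the rounding interval of a number printed to ``decimals``."""
    return 0.5 * 10.0 ** (-decimals)


def p_interval_from_stat(report: StatReport) -> PInterval:
    """Bound the recomputed p over the rounding interval of the statistic.

    The printed statistic v with d decimals stands for magnitudes in
    [|v| - h, |v| + h] with h = 0.5 * 10^-d, clipped to the distribution's
    support.  Because p is monotone non-increasing in magnitude, the p at the
    smaller endpoint is the upper bound.  A ``<``/``>`` comparator on the
    statistic widens the corresponding side to the distribution's limit.
    """
    fam = report.test_family
    h = rounding_half_width(report.stat_decimals)
    mag = abs(report.stat_value)
    lo_stat = max(mag - h, 0.0)
    hi_stat = mag + h
    if fam == "r":
        lo_stat = min(lo_stat, 1.0)
        hi_stat = min(hi_stat, 1.0)

    p_mid = computed_p(fam, min(mag, 1.0) if fam == "r" else mag, report.df1, report.df2)
    p_hi = computed_p(fam, lo_stat, report.df1, report.df2)
    p_lo = computed_p(fam, hi_stat, report.df1, report.df2)

    if report.stat_comparator == "lt":
        p_hi = computed_p(fam, 0.0, report.df1, report.df2)
    elif report.stat_comparator == "gt":
        p_lo = 0.0

    # Guard against floating noise violating the ordering invariant.
    p_lo = min(p_lo, p_mid)
    p_hi = max(p_hi, p_mid)
    return PInterval(p_lo=p_lo, p_hi=p_hi, p_mid=p_mid)


def _require_df(df: float | None) -> None:
    if df is None or df <= 0:
        raise ValueError(f"degrees of freedom must be positive, got {df}")
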