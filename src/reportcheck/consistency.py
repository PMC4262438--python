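"""Compare reported p-values with recomputed bounds and classify errors.

A reported p-value, read together with its comparator and printed precision,
admits a region of p-values it could honestly describe: ``p = .03`` printed to
two decimals stands for [.025, .035]; ``p < .05`` claims [0, .05).  A result
is *consistent* when that region overlaps the interval of p-values implied by
the test statistic's own rounding; otherwise it is an *error*.  An error is a
*gross error* (decision error) when the reported value claims significance at
the threshold alpha while every p in the recomputed interval lies on the other
side of alpha, or vice versa — the kind of inconsistency that can flip a
study's conclusion.

Results flagged as one-tailed are given a rescue pass: for the symmetric
families (t, r, Z) the recomputed two-tailed interval is halved and the
overlap re-checked before the result is declared inconsistent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .grammar import StatReport
from .recompute import PInterval, rounding_half_width

__all__ = ["PRegion", "ConsistencyResult", "reported_p_region", "classify",
           "reported_significance"]

_SYMMETRIC_FAMILIES = frozenset({"t", "r", "Z"})


@dataclass(frozen=True)
class PRegion:
    """Sub-interval of [0, 1] admissible under the reported p claim."""

    lo: float
    hi: float
    lo_open: bool = False
    hi_open: bool = False

    def overlaps(self, p_lo: float, p_hi: float) -> bool:
        """Overlap with the closed interval [p_lo, p_hi]."""
        below = p_lo < self.hi if self.hi_open else p_lo <= self.hi
        above = p_hi > self.lo if self.lo_open else p_hi >= self.lo
        return below and above


@dataclass
class ConsistencyResult:
    """Verdict for one extracted result."""

    report: StatReport
    interval: PInterval
    consistent: bool
    error: bool
    gross_error: bool
    one_tailed_applied: bool
    reason: str

    def to_row(self) -> dict:
        row = self.report.to_row()
        row.update(
            computed_p=self.interval.p_mid,
            p_lo=self.interval.p_lo,
            p_hi=self.interval.p_hi,
            consistent=self.consistent,
            error=self.error,
            gross_error=self.gross_error,
            one_tailed_applied=self.one_tailed_applied,
            reason=self.reason,
        )
        return row


def reported_p_region(p_comparator: str, p_reported: Optional[float],
                      p_decimals: int = 0, alpha: float = 0.05) -> PRegion:
    """Region of true p-values compatible with the reported claim.

    ``eq``: the rounding band around the printed value, except that the
    special print "p = .000" means "rounds to zero", i.e. [0, h).
    ``lt``/``gt``: strict one-sided claims, with no rounding band on the
    threshold.  ``ns``: anything above alpha.
    """
    if p_comparator == "ns":
        return PRegion(alpha, 1.0, lo_open=True)
    if p_reported is None:
        raise ValueError("p_reported required unless comparator is 'ns'")
    if not 0.0 <= p_reported <= 1.0:
        raise ValueError(f"reported p outside [0, 1]: {p_reported}")
    if p_comparator == "eq":
        h = rounding_half_width(p_decimals)
        if p_reported == 0.0:
            return PRegion(0.0, h, hi_open=True)
        return PRegion(max(p_reported - h, 0.0), min(p_reported + h, 1.0))
    if p_comparator == "lt":
        return PRegion(0.0, p_reported, hi_open=True)
    if p_comparator == "gt":
        return PRegion(p_reported, 1.0, lo_open=True)
    raise ValueError(f"unknown p comparator: {p_comparator!r}")


def reported_significance(report: StatReport, alpha: float = 0.05) -> Optional[bool]:
    """Did the authors claim significance at alpha?  None if undeterminable.

    ``p = .05`` exactly at the threshold is resolved by the sentence wording;
    with unknown wording the claim is undetermined, so such a result can be an
    error but never a gross error.
    """
    comp, p = report.p_comparator, report.p_reported
    if comp == "ns":
        return False
    if comp == "lt":
        return True if p <= alpha else None
    if comp == "gt":
        return False if p >= alpha else None
    # eq
    if p < alpha:
        return True
    if p > alpha:
        return False
    if report.sig_wording == "significant":
        return True
    if report.sig_wording == "nonsignificant":
        return False
    return None


def classify(report: StatReport, interval: PInterval,
             alpha: float = 0.05) -> ConsistencyResult:
    """Classify one result as consistent, error, or gross error.

    The gross-error flag is conservative: it requires the entire recomputed
    interval on the opposite side of alpha from the reported claim, so that
    rounding ambiguity in the statistic can never manufacture a decision
    error.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    region = reported_p_region(report.p_comparator, report.p_reported,
                               report.p_decimals, alpha=alpha)
    consistent = region.overlaps(interval.p_lo, interval.p_hi)
    one_tailed_applied = False
    if (not consistent and report.one_tailed
            and report.test_family in _SYMMETRIC_FAMILIES):
        half = interval.halved()
        if region.overlaps(half.p_lo, half.p_hi):
            consistent = True
            one_tailed_applied = True

    error = not consistent
    gross = False
    if error:
        claim = reported_significance(report, alpha=alpha)
        if claim is True and interval.p_lo > alpha:
            gross = True
        elif claim is False and interval.p_hi < alpha:
            gross = True

    if consistent:
        reason = "consistent_one_tailed" if one_tailed_applied else "consistent"
    else:
        reason = "gross_inconsistency" if gross else "inconsistency"
    return ConsistencyResult(
        report=report,
        interval=interval,
        consistent=consistent,
        error=error,
        gross_error=gross,
        one_tailed_applied=one_tailed_applied,
        reason=reason,
    )
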