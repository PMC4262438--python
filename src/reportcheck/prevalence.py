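"""Prevalence estimation and group comparisons for reporting-error flags.

Two levels of analysis, matching the nested structure of the data:

* article level — does an article contain at least one error?  A binary flag
  per article; an intercept-only logistic regression yields the probability
  (identical to the sample proportion) with a Wald confidence interval on the
  log-odds scale, back-transformed.
* p-value level — is a given reported p-value an error?  P-values are nested
  within articles, so a random-intercept logistic model with article as the
  clustering factor is used; the reported probability is the inverse logit of
  the fixed intercept (conditional on a typical article), with the
  population-averaged probability exposed alongside.

Group contrasts (journal, co-piloting indicators, survey response) enter the
multilevel model as a fixed factor; the omnibus test is a likelihood-ratio
chi-square and pairwise contrasts are Wald tests at a Bonferroni-corrected
alpha (the division constant is a parameter, conventionally the number of
planned tests).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import statsmodels.api as sm
from scipy import special, stats

from .glmm import fit_random_intercept_logit, marginal_probability

__all__ = [
    "CorpusEstimate",
    "GroupComparison",
    "SeparationWarning",
    "estimate_article_rate",
    "estimate_p_level_rate",
    "compare_groups",
    "conditional_gross_given_error",
]

_Z95 = stats.norm.ppf(0.975)


class SeparationWarning(UserWarning):
    """All outcomes identical: the logit intercept is unbounded."""


@dataclass
class CorpusEstimate:
    """A probability with its 95% confidence interval."""

    probability: float
    ci_lo: float
    ci_hi: float
    model: str                      # 'simple_logit' | 'multilevel_logit'
    n: int
    random_intercept_sd: Optional[float] = None
    se_random_intercept_sd: Optional[float] = None
    marginal: Optional[float] = None   # population-averaged probability
    intercept: Optional[float] = None
    se_intercept: Optional[float] = None

    def __post_init__(self):
        finite = np.isfinite([self.ci_lo, self.probability, self.ci_hi]).all()
        if finite and not (self.ci_lo <= self.probability <= self.ci_hi):
            raise ValueError("confidence interval must bracket the estimate")

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "probability": self.probability,
            "ci_lo": self.ci_lo,
            "ci_hi": self.ci_hi,
            "n": self.n,
            "random_intercept_sd": self.random_intercept_sd,
            "marginal_probability": self.marginal,
        }


@dataclass
class GroupComparison:
    """Omnibus likelihood-ratio test plus Bonferroni-flagged pairwise contrasts."""

    test_statistic: float
    df: int
    p_value: float
    alpha_corrected: float
    pairwise: List[Tuple[Tuple[str, str], float, bool]] = field(default_factory=list)
    n: int = 0
    group_probabilities: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "chi2": self.test_statistic,
            "df": self.df,
            "p_value": self.p_value,
            "alpha_corrected": self.alpha_corrected,
            "n": self.n,
            "pairwise": [
                {"groups": list(pair), "p_value": p, "significant": sig}
                for pair, p, sig in self.pairwise
            ],
            "group_probabilities": self.group_probabilities,
        }


def estimate_article_rate(any_flags: Sequence[bool]) -> CorpusEstimate:
    """Intercept-only logistic estimate of an article-level probability.

    The ML estimate of the intercept-only logistic model is exactly the
    sample proportion; the confidence interval is Wald on the logit scale,
    back-transformed.  With all-true or all-false input (separation) the
    proportion is returned with a degenerate interval and a warning.
    """
    y = np.asarray(any_flags, dtype=float)
    n = len(y)
    if n < 1:
        raise ValueError("need at least one observation")
    k = y.sum()
    if k == 0 or k == n:
        p = k / n
        warnings.warn(
            f"separation: all {n} outcomes are {bool(p)}; CI is degenerate",
            SeparationWarning,
        )
        return CorpusEstimate(probability=p, ci_lo=p, ci_hi=p,
                              model="simple_logit", n=n)
    model = sm.GLM(y, np.ones((n, 1)), family=sm.families.Binomial())
    fit = model.fit()
    b0 = float(fit.params[0])
    se = float(fit.bse[0])
    return CorpusEstimate(
        probability=float(special.expit(b0)),
        ci_lo=float(special.expit(b0 - _Z95 * se)),
        ci_hi=float(special.expit(b0 + _Z95 * se)),
        model="simple_logit",
        n=n,
        intercept=b0,
        se_intercept=se,
    )


def estimate_p_level_rate(flags: Sequence[bool], article_ids: Sequence,
                          *, n_nodes: int = 15) -> CorpusEstimate:
    """Multilevel (random-intercept) estimate of a p-value-level probability.

    Articles are the clusters; the reported probability is the inverse logit
    of the fixed intercept (a typical article, random effect zero), with the
    population-averaged value in ``marginal``.
    """
    y = np.asarray(flags, dtype=float)
    if len(y) != len(article_ids):
        raise ValueError("flags and article_ids must align")
    X = np.ones((len(y), 1))
    fit = fit_random_intercept_logit(y, X, article_ids, n_nodes=n_nodes)
    b0, se = float(fit.beta[0]), float(fit.se_beta[0])
    return CorpusEstimate(
        probability=float(special.expit(b0)),
        ci_lo=float(special.expit(b0 - _Z95 * se)),
        ci_hi=float(special.expit(b0 + _Z95 * se)),
        model="multilevel_logit",
        n=len(y),
        random_intercept_sd=fit.sigma,
        se_random_intercept_sd=fit.se_sigma,
        marginal=marginal_probability(b0, fit.sigma),
        intercept=b0,
        se_intercept=se,
    )


def compare_groups(flags: Sequence[bool], article_ids: Sequence,
                   group_labels: Sequence, *, n_planned_tests: int = 6,
                   alpha: float = 0.05, n_nodes: int = 15) -> GroupComparison:
    """Test a fixed group factor in the multilevel model.

    Fits the random-intercept model with and without the factor; the omnibus
    statistic is the likelihood-ratio chi-square on (groups - 1) degrees of
    freedom.  All pairwise contrasts are Wald tests on the coefficient scale,
    flagged at alpha / n_planned_tests.
    """
    y = np.asarray(flags, dtype=float)
    groups = np.asarray(group_labels)
    articles = np.asarray(article_ids)
    if not (len(y) == len(groups) == len(articles)):
        raise ValueError("flags, article_ids and group_labels must align")
    levels = sorted(set(groups.tolist()))
    if len(levels) < 2:
        raise ValueError("need at least two groups to compare")
    for lev in levels:
        if not np.any(groups == lev):  # pragma: no cover - sorted(set()) precludes
            raise ValueError(f"group {lev!r} has no observations")

    # Dummy coding, first level as reference.
    X_null = np.ones((len(y), 1))
    X_full = np.column_stack(
        [np.ones(len(y))] + [(groups == lev).astype(float) for lev in levels[1:]]
    )
    fit_null = fit_random_intercept_logit(y, X_null, articles, n_nodes=n_nodes)
    fit_full = fit_random_intercept_logit(y, X_full, articles, n_nodes=n_nodes)
    lr = max(2.0 * (fit_full.loglik - fit_null.loglik), 0.0)
    df = len(levels) - 1
    p_omnibus = float(stats.chi2.sf(lr, df))
    alpha_corr = alpha / n_planned_tests

    # Group-level linear combinations: level k has coefficient c_k where
    # c_ref = 0; contrast (a, b) tests c_a - c_b = 0.
    coef = {levels[0]: 0.0}
    for j, lev in enumerate(levels[1:], start=1):
        coef[lev] = float(fit_full.beta[j])
    cov = fit_full.cov_beta
    pairwise = []
    for i, a in enumerate(levels):
        for b in levels[i + 1:]:
            va = _contrast_vector(levels, a)
            vb = _contrast_vector(levels, b)
            v = va - vb
            est = coef[a] - coef[b]
            var = float(v @ cov @ v)
            if var <= 0 or not np.isfinite(var):
                p_pair = float("nan")
            else:
                z = est / np.sqrt(var)
                p_pair = float(2.0 * stats.norm.sf(abs(z)))
            pairwise.append(((str(a), str(b)), p_pair,
                             bool(p_pair < alpha_corr)))

    probs = {
        str(lev): float(special.expit(fit_full.beta[0] + coef[lev]))
        for lev in levels
    }
    return GroupComparison(
        test_statistic=float(lr),
        df=df,
        p_value=p_omnibus,
        alpha_corrected=alpha_corr,
        pairwise=pairwise,
        n=len(y),
        group_probabilities=probs,
    )


def conditional_gross_given_error(error_flags: Sequence[bool],
                                  gross_flags: Sequence[bool],
                                  article_ids: Sequence,
                                  group_labels: Sequence, *,
                                  n_planned_tests: int = 6,
                                  alpha: float = 0.05,
                                  n_nodes: int = 15) -> GroupComparison:
    """Compare P(gross | error) across groups.

    Restricts to the rows flagged as errors and tests the group factor on the
    gross flag within that subset.  Inputs violating gross => error are
    rejected; a corpus without any errors has no conditional distribution and
    raises with an explicit message.
    """
    err = np.asarray(error_flags, dtype=bool)
    gross = np.asarray(gross_flags, dtype=bool)
    if np.any(gross & ~err):
        raise ValueError("invariant breach: gross error flagged without error")
    if not err.any():
        raise ValueError("empty subset: no errors in corpus, "
                         "conditional probability undefined")
    sub = err
    return compare_groups(
        gross[sub], np.asarray(article_ids)[sub], np.asarray(group_labels)[sub],
        n_planned_tests=n_planned_tests, alpha=alpha, n_nodes=n_nodes,
    )


def _contrast_vector(levels, lev) -> np.ndarray:
    """Coefficient-space vector picking out group ``lev``'s offset."""
    v = np.zeros(len(levels))  # [intercept, dummies...]
    if lev != levels[0]:
        v[levels.index(lev)] = 1.0
    return v
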