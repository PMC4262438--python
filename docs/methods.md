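# Methods

## The consistency model

An APA-formatted result carries three linked numbers: a test statistic, its
degrees of freedom, and a p-value. Under the null distribution appropriate to
the family, the first two determine the third:

* *t*(ν): two-tailed, p = 2·P(T_ν ≥ |t|);
* *F*(ν₁, ν₂) and χ²(ν): upper-tailed by construction;
* *Z*: two-tailed standard normal;
* *r*(ν): converted to t = r·√(ν / (1 − r²)) on ν degrees of freedom
  (ν = n − 2), then two-tailed. |r| = 1 maps to p = 0.

Two-tailed is the default for the symmetric families because that is the APA
convention; sidedness wording in the text is handled separately (below).
Negative t, r, Z are used in absolute value; a negative F or χ² is rejected
at validation as outside the null support.

**Rounding of the statistic.** A statistic printed as v with d decimals
stands for any magnitude in [|v| − h, |v| + h], h = ½·10⁻ᵈ. Because every
supported family's p is monotone non-increasing in the statistic's magnitude,
the implied p-values form the interval [p(|v| + h), p(|v| − h)], evaluated at
the endpoints (closed endpoints; immaterial for continuous CDFs but fixed for
determinism). A `<` or `>` comparator on the statistic widens the
corresponding side to the distribution's limit. The endpoints are clipped to
the support (magnitude at 0; |r| at 1).

**Rounding of the reported p.** The reported claim admits a region of
[0, 1]: `p = v` at d decimals admits [v − h, v + h]; `p < v` admits [0, v)
and `p > v` admits (v, 1] with no rounding band on v (a one-sided claim
carries no rounding ambiguity); `ns` admits (α, 1]; the special print
`p = .000` admits [0, h) — "rounds to zero", not "equals zero".

**Classification.** A result is *consistent* iff the recomputed interval
overlaps the admissible region. If it does not and the text marks the test
as one-tailed, the interval is halved and the overlap re-checked — but only
for t, r and Z, whose two-tailed p is twice the one-tailed p; F and χ² are
already one-tailed. An inconsistent result is a *gross error* iff the
reported claim takes a definite side of α and the **entire** recomputed
interval lies on the other side. Requiring the whole interval is a
deliberate conservatism: statistic-rounding ambiguity can then never
manufacture a decision error, mirroring the manual-verification step such
flags traditionally receive. A result reported exactly as `p = .05` takes a
side only through its sentence wording ("significant" / "not significant");
with unknown wording it can be an error but never a gross error.

The whole checker is deterministic: identical inputs give identical tables.

## Extraction grammar

The scanner is a single regular-expression pass accepting the dialect
variation publisher HTML actually shows: `=`, `<`, `>` around both numbers;
p with or without a leading zero; χ² written as `χ2`, `χ²`, `chi2` or
`chi-square`; decimal (corrected) degrees of freedom; ASCII hyphen or
Unicode minus; `ns`/`n.s.`; an optional `N = n` annotation inside χ²
parentheses (stored, never used in recomputation — it does not affect the
null distribution). `Wald χ2(df)` parses as χ², `Wald Z` as Z; a bare
`Wald = x` names no distribution and is skipped with a diagnostic. Results
with effect sizes interposed between statistic and p-value do not match the
grammar; they are counted as skipped candidates, a known retrieval
limitation of this style of checker.

Context heuristics automate what human coders otherwise judge:

* **Sidedness**: a keyword ("one-tailed", "one-sided", "directional",
  case-insensitive) within a 200-character window of the result's span
  (configurable). A window is the automatable proxy for full-article
  judgement; 200 characters roughly spans the enclosing sentence and its
  neighbours.
* **Significance wording**: the sentence containing the result (split on
  `.`, `!`, `?` followed by whitespace; abbreviation false-positives are
  accepted noise), with negation-qualified phrases ("not significant",
  "non-significant", "no significant") taking precedence over a bare
  "significant".

Validation excludes p-values above 1 and p-values in power-of-ten notation
(`3.2 × 10−5`), which the grammar cannot read reliably.

## Synthetic corpus

The generator emulates the structure of a six-journal psychology corpus:

| parameter | default | meaning |
|---|---|---|
| `n_articles` | 430 | articles in the corpus |
| journal means | 8.10–30.21 | mean results per article, per journal (weights 42/67/107/39/133/42) |
| `reports_per_article_dispersion` | 3.0 | negative-binomial shape (variance m + m²/k), giving the over-dispersed per-journal spread |
| `family_mix` | F .40, t .35, χ² .12, r .10, Z .03 | typical family shares in psychology reporting |
| `error_rate` | 0.106 | base probability a reported p is perturbed into inconsistency |
| `gross_fraction` | 0.0755 | share of planted errors forced across α (= .008/.106) |
| `article_effect_sd` | 1.0 | SD of the per-article Gaussian offset on the error log-odds |
| `one_tailed_rate` | 0.05 | share of consistent symmetric-family results rendered with a one-tailed marker |

Statistics are drawn by inverting a log-uniform target p over roughly
[2·10⁻⁴, 0.9] (journals skew towards small p-values), rounding to two
decimals, and recomputing the implied interval from the rounded value.
Consistent reports echo the recomputed p (rounded to 2–3 decimals, or
`p < .001`, occasionally `p > .05`/`ns` when the interval allows).
One-tailed consistent reports halve the p before rounding, exercising the
rescue path; sentences carrying the marker are padded with long neutral
prose so the keyword cannot fall inside a neighbouring result's window.

Planted errors are made *unambiguous by construction*: the statistic is
redrawn until its interval clears α on one side (p_hi ≤ .035 or
p_lo ≥ .07), and the reported p is then drawn from a window at least two
reported-p rounding half-widths away from the recomputed interval — on the
opposite side of α for gross errors, on the same side otherwise. This makes
truth-recovery tests exact rather than probabilistic. Planted errors are
always rendered two-tailed, since a one-tailed marker could legalise a
planted inconsistency through the rescue rule. Fixed seeds give
byte-identical corpora.

What the generator does **not** emulate: real journal layout, tables,
references, study boundaries, statistically dependent results within a
study, malformed APA variants beyond the accepted dialect, and genuinely
ambiguous roundings. Passing tests therefore demonstrate correctness of the
extraction–recomputation–classification logic under clean reporting, not
retrieval performance on raw publisher files.

## Prevalence models

* **Article level** (does an article contain ≥ 1 error?): intercept-only
  logistic regression. The ML intercept is the logit of the sample
  proportion exactly; the 95% CI is Wald on the logit scale,
  back-transformed. Separation (all-true/all-false) returns the proportion
  with a degenerate CI and a warning rather than failing.
* **P-value level** (is a given p an error?): p-values are nested within
  articles, so a random-intercept logistic model
  y_ij ~ Bernoulli(logit⁻¹(x_ij'β + u_i)), u_i ~ N(0, σ²) is fitted by
  maximum likelihood with adaptive Gauss–Hermite quadrature (15 nodes by
  default; each cluster's integrand is recentred at its posterior mode and
  rescaled by its Laplace SD, which keeps few-node quadrature accurate for
  binary outcomes with small clusters). The reported probability is the
  inverse logit of the fixed intercept — the *typical-article* (conditional)
  rate — because single reported probabilities of this kind conventionally
  come from the fixed part of the model; the population-averaged (marginal)
  value ∫ logit⁻¹(β₀ + σz) φ(z) dz is exposed alongside, since the two
  differ under heterogeneity. CIs are Wald on the logit scale. Standard
  errors come from a finite-difference Hessian; when σ is weakly identified
  (e.g. single-observation clusters make the joint Hessian near-singular),
  the fallback is the curvature in β with log σ held at its estimate.
  The implementation agrees with lme4's `glmer` (nAGQ = 15) to ~10⁻⁵ on
  shared data, which the test suite verifies through an `Rscript` call.
* **Group comparisons** (journal, co-piloting, response): the group enters
  the multilevel model as a dummy-coded fixed factor; the omnibus test is a
  likelihood-ratio χ² on (groups − 1) df, and all pairwise contrasts are
  Wald tests flagged at α / n_planned_tests (Bonferroni; the division
  constant is a parameter, conventionally six planned tests). The
  conditional P(gross | error) comparison restricts to error rows first and
  validates gross ⊆ error.

Co-piloting counts are coded binary: 1 when two or more persons were
involved, 0 otherwise.

## Numerical and testing choices

* Tail probabilities come from scipy; the test suite checks them to 10⁻¹⁰
  against an independent oracle that integrates density formulas written
  out from log-gamma functions.
* The classifier is verified against a brute-force oracle that enumerates a
  dense grid (step 10^−(d+3)) of candidate statistic values inside the
  rounding interval and checks region membership pointwise — 100% agreement
  on 1,000 randomized reports.
* Optimisation is L-BFGS-B over (β, log σ) with log σ bounded in [−10, 3];
  σ below 10⁻⁴ is reported as a zero-variance fit (valid, not an error).
  A `fix_sigma_zero` option collapses the model to ordinary logistic
  regression, used both as the LR-test null and as a consistency check.
* Problem sizes in the acceptance checks — 1,000 oracle reports, 50 seeds ×
  500 articles for rate recovery, one 500-article corpus for multilevel
  recovery — were chosen to give ~3-sigma resolution on each recovered
  parameter while keeping a full run to minutes on one core.

## Known limitations

* Sentence segmentation and the sidedness window are heuristics; both can
  mislabel contrived prose (e.g. a sidedness keyword near, but not about,
  a result).
* The grammar does not recover results interleaved with effect sizes, so
  retrieval is a lower bound on what an article contains.
* `p < v` is read as a strict claim about v with no rounding band; authors
  who write `p < .036` meaning "rounds below" would be judged slightly more
  strictly.
* The checker cannot say which of the three numbers is wrong, only that
  they disagree.
* Wald CIs on σ near the boundary are unreliable; the LR test against
  `fix_sigma_zero` is the better tool there.
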