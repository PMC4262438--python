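"""Estimate error prevalence at the article and p-value level.

Article level uses an intercept-only logistic model (the probability equals
the sample proportion; the CI is Wald on the log-odds scale).  The p-value
level respects the nesting of p-values within articles with a
random-intercept logistic model fitted by adaptive Gauss-Hermite quadrature;
it reports the typical-article probability, the population-averaged
probability and the between-article SD on the log-odds scale.
"""

from reportcheck import (SyntheticSpec, check_texts, estimate_article_rate,
                         estimate_p_level_rate, generate)

# Corpus with genuine between-article heterogeneity (SD 1.0 on the log odds).
spec = SyntheticSpec(n_articles=300, error_rate=0.10, article_effect_sd=1.0,
                     seed=7)
corpus = generate(spec)
results, articles = check_texts(corpus.texts)

art = estimate_article_rate(articles["any_error"])
print(f"P(article has >= 1 error)   = {art.probability:.3f} "
      f"[{art.ci_lo:.3f}, {art.ci_hi:.3f}]  (n = {art.n} articles)")

p = estimate_p_level_rate(results["error"], results["article_id"])
print(f"P(p-value is an error)      = {p.probability:.3f} "
      f"[{p.ci_lo:.3f}, {p.ci_hi:.3f}]  (n = {p.n} p-values)")
print(f"  population-averaged rate  = {p.marginal:.3f}")
print(f"  between-article SD (logit)= {p.random_intercept_sd:.2f} "
      f"(generating value: 1.0)")

# The typical-article probability is below the population-averaged one when
# heterogeneity is large and the rate is below one half.
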