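"""Generate a synthetic corpus with planted errors and check it end to end.

The generator writes articles whose APA results have a known consistency
status: a configurable fraction of reported p-values is perturbed into
inconsistency, and a sub-fraction of those is forced across the alpha = .05
boundary.  Because planted errors are placed well clear of all rounding
ambiguity, the checker's verdicts must match the planted truth exactly.
"""

from reportcheck import SyntheticSpec, check_texts, generate

spec = SyntheticSpec(n_articles=50, error_rate=0.10, gross_fraction=0.08,
                     article_effect_sd=0.0, seed=42)
corpus = generate(spec)
results, articles = check_texts(corpus.texts)

print(f"articles: {len(articles)}, extracted results: {len(results)}")
print(f"flagged errors:       {int(results['error'].sum())}")
print(f"flagged gross errors: {int(results['gross_error'].sum())}")
print(f"planted errors:       {int(corpus.truth['is_error'].sum())}")
print(f"planted gross errors: {int(corpus.truth['is_gross'].sum())}")

match = (results["error"].to_numpy() == corpus.truth["is_error"].to_numpy()).all()
print(f"checker matches planted truth exactly: {bool(match)}")

# Per-article aggregation: the fraction of articles with >= 1 error grows
# with the article's report count, so it is much larger than the per-p rate.
print(f"articles with >= 1 error: {articles['any_error'].mean():.1%}")
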