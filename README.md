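# reportcheck

Automated consistency checking of statistical results reported in APA style,
with prevalence modelling of the errors it finds.

Most empirical psychology (and much of the life and social sciences) reports
null-hypothesis significance tests in the APA format, e.g.
`t(28) = 2.20, p = .036` or `F(1, 20) = 9.5, p < .006`. That format is
redundant: the test statistic and its degrees of freedom determine the
p-value. `reportcheck` exploits the redundancy to audit articles
automatically. It

1. **extracts** APA-formatted *t*, *F*, χ², *r* and *Z* results from plain
   text or HTML, with heuristics for one-tailed wording ("one-tailed",
   "one-sided", "directional") and significance wording in the surrounding
   sentence;
2. **recomputes** the p-value implied by each statistic, propagating the
   rounding of the printed statistic into an interval
   [p(|s|+h), p(|s|−h)] with h = ½·10⁻ᵈ for a statistic printed to d
   decimals;
3. **classifies** each result: *consistent* when the recomputed interval
   overlaps the region admissible under the reported claim (`p = .03` at two
   decimals claims [.025, .035]; `p < .05` claims [0, .05)), an **error**
   otherwise, and a **gross error** when the entire recomputed interval sits
   on the opposite side of α = .05 from the reported claim — an
   inconsistency that can flip the study's conclusion;
4. **estimates prevalence**: the probability that an article contains at
   least one error (intercept-only logistic regression; the estimate equals
   the sample proportion, with a Wald CI on the logit scale) and the
   probability that a given p-value is an error (random-intercept logistic
   regression with article as the clustering factor, fitted by adaptive
   Gauss–Hermite quadrature), plus multilevel group comparisons at a
   Bonferroni-corrected α.

Real journal corpora are copyrighted, so the package ships a synthetic
corpus generator that plants errors at known rates — including forced
significance flips and between-article heterogeneity on the log-odds scale —
letting every pipeline stage be validated against ground truth.

## Worked example

```python
from reportcheck import scan_text, p_interval_from_stat, classify

SNIPPET = ("All two-way interactions were significant: "
           "A×B, F(1, 20) = 9.5, p<.006; A×C, F(1, 20) = 0.54, p<.03; "
           "and C×B, F(1, 20) = 6.8, p<.02")

for report in scan_text(SNIPPET, article_id="example"):
    interval = p_interval_from_stat(report)
    verdict = classify(report, interval)
    print(report.raw, "->", verdict.reason, f"(recomputed p={interval.p_mid:.3f})")
```

prints

```
F(1, 20) = 9.5, p<.006 -> consistent (recomputed p=0.006)
F(1, 20) = 0.54, p<.03 -> gross_inconsistency (recomputed p=0.471)
F(1, 20) = 6.8, p<.02 -> consistent (recomputed p=0.017)
```

An F of 0.54 on (1, 20) degrees of freedom implies p = .47, not p < .03: the
second result is not just misreported but would reverse the significance
decision. The other two reported bounds agree with their recomputed values.

Longer narrative examples live in `examples/`:

* `worked_example.py` — the snippet above with rounding bounds shown;
* `synthetic_pipeline.py` — generate a 50-article corpus with 10% planted
  errors and verify the checker recovers the planted truth exactly;
* `prevalence_models.py` — article- and p-value-level prevalence with a
  multilevel model recovering the generating between-article SD;
* `group_comparison.py` — journal comparisons with likelihood-ratio omnibus
  tests and Bonferroni-corrected pairwise contrasts.

## Command line

```bash
reportcheck synth --n-articles 50 --seed 123 --out-dir corpus/ --truth truth.csv
reportcheck check corpus/*.txt --out-results results.csv --out-articles articles.csv
reportcheck prevalence --results results.csv --articles articles.csv --out estimates.json
```

`check` accepts `--metadata meta.csv` (columns `article_id`, `journal`,
`copilot_*` involvement counts), `--alpha` and `--one-tailed-window`; it
exits 0 on success and 2 on hard errors such as duplicate metadata ids.

## Scope and caveats

* Input is already-converted text: no PDF parsing or OCR.
* Results with effect sizes interposed between statistic and p-value
  (`F(1, 46) = 8.41, ηp² = .16, p = .006`) are not parseable under the
  grammar; they are counted in a skipped-candidates diagnostic.
* P-values in power-of-ten notation, p-values above 1, and statistics
  outside their null support are excluded at validation.
* The checker flags inconsistencies; it does not infer which of the
  statistic, the degrees of freedom, or the p-value is the wrong one.

See `docs/methods.md` for the statistical details and design decisions.
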