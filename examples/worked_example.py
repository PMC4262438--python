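"""Check a prose snippet containing three F-test results.

The middle result, F(1, 20) = 0.54, is reported as p < .03, but an F of 0.54
on 1 and 20 degrees of freedom actually implies p = .47 — an inconsistency
large enough to flip the significance decision (a gross error).
"""

from reportcheck import classify, p_interval_from_stat, scan_text

SNIPPET = (
    "All two-way interactions were significant: A×B, F(1, 20) = 9.5, p<.006; "
    "A×C, F(1, 20) = 0.54, p<.03; and C×B, F(1, 20) = 6.8, p<.02"
)

reports = scan_text(SNIPPET, article_id="example")
print(f"extracted {len(reports)} APA-formatted results\n")
for report in reports:
    interval = p_interval_from_stat(report)
    verdict = classify(report, interval)
    status = "GROSS ERROR" if verdict.gross_error else (
        "error" if verdict.error else "consistent")
    print(f"  {report.raw}")
    print(f"    recomputed p = {interval.p_mid:.3f} "
          f"(rounding bounds [{interval.p_lo:.3f}, {interval.p_hi:.3f}]) -> {status}")

# The recomputed p is the tail probability of the F distribution at the
# printed statistic; the bounds account for the statistic's own rounding.
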