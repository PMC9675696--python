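"""Compare the tiered staining algorithms with the full-panel gold standard.

Loads the packaged 113-tumour reconstructed cohort, replays the gold
standard and tiered Algorithms 1-3 against every tumour, and prints the
concordance / workload / cost table.
"""

from pitnet_triage import build_reference_cohort, evaluate, render_report

cohort = build_reference_cohort()
report = evaluate(cohort, algorithms=(1, 2, 3), unit_cost=50.0)
print(render_report(report))
print()
print(
    "Each row is one staining strategy: concordance is the fraction of\n"
    "tumours whose tier-limited diagnosis equals the full 9-stain diagnosis;\n"
    "avg_stains is the mean number of immunostains per tumour and avg_cost\n"
    "its cost at $50 AUD per stain.  The tiered algorithms lose no diagnoses\n"
    "on this cohort while Algorithm 3 nearly halves the staining cost."
)
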