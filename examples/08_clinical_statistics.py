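"""Clinical association statistics on printed cohort counts.

Reproduces the study-level worked examples: mutation-phenotype enrichment
by Wald test on the log odds ratio (with Haldane correction for zero
cells), and the matched-therapy complete remission comparison by Fisher's
exact test.
"""

import math

from mpalkit.stats import fisher_exact_2x2, wald_log_or

print("mutation enrichment (myeloid-B vs myeloid-T):")
for gene, table in (("RUNX1", [[6, 7], [2, 16]]), ("NOTCH1", [[9, 9], [0, 13]])):
    res = wald_log_or(table, label=gene)
    ci = f"[{math.exp(res.ci_low):.2f}, {math.exp(res.ci_high):.2f}]"
    haldane = " (Haldane 0.5 correction)" if res.haldane_applied else ""
    print(
        f"  {gene:7} OR={math.exp(res.log_odds_ratio):6.2f}  95% CI {ci:16}"
        f"  p={res.p_value:.3f}{haldane}"
    )

p = fisher_exact_2x2([[13, 5], [2, 7]])
print(
    f"\nmatched vs unmatched therapy CR: 13/18 (72%) vs 2/9 (22%), "
    f"Fisher p = {p:.3f}"
)
print(
    "\nRUNX1 mutations are enriched in myeloid-B and NOTCH1 in myeloid-T"
    "\n(both p < 0.05), and patients whose induction regimen matched their"
    "\nmethylation-defined lineage achieved complete remission significantly"
    "\nmore often."
)
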