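"""Test whether stem-loops and promoters are enriched by cluster side.

Uses the genome-survey count table for long (>50 bp) intergenic regions
between SBP genes and their cognate translocator genes: 221 IRs from
clusters with a 5'-end SBP and 85 from clusters with a 3'-end SBP.  The
exact one-sided hypergeometric test asks whether a feature concentrates on
one side beyond what sampling without replacement would give.
"""

from termstoich import EnrichmentInput, enrichment_test

counts = {
    "stemloop": EnrichmentInput(221, 85, 193, 20, "stemloop"),
    "promoter": EnrichmentInput(221, 85, 46, 45, "promoter"),
}

for name, inp in counts.items():
    res = enrichment_test(inp)
    print(f"{name:>9}: 5' {res.pct_5p:5.1f}%  3' {res.pct_3p:5.1f}%  "
          f"-> {res.direction}  (p = {res.p_value:.2e})")
# Stem-loops concentrate downstream of 5'-end SBPs (premature termination
# keeps the SBP transcript abundant); promoters concentrate upstream of
# 3'-end SBPs (independent re-initiation).  Both tails are far below 1e-4.
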