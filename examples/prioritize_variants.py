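"""Significance filtering, lead-SNP selection and functional ranking.

Variants are screened at p < 1e-8, the minimum-p variant becomes the
lead, and RegulomeDB-style ranks ("1a" most functional ... "7" least)
order the survivors for follow-up.
"""

from locusfine import (
    SimConfig,
    filter_significant,
    lead_variant,
    merge_functional_ranks,
    prioritize,
    simulate_locus,
)

table, _, truth = simulate_locus(SimConfig(m=100, rho=0.9, lam=9.0, seed=3))

sig = filter_significant(table, threshold=1e-8)
print(f"{len(sig)} of {len(table)} variants pass p < 1e-8")

lead = lead_variant(sig)
print(f"lead SNP (minimum p): {lead}")

# attach functional evidence to a few variants (normally read from a TSV)
ranks = {lead: "1b", sig.rsids[0]: "5", sig.rsids[-1]: "2a"}
annotated, rejected = merge_functional_ranks(sig, ranks)

report = prioritize(annotated)
print(report.head(5).to_string(index=False))
# Rows sort by functional rank first, then by p; a "1b" variant (strong
# TF-binding + matched footprint evidence) outranks everything ranked
# worse regardless of p, and unranked variants sort last.
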