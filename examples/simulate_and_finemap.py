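"""Simulate a GWAS locus with one causal variant and fine-map it.

The generator draws z-scores from MVN(R*lam*e_c, R) with AR(1) LD, turns
them into beta/SE/p/MAF/N summary statistics, and the fine-mapper
recovers the causal variant via Wakefield approximate Bayes factors.
"""

from locusfine import PriorSpec, SimConfig, finemap_locus, simulate_locus

# 100 variants, LD decaying as 0.9^distance, causal z-score expectation 8
table, ld, truth = simulate_locus(SimConfig(m=100, rho=0.9, lam=8.0, seed=42))

result = finemap_locus(table, PriorSpec(W=0.04), level=0.95)

idx = result.rsids.index(truth.causal_rsid)
print(f"true causal variant : {truth.causal_rsid}")
print(f"top-PIP variant     : {result.top_variant}")
print(f"causal variant PIP  : {result.pip[idx]:.4f}")
print(f"95% credible set    : {list(result.credible_set)}")
print(f"credible-set mass   : {result.credible_mass:.4f}")
# The PIP is the posterior probability that the variant is THE causal one
# under a single-causal-variant model; the credible set is the smallest
# group of variants whose cumulative PIP exceeds 0.95.
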