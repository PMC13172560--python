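# locusfine

Single-causal-variant statistical fine-mapping of a GWAS locus from
summary statistics, for statistical geneticists who need to resolve a
dense cluster of associated SNPs down to its likely causal variant —
and to show that the rest of the cluster is linkage disequilibrium (LD)
shadow, not independent signal.

`locusfine` implements the full analysis chain around a locus such as
the BMI-associated *ADCY3* region on chromosome 2:

1. **Prioritization** — ingest per-variant summary statistics
   (rsID, position, β, SE, p, MAF, N), screen at p < 1×10⁻⁸, pick the
   lead SNP (minimum p), and order candidates by RegulomeDB-style
   functional rank ("1a" strongest … "7").
2. **Fine-mapping** — Wakefield's approximate Bayes factor per variant.
   With V = SE², shrinkage r = W/(V+W) and a N(0, W) prior on the true
   effect (default prior variance W = 0.04),

   &nbsp;&nbsp;&nbsp;&nbsp;log ABF = ½ [ ln(1−r) + r·z² ],&nbsp;&nbsp; z = β̂/SE,

   stored in the association direction.  Under a single-causal-variant
   model the posterior inclusion probability is the normalized Bayes
   factor, PIPᵢ = wᵢ·ABFᵢ / Σⱼ wⱼ·ABFⱼ (log-sum-exp, overflow-safe),
   and the 95% credible set is the smallest descending-PIP prefix whose
   cumulative PIP exceeds 0.95.
3. **LD structure and signal decay** — lead-relative r² from a signed
   correlation matrix or an LDlink-style export, variant counts per r²
   stratum, and mean −log₁₀(p) per stratum.  A strictly decreasing
   column of means is the signature of one causal signal diffusing
   through LD.
4. **Simulation** — synthetic loci with known truth under the standard
   summary-statistic model: AR(1) LD matrix R (R[i,j] = ρ^|i−j|),
   z ~ MVN(R·λ·e_c, R) with one causal variant of non-centrality λ,
   and β/SE/p derived via SE = 1/√(2·N·f·(1−f)).  This is how the
   credible sets are shown to be calibrated.

All −log₁₀(p) arithmetic goes through the normal log-survival function,
so loci with p far below the double-precision floor (the lead SNP of
the *ADCY3* region sits at p ≈ 5×10⁻⁸⁸; |z| > 38 underflows p to 0)
are handled exactly.

## Worked example

```python
from locusfine import PriorSpec, SimConfig, finemap_locus, simulate_locus

table, ld, truth = simulate_locus(SimConfig(m=100, rho=0.9, lam=8.0, seed=42))
result = finemap_locus(table, PriorSpec(W=0.04), level=0.95)
idx = result.rsids.index(truth.causal_rsid)
print(truth.causal_rsid, result.top_variant, result.pip[idx], result.credible_set)
```

Running `python examples/simulate_and_finemap.py` prints:

```
true causal variant : rs900050
top-PIP variant     : rs900050
causal variant PIP  : 0.9964
95% credible set    : ['rs900050']
credible-set mass   : 0.9964
```

The simulated causal variant carries 99.6% of the posterior mass and is
the sole member of the 95% credible set — the locus resolves to a single
variant, exactly the behaviour the method is meant to demonstrate on a
real locus.  The other scripts in `examples/` walk through LD binning
and signal decay, functional-rank prioritization, and credible-set
calibration; `examples/cli_pipeline.sh` drives the same pipeline from
the shell via the `locusfine` command (subcommands `simulate`,
`prioritize`, `finemap`, `decay`, `calibrate`, `report`).

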