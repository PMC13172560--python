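# Methods

## Model

`locusfine` works entirely from GWAS summary statistics under the
single-causal-variant assumption: exactly one variant at the locus has
a true effect, every other variant's association is induced through LD
with it.  This is the model under which the Wakefield approximate Bayes
factor (ABF) yields posterior inclusion probabilities by simple
normalization, and it is the right model for a locus whose association
strength decays monotonically with lead-relative r² — the pattern the
decay module is designed to test.

For a variant with estimated effect β̂, standard error SE (V = SE²) and
a normal prior N(0, W) on the true effect, the marginal-likelihood
ratio of the association model to the null is available in closed form:

    ABF = √(V/(V+W)) · exp(z²·W / (2(V+W))),   z = β̂/SE.

We store the natural log, `log_abf = ½[ln(1−r) + r·z²]` with shrinkage
r = W/(V+W).  Wakefield's original ABF favours the null; this package
stores the reciprocal (association direction) because PIP normalization
requires evidence *for* association — the sign convention is stated
here once and asserted in tests.  The closed form is exact for the
normal–normal model; the test suite verifies it against adaptive
quadrature of the defining integral to 1e−6 relative (it agrees to
~1e−14).

PIPs are w·exp(labf) normalized by log-sum-exp (max subtraction), so
log-ABFs of any magnitude — loci with z ≈ 20 produce labf ≈ 160, and
nothing prevents thousands — normalize without overflow.  PIPs sum to
1 within 1e−12 (asserted).

The level-α credible set sorts variants by PIP descending (ties broken
by smaller p, then smaller position, then rsid — fully deterministic)
and returns the shortest prefix with cumulative PIP strictly greater
than α ("exceeds", not "reaches": the boundary case goes to the larger
set).  Minimality is a tested invariant: dropping the last member
always leaves mass ≤ α.

## Parameters that matter

- **W (prior variance of the causal effect), default 0.04.**  Units:
  squared trait-SD per allele, i.e. prior SD 0.2 — the conventional
  choice for quantitative traits.  W is interpreted on the β scale; if
  only z-scores exist, `finemap_zscores` takes V = 1 and reinterprets W
  on the z scale, always with a loud `ZScaleWarning`, never silently.
  W = 0 degenerates to BF = 1 everywhere and exactly uniform PIPs.
- **Credible level, default 0.95.**
- **Screening threshold, default 1×10⁻⁸** (the locus-definition step),
  with 5×10⁻⁸ available as the conventional genome-wide preset used by
  the significance-count analysis.
- **Per-variant priors: uniform.**  No MAF- or annotation-dependent
  weighting; functional ranks order the report but never reweight the
  posterior.

## LD binning

r² strata are half-open intervals partitioning [0, 1], boundary in the
upper bin, so every value lands in exactly one stratum.  Two presets:
`counts` (edges 0, 0.2, 0.5, 0.8, 1) matching the high/moderate/lower/
low-LD accounting, and `decay` (edges 0, 0.2, 0.4, 0.6, 0.8, 1) for the
equal-width decay analysis.  The decay preset includes the 0.2–0.4 bin
even though summaries often omit it: a partition must be exhaustive,
and reporting layers can drop rows.  Variants with missing r² (absent
from the reference panel) are excluded from every stratum and counted
separately — missing is not zero.  Decay means are arithmetic means of
−log₁₀(p), not −log₁₀ of mean p; display rounds to one decimal, full
precision is retained.  The lead variant (r² = 1) is included in the
top stratum by default (the regional-plot convention) with a flag to
exclude it.

## Synthetic-data generator

The generator emulates precisely the statistical structure the
fine-mapper assumes — the point is a closed loop in which calibration
claims are checkable:

- **LD**: AR(1), R[i,j] = ρ^|i−j|, positive-definite by construction,
  one interpretable parameter.  A block-diagonal preset (constant
  within-block correlation) exercises credible-set edge cases with
  near-exchangeable variants.  User-supplied matrices that fail
  Cholesky get one 1e−8 ridge retry with a warning.
- **Z-scores**: z = R·λ·e_c + L·η, L the Cholesky factor, η iid
  standard normal — i.e. z ~ MVN(R·λ·e_c, R), the standard
  summary-statistic sampling model.  E[z_j] = λ·ρ^|j−c|, so signal
  decays geometrically with distance from the causal variant, feeding
  the decay analysis its expected monotone structure.
- **Summary statistics**: SE = 1/√(2·N·f·(1−f)) (per-allele effect on
  a standardised trait at MAF f), β = z·SE, two-sided normal p.  λ is
  specified on the z scale so power is independent of N/MAF
  bookkeeping; the implied β-scale effect is recorded in the truth
  record.

Defaults are the calibration study conditions: m = 100 variants,
ρ = 0.9, λ = 8 (causal p ≈ 1.2×10⁻¹⁵ in expectation — a strong but
realistic GWAS signal), N = 100,000, MAF ~ U(0.05, 0.5), 1 kb spacing.
All randomness flows from one integer seed through a named
`numpy.random.Generator`; identical config + seed reproduces outputs
byte-for-byte.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: allelic heterogeneity (multiple causal
variants), realistic block-structured LD from a finite reference panel
(including r² estimation noise and panel/GWAS ancestry mismatch),
MAF-dependent imputation quality, and summary-statistic quality-control
artefacts.  Calibration under the generator demonstrates internal
consistency of the method, not robustness to model misspecification.

## Numerical choices

- −log₁₀(p) is always computed from z via the normal log-survival
  function; p itself is never the internal carrier of significance.
  This keeps |z| up to (at least) 40 — p ≈ 10⁻³⁴⁹, far past
  double-precision underflow — finite and accurate to 1e−6 relative
  (checked against an arbitrary-precision erfc oracle).
- ln(1−r) is evaluated as ln(V/(V+W)) to remain accurate as r → 1.
- MAF folding (f > 0.5 → 1−f) is applied at record construction and is
  idempotent.
- Allele harmonization accepts exact match or swap-with-sign-flip only;
  ambiguous strand flips are rejected rather than guessed.
- Records carrying only a p-value (no β/SE and no explicit sign) are
  excluded from fine-mapping and reported — a sign is never invented.
- Pipeline runs stage outputs in a temporary directory and move them
  into place on success, so a failed run leaves no partial files; the
  run-metadata file records the configuration, a config hash (output
  path excluded, so identical analyses hash identically anywhere) and
  every warning raised by lower layers.

## Design decisions that were genuinely open

- **PIP normalization set**: over all variants with usable β/SE at the
  locus (not only those with LD data).  LD information affects binning
  and decay, not the posterior.
- **Null-calibration testing**: at λ = 0 the mean PIP of each variant
  over replicates should be 1/m within Monte-Carlo error.  Checking
  100 variants against 3-SE bands simultaneously implies ~0.3 expected
  chance exceedances, so the automated check asserts that ≥97% of
  variants sit within 3 SE and none beyond 5 SE — the multiplicity-
  aware reading of the per-variant criterion; genuine miscalibration
  moves all variants at once and fails both clauses immediately.
- **Calibration replicate seeds** are drawn from a master generator
  seeded once, keeping every replicate independent yet the whole run
  reproducible from a single integer.
- **Problem sizes** in the automated checks (1,000 calibration
  replicates, 1,000 null replicates, 200 decay replicates, 100 oracle
  triples) are the package's documented study conditions; they complete
  in well under a minute combined.

## Known limitations

Single-causal-variant only: no conditional analysis, no SuSiE/FINEMAP-
style multi-signal regression, no colocalization, no functional-prior
reweighting.  LD is consumed, never estimated from genotypes.  Genome
coordinates are taken as given (hg38 convention for the motivating
locus); no liftover.  These are scope boundaries, not TODOs.
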