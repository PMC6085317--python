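# Methods

This note documents the statistical models implemented in `metagwas`, the
assumptions behind them, the parameters that matter, and the design choices
made where the literature leaves the details open.

## Stratified meta-analysis

Each stratum k contributes a per-allele log odds ratio β̂ₖ with standard
error seₖ, assumed approximately normal (large-sample logistic regression).
Fixed-effects pooling uses weights wₖ = seₖ⁻²:

    β̂ = Σwₖβ̂ₖ / Σwₖ,   se(β̂) = (Σwₖ)^(−1/2),

which is exactly the generalized-least-squares solution for a common mean —
the test suite verifies this equivalence to 10⁻¹². Heterogeneity is
Cochran's Q = Σwₖ(β̂ₖ−β̂)² on K−1 df, with I² = max(0, (Q−df)/Q)·100.
Random-effects pooling is DerSimonian–Laird: τ² = max(0, (Q−df)/(Σw−Σw²/Σw)),
weights (seₖ²+τ²)⁻¹, so homogeneous inputs reduce exactly to the
fixed-effects result.

**QC filters.** Per stratum, a variant is excluded when info < 0.4,
MAF < 0.005, or |ln OR| > ln 3; all bounds are strict, so boundary values are
retained (the OR bound is compared on the log scale, which makes the (1/3, 3)
pair exactly symmetric and avoids the rounding asymmetry of exponentiating).
MAF is folded as min(eaf, 1−eaf) — the only frequency-symmetric reading.
After pooling, variants with fewer than two contributing strata or
heterogeneity P < 5×10⁻⁸ are dropped; every exclusion carries a reason code
in an audit table.

**Genomic control.** λ is the median pooled χ² divided by 0.4549364 (the
χ²₁ median) — the standard median estimator, chosen for robustness to true
signal. λ₁₀₀₀ applies the Freedman rescaling
1 + (λ−1)(1/n_cases + 1/n_controls)/(2/1000); the intent (comparability at a
notional 1000/1000 design) fixes the formula even though sources often state
only the intent.

## Locus definition and conditional analysis

Genome-wide-significant variants (P < 5×10⁻⁸) seed ±500 kb windows;
overlapping windows on a chromosome merge, and windows within 500 kb of a
supplied list of previously reported leads are removed before clumping. The
locus lead is the minimum-P member, with ties broken by smaller se and then
lexicographic variant id so output is deterministic.

Conditional analysis follows the standard summary-data joint-analysis
linearization. Marginal per-allele effects are standardized with
dⱼ = √(2pⱼ(1−pⱼ)); the joint coefficients on the restricted set S (current
signals plus one target) solve R_S b_joint = b_std using the external LD
correlation matrix R, and Var(b_joint) ≈ v̄·(R_S⁻¹) with v̄ the median
standardized marginal sampling variance over S (the per-variant variances in
a locus are near-equal once standardized; the median is robust to an outlier
frequency). The target coefficient is back-transformed by 1/d. This is a
linear approximation to the logistic joint model; its accuracy is quantified
against an individual-level joint regression oracle on simulated LD blocks
(within 3 joint-model se in ≥95% of blocks at n = 5000, m = 5 — a
simulation size chosen to make the joint fit well-conditioned while keeping
the suite fast). Stepwise selection admits the best remaining variant while
its conditional P < 5×10⁻⁸ and its r² with every selected signal is < 0.05;
targets with r² > 0.9 (configurable cap) against the conditioning set are
reported as degenerate rather than solved, and near-singular conditioning
sets raise a collinearity error naming the offending pair.

## Credible sets

The relative likelihood of member j versus the lead is the Wald
approximation Λⱼ = exp((zⱼ²−z_lead²)/2) — the only likelihood ratio
computable from summary data. ccrSNPs are members within ±500 kb of the lead
with Λⱼ ≥ 0.01; the comparison carries a 10⁻⁹ relative slack so a variant at
exactly the 1:100 boundary ("no less than") survives floating-point rounding
of z². Windows are anchored on the lead, not the merged locus span.

## Bayesian false discovery probability

V = se², with se recovered from the printed two-sided P via
se = |β|/Φ⁻¹(1−P/2) when no se is given — the P-derived route is the default
when both P and CI are available because printed CIs are more coarsely
rounded. The prior effect variance is W = (ln 1.5/1.96)², i.e. the prior
97.5th percentile of the OR equals the maximum plausible OR of 1.5; the
prior probability of association is π = 10⁻⁴. Then

    ABF = √((V+W)/V) · exp(−z²W/(2(V+W))),  BFDP = ABF·PO/(ABF·PO+1),

with PO = (1−π)/π. BFDP → 1 as z → 0 (for small π) and → 0 as |z| → ∞.

## Familial relative risk

Under a log-additive model, variant j with frequency pⱼ, log OR βⱼ and se τⱼ
contributes cⱼ = pⱼ(1−pⱼ)(βⱼ²−τⱼ²) to ln FRR, and a set explains
Σcⱼ/ln λ of the FRR (λ = 2 by default). The τ² subtraction debiases β̂ⱼ²;
negative contributions (τ > |β|) are retained with a warning, since flooring
would bias sums upward. The formula is symmetric in p ↔ 1−p, so the
EAF-vs-MAF ambiguity of printed tables is immaterial. Per-variant effective
sample sizes Nⱼ = 1/(2pⱼ(1−pⱼ)τⱼ²) are exported for frailty-scale
heritability estimation by external LD-score software; h²_f/(2 ln λ)
converts a frailty-scale heritability to an FRR fraction.

## Mendelian randomization

Univariable IVW combines per-SNP Wald ratios with fixed-effect weights
1/se_outcome², equivalent to a no-intercept weighted regression of outcome
on exposure effects (verified against that oracle to 10⁻¹²). Exposure-side
standard errors are ignored in the weighting, the standard two-sample
convention; no measurement-error (regression-dilution) correction is
applied, so simulations validating slope recovery use instrument effects
measured precisely relative to their spread. Fixed-effect weighting is the
default; a multiplicative random-effect option inflates se by √(Q/df) when
Q > df. Multivariable MR regresses outcome effects on two exposures'
effects (no intercept, weights 1/se_outcome²), yielding direct effects; a
mediator whose instrument effects are numerically zero degenerates cleanly
to the univariable fit (warned), while genuine collinearity raises an
identifiability error. No MR-Egger or median estimators are provided.

## Case-only subtype heterogeneity

Among cases only, logistic regression of the subtype indicator on allele
dosage estimates the difference between subtype-specific case-control log
ORs (shared controls cancel). Perfect or near separation (|se| blowing up)
raises a dedicated error carrying the exact 2×2 fallback. A hard-call 2×2
allele table with Fisher's exact test is always reported as a diagnostic
cross-check. The summary-level contrast z = (β₁−β₂)/√(se₁²+se₂²) is provided
for situations where only subgroup estimates exist, but is labeled
approximate: with shared controls the independence assumption fails and it
will generally disagree with the case-only test.

## Annotation enrichment

SNP positions are 1-based; BED intervals 0-based half-open. A SNP at
position q overlaps [s, e) iff s ≤ q−1 < e — this conversion is the single
point of truth. Overlap is computed by a per-chromosome binary-search sweep
over merged intervals (merging cannot change any-feature flags, a property
the suite checks), validated against a brute-force O(n·m) scan. Enrichment
between two overlap summaries uses Fisher's exact test with the two-sided
probability-mass definition (sum over tables no more probable than
observed), checked against full enumeration of the hypergeometric support.

## Synthetic data

Summary statistics are simulated at the summary level: β̂ⱼₖ ~ N(βⱼ, τ²ⱼₖ)
with τ²ⱼₖ = [2pⱼ(1−pⱼ)·infoⱼₖ·ñₖ]⁻¹, ñₖ = n_cases·n_controls/(n_cases+n_controls),
the balanced score-test variance consistent with the effective-sample-size
relation at info = 1. The default stratum design mirrors a 17-stratum
consortium (two dominant strata, a long tail of small ones; ~12.9k cases,
~109k controls). Individual-level data exist only where an oracle needs
them: LD blocks draw two latent AR(1)-correlated Gaussian haplotypes per
individual, thresholded at the allele-frequency quantile and summed to
dosages, with a Gaussian phenotype — the resulting dosage correlation is
below the latent ρ (the thresholded-bivariate-normal attenuation, verified
against numeric integration). Case-only sets shift the subtype-B allele
logit by the planted log OR; MR tables draw exposure effects uniform in
±[0.02, 0.1] with a mediated component and optional pleiotropy.

What the generators do *not* emulate: genome-scale LD structure, population
stratification, imputation artefacts correlated across strata, winner's
curse in lead selection, or overlapping samples between strata. Passing
tests therefore demonstrate correctness of the estimators under their
stated sampling models, not robustness to those real-data pathologies.

## Numerical choices and limitations

- Fixed normal quantile 1.959964 for all CI ↔ se conversions.
- P-values are floored at the smallest positive double rather than returned
  as 0.
- Meta-output ordering (chrom, pos, id) and lead tie-breaking are fully
  deterministic; all simulation randomness flows through a single
  `numpy.random.default_rng(seed)` per generator call.
- The conditional solver's v̄ (median standardized variance) assumption
  degrades when a locus mixes very rare and common variants; the
  individual-level oracle quantifies this in tests.
- Multi-allelic and indel variants are accepted as arbitrary allele strings;
  reconciliation across imputation panels is the caller's responsibility.
- `lambda_gc` warns below 100 variants; the estimator is meaningless on a
  handful of statistics.
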