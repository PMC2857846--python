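# Methods

This note documents the models, the sampler, the simulator and the numerical
choices behind `growsel`, in the spirit of the model documentation of
packages like statsmodels or msprime.  It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Growth models

**Gompertz (analysis model).**  y(t) = A·exp(−exp(B·e·(C − t)/A)) with
A > 0 the asymptotic final yield (trait units), B > 0 the maximum growth rate
(trait units per time unit) and C the age at maximum growth rate (time
units).  This parameterisation has two exact identities used as test
anchors: y(C) = A/e and dy/dt at C equals B.  The analytic derivative is
dy/dt = B·e·exp(z)·exp(−exp(z)) with z = B·e·(C − t)/A.

**Logistic (generating model).**  y(t) = asym / (1 + exp((xmid − t)/scal))
(the `SSlogis` naming: asymptote, inflection time, time scale).  The
simulator generates from the logistic while the pipeline fits the Gompertz —
both are S-shaped with an asymptote, but the non-asymptote parameters do not
map onto each other.  This misspecification is intentional: the pipeline's
claim is robustness of breeding-value estimation to the curve family, and a
matched generator would make that claim untestable.

**Fitting.**  Per individual, Levenberg–Marquardt least squares
(`scipy.optimize.least_squares`, `method="lm"`) with the analytic Jacobian,
`ftol = xtol = 1e-10`, at most 200 function evaluations.  The inner exponent
is clipped to ±50, which leaves double-precision values unchanged while
keeping `exp` finite.  Default starting values are scale-free: A₀ = 1.05 ×
max(y); C₀ = the observed time whose yield is nearest A₀/e; B₀ = the steepest
successive slope (fallback: range/time-span for non-increasing data).
Constant records are degenerate (A and B unidentifiable) and are returned
unconverged without optimisation.  A fit is `converged` only if the optimizer
reports success *and* the solution satisfies A > 0, B > 0.  Individuals whose
fit fails are excluded from genomic evaluation with a logged count; under the
default simulator settings this affects at most a handful of the 1000
training individuals.

## Marker-effect model and Gibbs sampler

Model: y = Xb + Σᵢ gᵢαᵢ + e with e ~ N(0, σ²ₑI); each SNP effect is 0 with
probability 1 − π or N(0, σ²α) with probability π.  One slab variance is
shared by all SNPs and π is estimated — the BayesCπ flavour of whole-genome
regression rather than the original per-SNP-variance Bayes B; the shared
slab matches the single N(0, σ²α) statement of the model and is the smaller,
better-identified parameterisation.

Genotype files use codes 1/2/3 for genotypes 00, 01|10, 11.  Columns are
centered in memory before sampling (the intercept absorbs the shift); this
improves mixing and makes GEBVs mean-zero by construction.  Monomorphic
columns carry no information: their indicators are forced to 0 and their
indices reported.

Updates per cycle:

* **(δᵢ, αᵢ), i = 1…p, sequentially.**  Collapsed update: the inclusion
  probability is computed with αᵢ integrated out analytically,
  log BF = −½·log(1 + σ²α·gᵢᵀgᵢ/σ²ₑ) + σ²α·(gᵢᵀr₋ᵢ)² / (2σ²ₑ(σ²ₑ + σ²α·gᵢᵀgᵢ)),
  where r₋ᵢ is the residual excluding SNP i.  Included effects are drawn from
  the normal full conditional N(gᵢᵀr₋ᵢ/v, σ²ₑ/v), v = gᵢᵀgᵢ + σ²ₑ/σ²α.  The
  computation is log-space guarded; the collapsed form is validated against
  one-dimensional quadrature in the tests.  The residual vector is maintained
  incrementally, so a full cycle costs two length-n BLAS-1 operations per SNP.
* **b** from its flat-prior normal full conditional (intercept-only by
  default; any fixed-effect design X is accepted).
* **σ²ₑ** ~ eᵀe / χ²(n − 2) and **σ²α** ~ Σαᵢ² / χ²(k − 2), the scaled
  inverse-χ² conditionals implied by flat priors on the variances (k = number
  of active effects).  For k < 3 the effect-variance conditional is improper;
  the sampler then draws from a weakly-informative scaled-inv-χ²(df = 4.2)
  whose scale is the second moment Σαᵢ²/k of the active effects (k = 1, 2) or,
  when no effect is active, the fixed initialisation value of σ²α.  The k = 0
  scale must be a *fixed* anchor: re-centering it on the previous draw makes
  the conditional a multiplicative random walk with mean factor
  df/(df − 2) ≈ 1.9, which diverges and locks the chain into excluding
  everything.  Fallback uses are counted and reported.  Note that with a flat
  prior and few active effects the σ²α conditional is extremely heavy-tailed
  (its mean is infinite for k ≤ 4), so the posterior-mean summary of σ²α can
  be dominated by spikes; inclusion probabilities and effects are unaffected
  and are the quantities of interest.
* **π** ~ Beta(1 + k, 1 + p − k), the conjugate update under the uniform
  prior.

Initialisation: b by least squares on X alone, α = 0, δ = 0, π = 0.5,
σ²ₑ = var(y)/2, σ²α = var(y)/(2·p·0.5).  Chains are deterministic given the
seed.  Per-SNP random draws are consumed positionally, so permuting SNP
columns changes the realised path; exchangeability of the *posterior means*
is verified within Monte-Carlo error in the tests.

**Schedules.**  The reference schedule is 10000 burn-in cycles, then 10000
kept realisations separated by 50 cycles (`McmcConfig.full_scale()`).  All
package defaults use a reduced desk-scale preset — 2000 burn-in, 600 kept,
thinning 5 — which completes one 1000 × 453 analysis in roughly ten seconds
and leaves the posterior means of the quantities used downstream (inclusion
probabilities, effects, GEBVs) accurate enough that the headline correlations
are insensitive to further chain length.  Posterior means are computed over
exactly the kept states; an optional trace (π, variances, k, intercept) is
recorded for diagnostics and Monte-Carlo-error estimates.

**GEBVs.**  gebv_j = Σᵢ (g_ij − ḡᵢ)·ᾱᵢ with column means taken over exactly
the individuals being scored, so every reported GEBV vector is mean-zero over
its population.  Candidates (genotypes only) are scored identically to
training individuals.

## Two-step pipeline

Step 1 fits curves to all training individuals.  Step 2 runs four univariate
desk-scale analyses — on fitted A, B, C and on the Gompertz prediction at the
target time (default t = 600) — using point estimates as phenotypes; the
per-individual fitting uncertainty is deliberately ignored, which is exactly
the simplification the two-step design trades for tractability.  Per-analysis
chains use independent child seeds derived from the configured seed, so the
whole pipeline is reproducible bit for bit.

* **Method I**: v_j = Gompertz(μA + gebvA_j, μB + gebvB_j, μC + gebvC_j,
  t_target), re-centered.  The population means μ are the sample means of the
  training-set fitted parameters.  Individuals whose shifted A or B would
  leave the valid domain are evaluated at clipped values and counted.
  Centering both methods makes them directly comparable (they otherwise
  differ by an arbitrary mean offset).
* **Method II**: GEBVs from the analysis of the predicted t-target phenotypes.

Across replicate default populations the two routes correlate above 0.99 and
their variances agree to within about 1%; neither route has systematically
larger variance in this simulator (the sign of the small difference flips
between seeds), so the package asserts scale agreement rather than an
ordering.

Reporting: a square correlation table with Pearson below and Spearman (average
ranks for ties) above the diagonal; per-SNP tables of inclusion probabilities
and effects rescaled so the largest absolute effect within an analysis is 1;
and, for simulated data, the same correlation table against true breeding
values, overall and split by training/candidate set.  Zero-variance vectors
produce NaN correlations, never silent zeros.

## Simulator

Design defaults mirror the QTLMAS2009 workshop dataset's stated dimensions:
100 full-sib families × 20 offspring from 200 unrelated founders (monogamous
pairs; configurable), 453 SNPs evenly spaced on 5 chromosomes of 1 Morgan,
half of each family phenotyped at t = 0, 132, 265, 397, 530.  (The third time
point is taken as 265 — the equal-spacing value — where sources print an
implausible 25.)

* **Founder haplotypes**: first-order Markov chain along each chromosome with
  adjacent-locus allele correlation ρ (distance-scaled for uneven spacing),
  allele frequencies U(0.1, 0.9), correlation targets clamped to the
  feasibility bounds implied by the frequencies.  The default ρ = 0.415 was
  calibrated once, by measuring the realised mean adjacent-SNP dosage r² over
  replicate default populations, to give r² ≈ 0.15 in the offspring
  generation (clamping and one meiosis make realised r² lower than ρ²).
* **Meiosis**: Haldane model — strand switches between consecutive loci at
  distance d Morgans with probability ½(1 − exp(−2d)), random starting
  strand per chromosome.  Mendelian consistency is asserted exhaustively in
  the tests.
* **QTL**: placed at randomly chosen SNP loci, disjoint across the three
  logistic parameters (6 on the asymptote, 3 each on the other two; the
  latter counts are assumptions — only the asymptote count is documented for
  the original data — and are configurable).  An option places QTL at
  unobserved loci midway between SNPs instead.  Effect magnitudes are
  Gamma(0.4) with random signs, rescaled so each parameter's TBV variance
  hits its target exactly; a zero target gives exactly zero effects.
* **Phenotypes**: each individual's realised curve parameters are
  φ_j = μ + TBV_j + E_j with permanent-environmental deviations
  E_j ~ N(0, env_var_scale × var_TBV) per parameter (default scale 1, i.e.
  parameter heritability 0.5), and records are the logistic curve at φ_j plus
  iid N(0, residual_sd²) measurement noise (default sd 0.2 trait units, 2% of
  the mean asymptote).  Putting environmental variation on the parameters
  rather than inflating the measurement noise reflects how such longitudinal
  datasets are generated, keeps yield heritability at t = 530 near 0.5
  (genetic and environmental curve variances ≈ 1.0 against measurement
  variance 0.04), and is what allows the fitted curves to track observed
  phenotypes at r > 0.99 while genomic accuracy remains a non-trivial target.
* **Truth**: TBVs are centered sums of dosage-weighted QTL effects; the true
  breeding value for yield at any time t is defined by *direct evaluation* of
  the logistic at the parameter TBVs around the population means (not a
  first-order approximation), centered — the same nonlinear composition
  method I applies to GEBVs.  Default population means (10, 200, 60) put
  t = 600 at > 99% saturation, so TBV(t600) is nearly collinear with the
  asymptote TBV (r ≥ 0.99).

What the simulator does *not* emulate: multi-generation pedigrees and
selection, non-additive QTL action, missing genotypes or phenotypes,
genotyping error, and any attempt to match the original workshop dataset's
actual QTL positions or allele-frequency spectrum.  Passing tests therefore
show the method behaves correctly under its own assumptions at realistic
scale — not that the original dataset's exact published numbers are
recovered, which without that dataset is not a testable claim.

## Problem sizes and tolerances

End-to-end checks run the default 2000 × 453 design with desk-scale chains;
replicate counts are 3 seeds for accuracy medians and 5 for LD summaries.
Oracle comparisons use: 1e-6 absolute for the collapsed-update-vs-quadrature
check; a few Monte-Carlo standard errors (estimated from the kept draws) for
all sampler-moment checks, including the ridge/BLUP closed-form limit on a
20 × 10 instance with indicators forced on and variances fixed; 1e-12 for
pure-arithmetic oracles; and 1e-5 relative for noise-free curve recovery.
Degenerate inputs have defined behaviour throughout: constant records →
unconverged fit; zero-variance vectors → NaN correlations; monomorphic SNPs →
forced exclusion; all-zero effect vectors → rescaling flagged, not divided.

## Known limitations

* Univariate analyses only: A, B, C are analysed separately (their GEBVs are
  correlated through LD and pleiotropy, not through the model).
* Fitting uncertainty is not propagated into step 2.
* σ²α's posterior mean is unstable under the flat prior when few SNPs are
  active (heavy-tailed conditional); use inclusion probabilities and effects.
* The sampler's per-SNP random streams are positional; only posterior means,
  not sampled paths, are exchangeable under SNP permutation.
* The simulator's LD calibration (ρ = 0.415 → r² ≈ 0.15) holds for the
  default design; changing marker density, founder count or family structure
  changes realised LD and would need recalibration via `founder_ld`.
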