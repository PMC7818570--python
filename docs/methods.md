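# Methods

## Estimand and data model

The package estimates the causal effect β of a continuous exposure on a
binary outcome on the log-odds scale, from two independent GWAS: for each
SNP *i* a summary pair (γ̂ᵢ, σ_γᵢ) for the exposure and (α̂ᵢ, σ_αᵢ) for the
outcome, joined by rsID and aligned to a shared effect allele. The working
assumptions are the three instrumental-variable conditions — relevance
(γᵢ ≠ 0), independence from confounders, and exclusion (the SNP affects the
outcome only through the exposure) — plus non-overlapping samples. Each
estimator relaxes the exclusion restriction differently; that is the point of
running a battery rather than one method.

## Estimators

**Wald ratio.** β̂ᵢ = α̂ᵢ/γ̂ᵢ with first-order SE σ_αᵢ/|γ̂ᵢ|. SNPs with
γ̂ᵢ = 0 are excluded with a warning (their ratio is undefined).

**IVW.** Weighted least squares of α̂ on γ̂ through the origin with weights
σ_αᵢ⁻², equivalently the inverse-variance meta-analysis of the Wald ratios.
The default effects model is multiplicative random effects: the fixed-effect
SE is multiplied by max(1, √(Q/(J−1))), so it can never undercut the
fixed-effect SE; the fixed-effects variant is always reported alongside. With
one instrument IVW degenerates to the Wald ratio.

**MR-Egger.** Weighted regression with a free intercept after orienting every
(γ̂ᵢ, α̂ᵢ) pair so γ̂ᵢ ≥ 0 — the regression is not orientation-invariant, and
the positive-γ convention makes the intercept the *average directional*
direct effect under InSIDE (instrument strength independent of direct
effects). SEs carry the same floored residual scale max(1, √(Q/(J−2))).

**Cochran's Q.** For IVW, Q = Σ wᵢ(α̂ᵢ/γ̂ᵢ − β̂)² with wᵢ = (σ_αᵢ/|γ̂ᵢ|)⁻²,
referred to χ²(J−1); for Egger, the weighted residual sum of squares about
the two-parameter fit, referred to χ²(J−2). The tail probability is the
regularized upper incomplete gamma Q(df/2, q/2) (at df = 2 exactly
exp(−q/2)).

**Profile maximum likelihood.** (γ̂ᵢ, α̂ᵢ) are modelled as independent
normals around (gᵢ, β·gᵢ) with known SEs. The nuisance means profile out in
closed form, leaving −2ℓ(β) = Σ (α̂ᵢ − βγ̂ᵢ)²/(σ_αᵢ² + β²σ_γᵢ²), minimized
by Brent's method; the SE comes from the numerical curvature at the optimum.
Unlike IVW this accounts for exposure-side measurement error; as σ_γ → 0 the
two coincide (tested).

**Weighted median.** Order the Wald ratios; with normalized inverse-variance
weights, interpolate the ratio at standardized cumulative weight ½ (using
cumulative weight minus half of each SNP's own weight). Consistent when >50%
of the weight rests on valid instruments. The penalized variant multiplies
each weight by min(1, 20·pᵢ), pᵢ the χ²(1) upper tail of that SNP's Q
contribution about the unpenalized estimate, then re-normalizes — heavily
outlying SNPs are damped, the rest essentially untouched.

**Mode estimators.** The argmax of a normal-kernel density over the Wald
ratios, bandwidth φ·0.9·min(sd, MAD)·J^(−1/5) with φ = 1 by default
(exposed); the weighted variant weights each kernel by the ratio's inverse
variance. The argmax is located on a 512-point grid and polished by bounded
scalar minimization, so it is grid-resolution-independent. Consistent when
the largest group of instruments sharing one ratio value is valid (ZEMPA).

**RAPS.** Root of the adjusted profile score
Σ (α̂ᵢ − βγ̂ᵢ)·γ̂ᵢ/(σ_αᵢ² + β²σ_γᵢ² + τ²) = 0, found by bracketed Brent
iteration starting from the IVW estimate with geometric bracket expansion.
With the overdispersion flag, a systematic pleiotropy variance τ² ≥ 0 is
estimated jointly by moment-matching the residual spread
(mean[(α̂ᵢ − βγ̂ᵢ)² − σ_αᵢ² − β²σ_γᵢ²], floored at 0) alternated with
re-solving for β to joint convergence. The SE is the sandwich
√(Σψᵢ²)/|Σ∂ψᵢ/∂β|; on exactly collinear inputs where the empirical meat
collapses, a model-based floor keeps it positive.

**Leave-one-out.** J re-estimates each omitting one SNP, plus the all-SNP
estimate for comparison; the default inner estimator is IVW.

Confidence intervals are computed on the log-odds scale as β̂ ± z₀.₉₇₅·se and
exponentiated to the OR scale; p-values are two-sided normal for *all* slope
estimates and for the Egger intercept. (A t reference with J−2 df is the
other common convention for Egger; the normal is used uniformly here for
consistency across the battery and is documented as such.)

## Selection pipeline

Fixed stage order: significance filter (strict p < 5×10⁻⁸) → confounder
blacklist exclusion → greedy LD clumping → proxy substitution →
harmonization → palindromic filter. Clumping repeatedly takes the lowest-p
unclaimed SNP as an index and discards SNPs with r² strictly above 0.001 to
any retained index; equal-p ties break lexicographically by rsID so output is
order-independent; pairs absent from the LD table count as unlinked (sparse
PLINK-style semantics). Proxy substitution replaces an instrument missing
from the outcome study by its highest-r² proxy with r² strictly above 0.8
that is present in both studies; a proxy already serving as an instrument is
not used twice. Whether confounder exclusion precedes or follows clumping is
not dictated by the protocol the package follows; it runs before clumping so
that a blacklisted SNP can never suppress a clean neighbour.

Harmonization joins on rsID only; identical allele pairs pass, swapped pairs
flip the outcome beta and mirror its frequency, strand-complement matches are
complemented first (never attempted for palindromic pairs, where complement
and swap are indistinguishable), everything else is excluded with a reason.
Palindromic instruments are dropped when the exposure-side MAF exceeds 0.3
(at higher MAF the allele frequency can no longer identify the strand);
below-threshold palindromes are retained under a forward-strand assumption
with no frequency-based inference — the smallest-departure reading of the
protocol. MAF is taken from the exposure study because it defines the
instrument set. A palindromic SNP with no frequency at all is dropped as
strand-indeterminate.

Instrument strength: per-SNP F = (β/se)², and when frequencies are available
R² = Σ 2·eaf(1−eaf)β² with aggregate F = ((n−k−1)/k)·R²/(1−R²). Published
per-trait F statistics in this literature do not always follow a
reconstructible formula (some printed values nearly equal other traits'
sample sizes); this package defines both statistics explicitly rather than
imitating any printed value.

## Synthetic-data generator

`simulate_pair` draws, per SNP: maf ~ U(maf_low, maf_high); γ ~
N(gamma_mean, gamma_sd) with an independent random sign unless
`sign_random=False`; direct effect δ ~ N(pleio_mean, pleio_sd), plus 0.5·γ
when the InSIDE-violation flag is set; α = β·γ + δ. Standard errors follow
the per-allele variance approximation 1/√(2·maf(1−maf)·n) — not a claim
about any particular consortium's SE model, but the standard approximation
that yields realistic instrument-strength F values — and observed effects
are normal around the truth. Effects are generated directly on the log-odds
scale (the pipeline only ever consumes summary statistics, so no
individual-level logistic simulation is warranted), and the two samples are
independent. Allele pairs include a configurable count of palindromes, and
the outcome study's coding is randomly swapped and (for non-palindromic
SNPs) randomly strand-complemented, so harmonization does real work in every
simulated run.

Default study conditions: n_exposure = 187,365 and n_outcome = 117,165 (the
sample sizes of the total-cholesterol and CKD GWAS this pipeline targets),
maf ∈ [0.1, 0.4] (common variants, as selected instruments are),
gamma_mean = 0.08, gamma_sd = 0.05 — per-allele effects giving per-SNP
F ≈ 10²–10³, typical of lipid instruments.

Presets:

| preset | J | β | pleio mean/sd | notes |
|---|---|---|---|---|
| null | 50 | 0 | 0 / 0.002 | balanced pleiotropy, for size/coverage |
| causal | 30 | −0.28 | 0 / 0.002 | protective effect, OR ≈ 0.756 |
| directional_pleiotropy | 30 | 0 | 0.01 / 0.005 | γ > 0 (sd 0.02), InSIDE holds |
| heterogeneous | 30 | −0.28 | 0 / 0.01 | E[Q] ≫ df |

The directional preset deliberately uses a null causal effect and a γ
distribution bounded away from zero: the Egger orientation step flips δ for
any negative-γ SNP, and exposure measurement error leaks a slope-dependent
term β(1−λ)E[γ] into the intercept, so a wide-spread γ with a nonzero β
would contaminate the very quantity the preset plants. Isolating the
pleiotropy signal on a null background is the clean design; IVW remains
visibly biased away from β = 0, which is the companion property the preset
must show.

What the generator does *not* emulate: genome-scale LD (LD enters only as a
supplied pairwise table), winner's-curse selection bias from discovery =
analysis samples, population stratification, sample overlap, non-normal
effect distributions, and indels. Passing calibration/recovery tests
therefore validates the estimators and plumbing under the stated model, not
robustness to those real-data pathologies.

## Numerical choices

- Strict inequalities at all protocol thresholds (p < 5×10⁻⁸, r² > 0.001
  excluded, proxy r² > 0.8, MAF > 0.3 removed), matching the protocol's
  wording; boundary cases are pinned by tests.
- Input p-values of exactly 0 are clamped to 1e-300 with a warning; non-ACGT
  alleles (indels) are dropped on read.
- z₀.₉₇₅ = Φ⁻¹(0.975) ≈ 1.959964, not the rounded 1.96.
- Bootstrap SEs (median/mode): parametric resampling of the Wald ratios from
  their normal errors, default n_boot = 1000, seeded (seed mandatory when a
  bootstrap runs; n_boot = 0 skips it and reports NaN uncertainty, used by
  the replicate studies that only consume point estimates). A degenerate
  zero-spread bootstrap reports √ε rather than 0 so downstream z-statistics
  stay finite.
- Penalization constant 20 in the penalized median and φ = 1 mode bandwidth
  are the canonical published defaults; both exposed as arguments.
- ML uses Brent with xtol 1e-12 around the IVW start; RAPS expands its root
  bracket geometrically (up to 60 doublings) before declaring failure.
- Per-estimator bootstrap seeds spawn from one run seed via
  `numpy.random.SeedSequence`, keyed by estimator name in sorted order, so
  adding an estimator does not shift the others' streams.
- Equal-p clumping ties break by rsID; all stage outputs preserve input row
  order.

## Replicate-study problem sizes

The packaged studies (`tsmr.replication`) use 500 replicates — null at
J = 50, causal/directional at J = 30 — which puts Monte-Carlo SEs of the
replicate means around 5×10⁻⁴ to 1×10⁻³ on the slope scale and completes in
seconds; recovery is asserted within 3 Monte-Carlo SEs, calibration within
[0.03, 0.07] for size and [0.93, 0.97] for coverage at the nominal 5% level.

## Known limitations

- No MR-PRESSO outlier correction, Steiger directionality filtering, or
  multivariable MR; no figure rendering (the single-SNP and leave-one-out
  tables carry the data a forest/funnel plot would show).
- LD is consumed, never computed: r² comes from a supplied table (PLINK's
  job), proxies from a supplied table (a proxy-lookup service's job).
- The RAPS implementation solves the plain adjusted profile score; it does
  not implement the robustified (Huber/Tukey) loss variants.
- Aggregate F requires frequencies and a sample size; with either missing it
  is reported as unavailable rather than guessed.
- rsID is the sole join key; records with positions but mismatched rsIDs will
  not be joined.
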