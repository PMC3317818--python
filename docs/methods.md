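# Methods

## Model

Responses are 5-category Likert items under Samejima's graded response
model.  For item *i* with discrimination `a_i > 0` and ordered thresholds
`b_{i1} ≤ … ≤ b_{i4}`, the boundary curves are logistic in the latent trait
θ (anhedonic depression, standardized scale):

    P*(X_i ≥ k | θ) = 1 / (1 + exp(−a_i (θ − b_{ik}))),   k = 1..4,

and category probabilities are consecutive differences with
`P*(X ≥ 0) = 1`, `P*(X ≥ 5) = 0`.  **Parameterization contract:** the link
is an unscaled logistic — no `D = 1.7` normal-ogive constant.  The packaged
MASQ-AD parameters (slopes up to 2.90) are interpreted on this scale, and
all parameters refer to *reverse-keyed* responses: positively worded items
("Felt cheerful") are flipped `c → 4 − c` once at ingestion so that a higher
category always means more depression.  The printed Likert anchor list for
the instrument skips anchor 1 (an apparent typographical slip); the package
treats the scale as five categories coded 0–4 internally and 1–5 in CSV
files.

Item information is the expected (Fisher) information

    I_i(θ) = Σ_k (W_{ik} − W_{i,k+1})² / P_{ik}(θ),
    W_{ik} = a_i P*_ik (1 − P*_ik),  W_{i0} = W_{iK} = 0,

and test information is its sum over the bank (local independence).  Note
that polytomous item information need not be unimodal: for low-slope items
with spread thresholds it ripples, so the only guarantees tested are
non-negativity and monotone decay outside the threshold range.

## Trait estimation

θ is estimated by maximum a posteriori under a standard-normal prior; the
log posterior is concave for the logistic GRM, so the mode is unique.  A
safeguarded Newton iteration (analytic first/second derivatives, steps
clipped to 1, convergence `|Δθ| < 1e−5`) falls back to a bounded scalar
search on [−6, 6].  The reported standard error is

    SE(θ̂) = [ I(θ̂) + 1 ]^{−1/2}

— expected test information at the mode plus the prior precision — rather
than a posterior SD.  This is the standard CAT stopping quantity: it is the
prior SE of exactly 1 at zero items and shrinks as information accrues.
Because the provisional θ̂ moves between administrations, the SE trace of a
CAT is only *nearly* monotone; occasional upticks of order 0.01–0.02 occur
when the estimate moves into a lower-information region.  Unlike maximum
likelihood, MAP is finite for all-lowest and all-highest response patterns.

## Calibration

Item parameters are estimated by marginal maximum likelihood with an EM
algorithm.  The latent density is approximated by 61 equally spaced
quadrature nodes on [−5, 5] with normalized standard-normal weights —
rectangular quadrature is robust for high slopes, where Gauss–Hermite node
placement can straddle steep response curves.  The M-step improves each
item's expected complete-data log-likelihood by L-BFGS over
`(log a, b₁, log gaps)`; the log-gap parameterization keeps thresholds
ordered at every iterate, and partial maximization (20 inner iterations,
with a no-worse-than-current acceptance guard) makes the procedure a
generalized EM whose marginal log-likelihood is non-decreasing.
Convergence: maximum absolute parameter change < 1e−3 *and* relative
log-likelihood change < 1e−7, capped at 500 iterations.  Missing responses
simply drop out of the likelihood (they are rejected in CAT input, which
replays complete records).  Items missing an observed category have
inestimable thresholds and raise an error naming the item and category.

One identifiability caveat: a *single* dichotomous item is not estimable
under this design (one marginal proportion, two parameters); slopes are
identified through inter-item covariation, so calibration is only
meaningful for multi-item banks.

Two-fold cross-validation mirrors the simulation design it supports: the
sample is split at random into halves, the GRM is fit in each, and every
respondent's CAT uses the parameters from the *other* half, preventing the
optimism of calibrating and simulating on the same records.

## Post-hoc CAT

Each complete 22-item record is replayed as if collected adaptively:

1. start at θ̂ = 0 (the prior mean), so the first item is always the
   maximum-information item at 0 (item 5 for the packaged bank);
2. administer the remaining item with maximum information at the current
   θ̂, ties broken by lowest item id (determinism; exact ties are
   measure-zero);
3. reveal the recorded response and re-estimate θ̂ by MAP over the items
   administered so far — after every single item, no burn-in batch;
4. stop when `SE(θ̂) < c` (checked only after an administration, so at
   least one item is always used) or when the pool is exhausted; records
   carry an explicit `stop_reason` so either accounting of the "used all
   items" percentage can be derived.

Item selection never consults the stopping rule, so the path under any SE
threshold is a prefix of the no-rule path.  The sweep implementation
(`build_tables`) exploits this: the full 22-step path is computed once per
respondent and each rule's record is derived by truncation at the first SE
crossing, which is exactly equivalent to running the loop per rule (a
tested invariant) and about six times faster for the standard sweep.

## Evaluation

Per stopping rule: mean and SD of items administered, percentage using the
whole pool, mean final SE, marginal reliability, and the Pearson
correlation between CAT and full-test estimates (always on final MAP
values, never trace intermediates).  Marginal reliability is fixed as
`1 − mean(SE²)` under the unit-variance trait — a deliberately crude
single-number summary (it pairs a mean SE of 0.23 with reliability ≈ 0.95)
used descriptively, not inferentially.  Criterion validity uses Pearson r
with Fisher-z 95% intervals for continuous criteria and the Mann–Whitney
AUC (ties at ½) with the Hanley–McNeil variance for a binary diagnosis;
Hanley–McNeil was chosen over DeLong for closed-form simplicity at these
sample sizes.  A sum-score reference row accompanies the θ̂ rows.

## Screening battery

The battery encodes the PROMIS-style vetting thresholds: first
principal component of the polychoric matrix ≥ 20% of variance and a
first/second eigenvalue ratio ≥ 4 (unidimensionality); one-factor residual
correlations > 0.2 and Yen's Q3 banded at 0.24/0.37 (local dependence;
under a true model Q3 has a mild negative bias of about −1/(m−1), which is
left uncorrected); Mokken item H ≥ 0.3 with scale bands 0.3/0.4/0.5 and
rest-score monotonicity (monotonicity); and proportional-odds DIF with
McFadden ΔR² ≥ 0.02 per covariate (invariance).  Implementation choices:

* polychorics use the two-step estimator (thresholds from marginal normal
  quantiles, correlation by bivariate-normal ML on the contingency table);
  non-PSD pairwise matrices are smoothed by eigenvalue clipping with a
  warning;
* the one-factor extraction is least-squares (minres) rather than ML SEM —
  only the residual matrix feeds a decision rule here, and Heywood loadings
  are clipped to |λ| ≤ 1 with a warning;
* Mokken `covmax` is computed by the comonotone coupling of the two
  marginals, which attains the rearrangement-inequality maximum (verified
  against a linear-program oracle in tests);
* DIF is single-pass with the all-item θ̂ as matching criterion (no
  purification iterations); the null log-likelihood of the thresholds-only
  ordinal model is closed-form from marginal frequencies.  Continuous
  covariates enter linearly (centered); categorical covariates are
  dummy-coded with a trait×group interaction.  Detection power scales with
  the item's discrimination: a threshold shift of 0.5 on a high-slope item
  (a ≈ 2.9) yields ΔR² ≈ 0.03 at n ≈ 3,600, while the same shift on a
  mid-slope item lands near the 0.02 cutoff.

On data simulated exactly under the packaged bank at the study size the
battery raises no flags, and each planted defect (a shared nuisance factor
of strength ≥ 1.5 SD for one pair, a 0.5 threshold shift on a high-slope
item, a reversed-keyed item) is caught by its dedicated diagnostic.

## Synthetic cohorts

The generator emulates the study population: n = 3,597 outpatients, 46%
with a depression diagnosis.  Latent traits are mixture normals; responses
are sampled category-wise from the GRM at the true θ; each continuous
criterion is `ρ·z(θ) + √(1−ρ²)·ε` with z the standardized true trait, so
its *population* correlation with θ equals the target (anxious arousal
0.46, general distress 0.74 by default).  Criteria are tied to the true
trait deliberately: the observed validity of any θ̂ is then attenuated by
measurement error exactly as a real shortened assessment would be, making
attenuation itself testable.  The two diagnostic groups share a common SD
and are separated so that the marginal trait variance is 1 *and* the
normal-theory true-trait AUC is 0.81:

    σ² = 1 / (1 + 2w(1−w)z²),  δ = σ√2·z,  z = Φ⁻¹(0.81), w = 0.46,

giving δ ≈ 1.056, σ ≈ 0.850.  The 0.81 anchor references the full-test AUC
of the original sample as a design target, not a reproduction claim.  What
the generator does **not** emulate: item-level structure of the criterion
scales (they are θ-linked Gaussians, not item composites), non-normal trait
distributions, response styles, or missingness.  Tests passing on this
cohort therefore validate the algorithms, not the behavior of any real
patient population.

## Problem sizes and numerics

Simulation-based checks run at the study size (n = 3,597) with fixed seeds;
parameter-recovery checks average 10 seeds; distributional convergence
checks use n = 20,000.  Dense-grid oracles for the MAP mode use 0.001
spacing on [−6, 6] so bracketing error stays below the 1e−3 agreement
tolerance.  Information-curve functionals use a 0.01 grid on [−4, 4] (peak
location) and trapezoidal integration on [−8, 8] (information shares).
Degenerate inputs are handled explicitly: empty item sets return the prior
estimate, single-respondent summaries report an undefined correlation with
a warning, zero-variance residuals mark Q3 pairs missing, and non-converged
DIF fits are reported indeterminate rather than flagged.

## Known limitations

* MAP is the only estimator (no EAP/WLE); the SE is information-based, not
  a posterior SD — with the unit-normal prior the numerical difference is
  small but systematic near the extremes.
* The calibrator reports no item-parameter standard errors and does no
  linking across banks.
* The CAT has no exposure control, content balancing, or randomesque
  selection; it is a simulation engine, not a live delivery system.
* Marginal reliability is descriptive only; it understates precision
  heterogeneity when information is peaked.
* Real-data criterion values from the original sample (e.g. its printed
  validity correlations) depend on unavailable patient records; the
  synthetic generator targets configurable population values instead, so
  only the qualitative attenuation pattern is reproducible.
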