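# Methods

## Setting and notation

Each subject carries a continuous diagnostic test value T, a three-class
ordinal disease status D (coded 1 = least severe, 2, 3), a binary
verification indicator V (1 when the gold-standard status was obtained),
and optional numeric auxiliary covariates A. The disease status is observed
only when V = 1. All inference assumes:

* **Monotone ordering** — test values stochastically increase with disease
  severity. `check_monotone_ordering` operationalizes this as a strict
  increase of the class-conditional sample means of T among verified
  subjects. This is a deliberate, simple stand-in for the stochastic
  ordering assumption: it is cheap, transparent, and catches the common
  failure mode (mislabelled class order), but it is not a formal test. A
  failed check is reported, never raised, so that analyses can proceed
  deliberately after relabelling or with an explicit override.
* **Missing at random (MAR)** — Pr(V = 1 | T, A, D) = Pr(V = 1 | T, A): the
  decision to verify depends only on observed quantities. Under MAR the
  disease model fitted to verified subjects is valid for everyone.

## Corrected disease values

Every estimator reduces to a single object: the n×3 matrix D̂ of corrected
disease values (see README for the six formulas). Design points:

* **SPE rows are not clipped to [0, 1].** The doubly-robust construction is
  unbiased exactly because the correction terms can be negative; clipping
  would reintroduce bias. Downstream consumers (VUS, TCF) tolerate
  out-of-range values, and the VUS/TCF ratios are reported with a warning
  when the point estimate itself leaves (0, 1) (the logit-scale interval is
  then unavailable).
* **IPW rows for unverified subjects are exact zeros**, not missing, and
  the VUS and TCF estimators normalize by the D̂ column sums. The IPW
  estimator is therefore the self-normalized (Hájek) ratio form, which is
  invariant to rescaling of the weights and considerably more stable than
  the fixed-n (Horvitz–Thompson) form when weights are heavy-tailed.
* **Verification probabilities are floored** at 1e-6 (configurable,
  `ModelSpec.pi_floor`) before entering any denominator, and flooring
  events are logged. The floor guards against division by numerically zero
  probabilities; it is intentionally far below any scientifically
  meaningful probability so that it never changes a well-behaved analysis.
  Under near-deterministic verification mechanisms a verified subject can
  legitimately carry a fitted π̂ of order 1e-4 and dominate a column of the
  SPE matrix, occasionally (about 1% of replicates at n = 1000 in the
  bundled simulation design) driving a column sum nonpositive; such
  degenerate estimates raise an error rather than being silently patched.
  Raising the floor (weight truncation at 0.01–0.025) removes the failures
  but attenuates IPW and shrinks the estimated variances faster than the
  true sampling variability, so it is left to the user's judgement.

## The VUS statistic

The point estimate is the tie-weighted trivariate Mann–Whitney form with
kernel weights 1 (strict ordering), 1/2 (one adjacent tie), 1/6 (triple
tie). The triple-tie weight makes a degenerate test with all values equal
score exactly 1/6, the useless-test value, and the estimator depends on the
test values only through ranks, hence is invariant under strictly
increasing transformations.

The normative definition is the full O(n³) sum over ordered index triples
(including coincident indices, whose contributions vanish for indicator
rows but not for imputed ones). The implementation groups subjects by
unique test value and reduces the sum to four cumulative-sum terms —
algebraically identical, O(n log n) — and is verified against an
independent brute-force triple sum on randomized instances in the tests.

## Variance estimation and inference

Two variance paths are provided:

* **Leave-one-out jackknife** (`asymptotic_variance`): drop one subject,
  recompute the ratio-form VUS with the fitted nuisance *predictions* held
  fixed, and combine as ((n−1)/n)·Σ(v₍₋ᵢ₎ − v̄)². This is the fast path —
  removal updates the grouped sums in O(m) — and is consistent for the
  U-statistic sampling variability. Holding the nuisance fits fixed is
  adequate for the SPE estimator, whose efficient influence function is
  insensitive to first-order nuisance estimation error, and exact for the
  full-data estimator (jackknife CIs achieve ~96% empirical coverage at
  nominal 95% on fully verified data in the test suite). It *understates*
  the variance of FI and MSI, whose variability is dominated by the fitted
  multinomial-logit coefficients; for those estimators use the bootstrap.
* **Nonparametric bootstrap** (`bootstrap_variance`): resample subjects
  with replacement, refit both nuisance models inside each replicate,
  recompute the VUS. Replicate r uses seed `seed + 1 + r`, so results are
  identical for any worker count; a replicate that loses a disease class
  among verified subjects (or fails to refit) is redrawn, up to 100
  attempts per replicate.

Confidence intervals are normal-theory on the natural scale and, when the
estimate lies in (0, 1), on the logit scale via the delta method
(se(logit p) = se/(p(1−p))), with endpoints mapped back through the inverse
logit — guaranteeing bounds strictly inside (0, 1). The useless-marker test
uses t = (V̂US − 1/6)/se against the upper standard-normal tail. Displayed
p-values below 1e-4 print as "< 0.0001"; JSON output keeps full precision.

## ROC surface and confidence regions

At a cut pair c1 ≤ c2 the true class fractions are estimated by normalized
sums of D̂ with the half-open, right-closed convention: TCF1 uses T ≤ c1,
TCF2 uses c1 < T ≤ c2, TCF3 uses T > c2. Any consistent convention
partitions the line for full data; this one matches the "higher test ⇒ more
severe" orientation. Default surface grids are the unique observed test
values with below-minimum/above-maximum sentinels, so the surface attains
the unit-cube vertices (1,0,0), (0,1,0), (0,0,1) exactly. `surface_volume`
integrates the surface height TCF2 against the per-cut increments of TCF1
and decrements of TCF3; on fully verified data with distinct values it
reproduces the U-statistic VUS to floating-point accuracy, and it serves as
an independent cross-check between the surface and VUS code paths.

The ellipsoidal confidence region for (TCF1, TCF2, TCF3) at a fixed cut
pair centers at the plug-in estimate, uses the bootstrap covariance of the
TCF vector over B replicates, and takes the squared radius from the
chi-square quantile with 3 degrees of freedom — the three fractions at a
fixed cut pair are not linearly constrained once bias correction is
applied. A numerically singular covariance is flagged and handled through
the pseudo-inverse.

## Nuisance models

* `fit_verification_model`: binomial GLM (statsmodels) with logit, probit,
  or "threshold" link. The threshold option is implemented as the
  complementary log-log link; the term "threshold regression" is ambiguous
  in this context, and this reading keeps a third qualitatively distinct
  link without inventing new semantics. A pre-check refuses perfectly
  separating predictors by name.
* `fit_disease_mlogit`: multinomial logistic regression (statsmodels
  MNLogit, Newton, max 100 iterations), class 1 as baseline, fitted on
  verified subjects, predicted for all. Under the bundled generating model
  the true class posterior is exactly linear-logistic in (T, A) (equal
  class covariances), so this model is correctly specified there.
* `fit_disease_knn`: Euclidean K-nearest-neighbour average of verified
  indicator rows in predictor space standardized by the verified-subject
  mean and standard deviation (exactly scale-invariant). Ties at the K-th
  distance break toward the lowest subject index (stable sort), making the
  fit fully deterministic. `select_k` cross-validates K on verified
  subjects (seeded folds, mean squared error on indicator rows, ties to
  the smaller K) over the default odd grid 1, 3, …, ⌈√n_verified⌉.

## Synthetic data and truth oracles

`simulate` draws disease class k with probabilities θ = (0.40, 0.35, 0.25),
then (T, A) | k from a bivariate normal with mean k·(2, 1)ᵀ and covariance
[[1.75, 0.1], [0.1, 2.5]], then V from a logistic model with linear
predictor 1 − 2.2·T + 4·A. Unverified labels are hidden; the complete
labels ride along on a side channel used only by oracles. Missingness is
exactly the verification draw — MAR by construction, with no extra noise.

Features of real data this generator does **not** emulate: measurement
error or detection limits in the marker, non-normal class-conditional
distributions, covariate-dependent class covariances, and — most
importantly — verifier behaviour with bounded randomness. The generating
verification model is nearly deterministic: the linear predictor has
standard deviation ≈ 6.8 across the mixture, so fitted probabilities pile
up near 0 and 1 and positivity (π bounded away from 0) effectively fails.
Consequences, measured in the test suite at n = 1000:

* FI, MSI and SPE recover the true VUS (0.7173 by the million-draw
  Monte-Carlo oracle, which matches closed-form quadrature);
* IPW carries a persistent finite-sample median bias of about +0.02 that
  does not shrink visibly through n = 8000 (heavy-tailed weights);
* the KNN estimator is attenuated by roughly −0.045: unverified subjects
  occupy a region nearly empty of verified subjects, so nearest-neighbour
  imputation extrapolates (mean absolute ρ̂ error ~0.18 on unverified vs
  ~0.14 on verified rows at K = 3);
* jackknife-based 95% intervals for SPE cover the truth in ~90% of 500
  replicates rather than 95% — the estimator's sampling distribution is
  heavy-tailed under near-positivity-violation, and normal-theory
  intervals undercover.

Passing tests under this design therefore demonstrate correctness of the
implementations and the expected relative behaviour of the estimators, not
that every estimator is reliable under arbitrarily extreme verification
mechanisms; with moderate verification probabilities all five corrected
estimators behave markedly better.

`true_vus` Monte-Carlo-averages the tie kernel over independent
class-conditional draws (reported with its standard error); `true_tcf`
evaluates the class-conditional normal CDFs exactly.

## Problem sizes used in the test suite

Simulation-backed tests use n = 1000 with 100 replicates for estimator
recovery, 500 replicates for CI coverage, n = 20000 single datasets for
coefficient recovery, and n ≤ 60 instances for brute-force oracle
equivalence — sizes at which the Monte-Carlo error bands quoted in the
tests are meaningful while the full suite stays fast.

## Known limitations

* The fixed-prediction jackknife is not a valid variance for FI/MSI (use
  the bootstrap there); a closed-form influence-function variance is not
  implemented.
* "Threshold" link semantics are an interpretation (cloglog), documented
  above.
* No MNAR verification mechanisms, no more than three disease classes, no
  smoothed or parametric ROC surfaces, no partial-VUS variants.
* Degenerate SPE estimates (nonpositive corrected class mass) raise rather
  than self-repair; see the flooring discussion above.
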