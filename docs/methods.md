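# Methods

`ipssirt` implements a pharmacometric item-response-theory (IRT) analysis
chain for the International Prostate Symptom Score (IPSS), the 7-item
0–5-scored questionnaire used to grade lower urinary tract symptoms in
benign prostatic hyperplasia (BPH-LUTS). This note records the models, the
numerical choices, and what the synthetic-data experiments do and do not
demonstrate.

## Graded response model

The probability that patient *i* answers item *j* with a score of at least
*k* is a cumulative logistic in the latent disability ψ:

    P(Y_ij ≥ k) = expit( a_j (ψ_i − τ_jk) ),  k = 1..5,

with item discrimination `a_j > 0` and strictly increasing thresholds
`τ_j1 < … < τ_j5`. Category probabilities are differences of adjacent
cumulative curves; no 1.7 scaling constant is used; higher ψ means more
severe symptoms. Item Fisher information is
`Σ_k (∂P_k/∂ψ)² / P_k` over the six categories.

**Threshold parameterisation.** Reported difficulty vectors are read as a
first threshold plus four strictly positive increments; absolute thresholds
are cumulative sums. Read as absolute locations the reference difficulty
values would be non-monotone (e.g. item 1: 1.82 > 1.68 > 1.41) and would
produce negative category probabilities, so the increment reading is the
only admissible one. All reporting shows both increments and absolute
thresholds.

## ICC estimation (IDVIS)

Item characteristic curves are estimated by marginal maximum likelihood
with every (patient, visit) record treated as an independent
pseudo-individual ("IDVIS"). The baseline latent distribution is fixed to
N(0, 1) per dimension — it anchors the scale and is not a free parameter —
while all post-baseline pseudo-individuals share an estimated mean/variance
shift per dimension. One shift pair is shared by all post-baseline visits.
The unidimensional model has 44 free parameters (35 difficulties, 7
discriminations, 2 shift parameters); the bidimensional model, with the
voiding items {1, 3, 5, 6} and storage items {2, 4, 7} on separate
correlated coordinates, has 47 (two shift pairs plus one inter-dimension
correlation, shared by the baseline and post-baseline distributions).

Integration uses Gauss–Hermite quadrature re-centred on the origin-specific
prior: 21 nodes (unidimensional), a 15×15 tensor grid with the correlation
applied through a Cholesky factor (bidimensional). A per-individual
adaptive variant (nodes at the posterior mode scaled by the posterior
curvature) exists for verification; on a 50-record fixture it agrees with
101-node quadrature to well under 0.01 OFV units (OFV = −2 log marginal
likelihood). Parameters are optimised on transformed scales — log
discriminations, log increments, free first thresholds, log shift variance,
atanh correlation — by L-BFGS-B with finite-difference gradients;
convergence at relative OFV change below 1e−9. Optional seeded multi-start
(`n_starts`) perturbs the data-derived starting values; the default single
start converged reliably in all recovery experiments. Standard errors come
from the numerically differentiated observed information, mapped to the
reporting scale by the delta method. Missing item scores drop out of the
likelihood (missing at random).

**Disability estimates.** Per-pseudo-individual MAP estimates maximise the
response log-likelihood plus the origin-specific log prior (batched damped
Newton; grid-search fallback on [−10, 10]); the standard error is the
inverse square root of the negative posterior curvature (per dimension from
the full 2×2 Hessian in the bidimensional case). SD-based η-shrinkage is
`1 − SD(η̂/ω)` pooled over origins; per-individual shrinkage uses the
conditional-variance decomposition `1 − √(1 − se²/ω²)`.

## Fisher-information ranking

Information curves are evaluated item-wise on a 2,001-point grid and ranked
by trapezoidal area over a disability range, expressed as a share of the
total. The default range is the empirical span of the MAP disability
estimates, because "the estimated disability range" has no canonical
numeric value; a sensitivity sweep over (−4, 4), (−6, 3) and the empirical
range is part of the report. The ranking (incomplete emptying first,
nocturia last) and the combined voiding share (~72%) are stable across
these ranges; the individual percentages move by fractions of a point.
Information ranking is restricted to unidimensional banks: across-dimension
information is not comparable in a multidimensional model.

## Longitudinal models

Structural model on both the total-score and latent scales:

    IPSS or Disability = Baseline + Placebo + Drug
    Placebo = Pmax (1 − exp(−((ln2 / Tprog) · t)^WEI)) + Drift · t

with `WEI = 1` (exponential) except in the bidimensional latent model
(`WEI = 1.53`, shared across dimensions), typical Drift fixed to 0, and
Drug an offset effect on active arms from the first post-dose visit — the
drug effect carries no inter-individual variability (IIV) by default
because placebo and drug variability are not separable in this design.
IIV is additive-normal, log-normal, or Box-Cox-transformed normal
(`η* = ((e^η)^λ − 1)/λ`, continuous in λ with the identity as the λ→0
limit) per parameter. Percent magnitudes are 100·√variance of the
untransformed η.

**Time units.** The package works in months. The reference placebo
half-lives (12.3–15.3) are day-scale quantities and are converted by
30.44 d/month, giving half-lives near two weeks. This calibration follows
from internal consistency: with month-scale half-lives the placebo response
would barely develop within the 6-month trial, contradicting the marked
early placebo drop such trials show, and truth-recovery simulations would
put the drug-effect likelihood-ratio ΔOFV near 170 at n = 403 instead of
the ~22 the reference estimates imply; with the day-scale reading the
simulated ΔOFV lands at that reference scale.

**Estimation.** All three model classes share a per-subject Laplace
marginalisation: the inner mode over each subject's random effects is found
by a batched Gauss–Newton/Newton loop with analytic η-gradients (structural
derivatives in closed form; item-likelihood curvature approximated by the
expected Fisher information, which keeps the inner Hessian positive
definite), and the outer parameters are optimised by L-BFGS-B with
finite-difference gradients on transformed scales. Because the objective
contains an iterative inner loop, the finite-difference step is a relative
1e−4 — far above the inner noise — and the optimiser is restarted from its
own solution (up to three times) to reset the curvature memory; this
resolved ridge stalls between the drug, Pmax and Tprog directions.
Full/reduced likelihood-ratio pairs chain: the reduced model starts at the
full solution, and the full fit is re-polished from the reduced solution
whenever the reduced OFV undercuts it.

* `TotalScoreModel`: total IPSS with combined proportional + additive
  residual error; baseline/placebo/Tprog starting values are derived from
  the placebo-arm visit means (the progression rate by bisection on the
  observed early/late response fractions).
* `LatentDisabilityModel` (PSI-IPPSE): MAP disabilities as the dependent
  variable, each estimate's SE entering the residual variance as a known
  per-observation component, `Var = se² + σ²_add`; additive covariate
  forms on Baseline because the typical latent baseline is near zero.
* `JointIRTModel`: item-level likelihood with ψ following the longitudinal
  model; ICCs fixed (default, mirroring the sequential workflow) or
  appended to the free parameters (`re_estimate_icc=True`). The
  bidimensional variant shares the Pmax, Tprog and Drift random effects
  across dimensions with correlated baselines and per-dimension drug
  effects (drug LRT df = 2).

Estimation omits the IIV correlations and Box-Cox shapes by default (both
can be enabled); the simulator applies them whenever the truth specifies
them. Covariate relations are linear, multiplicative
(`θ(1 + θ_cov(c − median))`) or additive, centred at the sample median.
Stepwise covariate search: greedy forward inclusion at ΔOFV > 6.635
(χ², p = 0.01, df = 1), backward elimination retains at ΔOFV > 10.828
(p = 0.001).

**Residual-model assignment.** The proportional residual component belongs
to the total-score model and the additive component to the latent model: a
proportional error on a latent variable centred near zero is ill-defined.
The reference additive residual SD on the score scale is taken as 1.892
IPSS points (the percent-printed value read in score units).

## Synthetic-trial generator

The generator emulates a four-arm (placebo/10/20/30 mg single dose),
6-month design: 403 patients, 1:1:1:1 allocation (the realised reference
counts 98/101/99/105 are available as a preset), visits at 0, 0.5, 1, 2, 3,
4, 5, 6 months, screening total IPSS ≥ 13. Screening is a separate
pre-baseline item-response vector at the patient's baseline latent value
plus an independent N(0, 0.3²) perturbation; rejection sampling enforces
the threshold at screening only, so baseline totals below 13 remain
possible, as observed in practice. Dropout and item-missingness default to
0 (the power-simulation assumption) and are configurable. Baseline
covariates — quality-of-life score 1–6 (median 4), BPH Impact Index 0–12
(median 7), region (~60% North America) — are sampled from discrete
distributions chosen to match the reference medians; their exact shapes are
synthetic choices. Random streams are split per patient
(seeded by (seed, patient index)), so enlarging a trial never reshuffles
earlier patients. Item scores are drawn by inverting the cumulative
category curves with a single uniform draw.

What the generator does **not** emulate: visit-to-visit within-patient
latent fluctuation (inter-occasion variability), informative dropout,
dose–response or exposure–response structure, item-level local dependence,
and site/region heterogeneity beyond the baseline covariate effect.
Passing recovery tests therefore demonstrate internal consistency of
estimator and simulator under the stated model, not robustness to those
real-data features; the simulated drug-effect information can differ from a
real trial's wherever those features matter.

## Diagnostics

**η-sampling GAM ICC check.** For each pseudo-individual, `n_samples`
(default 200) disability values are drawn from N(MAP, SE²), respecting the
baseline/post-baseline origin through the fitted shift parameters. Each
binary exceedance indicator (score ≥ k; 35 item–category panels) is
smoothed against the sampled disability with a cross-validated cubic
P-spline: basis dimension 10, knots at data quantiles, second-difference
penalty, binomial likelihood fitted by penalised IRLS after aggregating the
draws into ~400 fine x-bins (cost independent of `n_samples`; the binned
likelihood is essentially exact), penalty weight by generalised
cross-validation on the deviance. The logistic-scale band is
`±1.96 · SE · √n_samples` — the √n_samples factor widens the band to what
the real number of pseudo-individuals supports (equivalently the SE is
multiplied before the 1.96 expansion; the two orders are identical). A
binomial-likelihood smoother is essential here: a homoscedastic Gaussian
spline understates the band near probabilities 0 and 1 and falsely flags
extreme-category panels on data simulated from the true model. A panel is
flagged when the model ICC leaves the band on more than 10% of a 100-point
grid over the central 99% of sampled disability. With `n_samples = 1` and
zero SEs the check degenerates to the traditional EBE-based smooth.

**Residual item correlations.** `RES = DV − E`, with E the
probability-weighted expected item score at the MAP disability; Pearson
correlations across pseudo-individuals. Because the same responses
estimate the disability, an adequate model still shows a mild negative
off-diagonal background (about −0.05 to −0.2 at the full design);
violations of local independence appear as entries that are positive
against that background. Residuals computed at the true simulated ψ are
uncorrelated (|r| < 0.1), which the tests use as the null oracle.

**VPC.** Replicate trials simulated at the observed design; observed
5th/50th/95th percentiles per nominal visit (balanced design, no adaptive
binning) against 95% simulation intervals; defaults 200 replicates for
summary-score checks and 2000 for item-level checks.

## Power engine

Stochastic simulation and estimation: trials simulated from the
bidimensional latent model (the lowest-AIC reference model), analysed by
bidimensional IRT, unidimensional IRT and total-score likelihood-ratio
pairs (empirically calibrated ΔOFV thresholds: the 95th percentile of the
null-simulation ΔOFV per sample size, so the realised type I error is 5%
by construction) and by two ANCOVAs (p < 0.05): change from baseline at
the 3-month landmark, and the "while-on-treatment" average post-baseline
change, both with treatment as factor (pooled active vs placebo by
default, matching the dose-independent simulated effect; a 4-level factor
F-test is available) and baseline total as covariate. Only converged
full/reduced pairs count. Per-replicate seeds derive deterministically
from (master seed, sample-size index, replicate), so results are identical
under any parallelisation. The 80%-power sample size interpolates the
isotonic-pooled power curve linearly.

Default replicate counts are 1000 (calibration and power); the packaged
tests run the engine at 10–250 replicates and sample sizes of 40–106 so
the whole suite stays within single-CPU minutes — at those counts the
test asserts paired method dominance (longitudinal models detect the
effect on more shared replicates than the ANCOVAs) rather than resolving
the few-percent gaps between the three model-based methods, and the
80%-power sample sizes themselves are left to full-scale runs of
`sse_power`.

## Known limitations

* The Laplace approximation (with Gauss–Newton curvature) can bias
  variance components at very small n; the quadrature-based ICC stage does
  not share this limitation.
* The bidimensional joint model inherits the stability issues expected of
  multi-latent pharmacometric IRT models; standard errors for it are off
  by default and covariates are untested there.
* `structural_prediction` treats any arm label other than "placebo" as
  active; it does not validate arm names against a trial design.
* The GAM check's posterior-normality assumption is shared with the
  method it implements; with exact-posterior sampling the calibration is
  unchanged in our experiments.
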