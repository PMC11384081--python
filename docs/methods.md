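# Methods

This note records the modelling assumptions, numerical choices and known
limitations of `tiapbms`, in the spirit of the methods documentation of
packages like statsmodels or msprime.

## Kinetic model family

Organ activity, expressed as a dimensionless fraction of injected activity,
is modelled as a sum of exponentials; every term decays with the total rate
μ = λ_bio + λ_phys so that physical decay (default ¹⁷⁷Lu, half-life
6.6443 d) is never absorbed into the biological constants. Internally all
times are minutes; λ_phys = ln 2 / (6.6443 · 1440) ≈ 7.245·10⁻⁵ min⁻¹. The
registry holds eleven parameterisations (f2a … f6b); the digit in a name is
the number of adjustable shape parameters. Constraints: pre-factors
A_j ≥ 0, biological rates λ_j ≥ 0, fractions α ∈ [0, 1]. The α constraint
is not forced by the curve algebra, but an unconstrained α would make the
f3b/f4b "fraction" reading meaningless and published shared-parameter
values (α = 0.9632) sit inside [0, 1]; we constrain it deliberately.

Two structural notes:

* f5a/f5b subtract their third term as written; the non-negativity
  constraints apply to A₁, A₂, A₃ themselves, not to the signed term, and
  f5b is pinned to zero at t = 0 by construction (A₁+A₂−(A₂+A₁)).
* f3b(α) ≡ f3c(1−α) pointwise. Under this package's logit-scale random
  effects (below) the two are *exactly* equivalent as statistical models,
  so a candidate set should contain only one of them.

Each function is stored termwise, f(t) = Σ c_m(p)·e^(−μ_m(p)t), where the
coefficient maps are at most bilinear and the rate maps affine in the
parameters. This gives a closed-form TIA over [0, T],
Σ c_m(1−e^(−μ_m T))/μ_m (a μ = 0 term contributes c_m·T; T = ∞ uses
c_m/μ_m), and cheap analytic derivatives for the fitting engines. The
default horizon is T = 100 000 min; TIAs are reported in minutes per unit
injected activity.

## Population model and estimation

For patient i, observation j:

* ln y_ij = ln f(t_ij; P_i) + ε_ij, ε_ij ~ N(0, σ_res²) — the
  multiplicative ("exponential") residual model. It requires strictly
  positive activities; non-positive rows are rejected at load with row
  numbers.
* P_ik = TVP_k · exp(η_ik), η_ik ~ N(0, ω_k²), diagonal covariance.
  Fraction parameters instead receive η additively on the logit scale,
  because a log-normal deviation cannot respect α ≤ 1; for A/λ parameters
  the log-normal form is kept exactly.

The marginal likelihood integrates out η per patient. We use the Laplace
approximation at the per-patient empirical-Bayes mode: an inner damped
Newton search (analytic gradients and exact analytic Hessians, vectorised
across patients, gradient tolerance 10⁻⁸, cold-started at η = 0 and
warm-started along the outer search) nested in an outer minimisation over
(log TVP, logit α-type TVPs, log ω², log σ_res). A non-converged inner
search maps to +∞ rather than an unreliable determinant.

**Determinant choice.** The Laplace log-determinant uses the Gauss–Newton
(Fisher-type) curvature G′G/σ² + Ω⁻¹ instead of the exact Hessian. The two
coincide whenever the model is log-linear in η (which is why the quadrature
cross-check below is exact), but the exact-Hessian variant is unusable
here: patients observed at as many time points as they have random effects
admit interpolating modes where the exact Hessian acquires a zero
eigenvalue, and the optimiser can drive −2lnP to arbitrarily low values
through the collapsing determinant. The Gauss–Newton curvature is bounded
below by Ω⁻¹ and immune to this, at the cost of a (standard,
FOCE-flavoured) approximation for strongly nonlinear random effects.

**Outer optimisation.** L-BFGS-B with finite-difference gradients
(step 10⁻⁶) followed by a Powell polish (ftol 10⁻⁸): the profile surface
has a narrow ravine between ω², σ_res and the fixed effects in which
finite-difference gradients stall before the bottom. Starting values are
data-driven — a pooled log-scale curve fit seeded by crude amplitude/slope
heuristics — plus seeded log-normal jitter (SD 0.5) for additional starts.
The default multi-start budget is 3: with a deterministic pooled-fit
initialisation, large blind multi-start brings little, and the budget is
configurable (`n_starts`). The recovery experiments use `n_starts=1` for
throughput; spot checks against larger budgets on the same seeds gave
identical optima.

**Standard errors and the goodness gate.** The covariance of the outer
estimates is 2H⁻¹ with H the central finite-difference Hessian of the
−2lnP objective at the optimum (in-package implementation; steps 10⁻³ on
the transformed scales). The per-fixed-effect coefficient of variation is
CV = √(exp(se²)−1) with se the log-scale (or logit-scale, for α) standard
error — i.e. the CV of a log-normal variate with that log-SD. A fit passes
the gate if it converged and max CV < 0.5; a singular or indefinite
Hessian yields CV = ∞ and a failed gate. The "variance of the fixed
effect" entering this CV is read as the squared *standard error* of the
estimate (a fit-quality measure), not the population variance ω²; this is
the reading under which the gate behaves as a goodness-of-fit check, and
it is a genuine interpretation choice.

K counts every estimated quantity: shape fixed effects + random-effect
variances + 1 residual parameter (f3a: 3+3+1 = 7). Candidates whose K
makes the AICc denominator N−K−1 non-positive are excluded before fitting,
with a recorded reason.

## Selection, averaging, jackknife

AICc = −2lnP + 2K + 2K(K+1)/(N−K−1) over the total observation count N.
Akaike weights are computed with the log-sum-exp trick over the
*gate-passing* set only (weights of failing candidates are exactly 0, with
the failure reason kept); renormalising over gate-passers is the natural
reading of restricting the candidate set to adequate models. Ties for the
best function break by smaller K, then name. The model-averaged TIA is the
weight-sum of per-function, per-patient empirical-Bayes TIAs. Visual
inspection of fits is replaced by machine checks (convergence flag, CV
gate, residual finiteness); diagnostic plots are not part of the decision
path. The jackknife refits the full pipeline once per left-out patient and
summarises each candidate's weight distribution and first-place counts;
failed replicates are reported and excluded with a warning.

BIC (−2lnP + K ln N) is provided as a convenience comparator only.

## Baselines

IBMS fits each patient separately by weighted least squares with the
constant-CV variance model SD_ij = 0.15·y_ij ("absolute variance model
with fractional SD 0.15" in SAAM-II terms; we read *fractional* as
proportional to the observation — the reading under which the weights are
scale-free). Patients with N ≤ K are skipped with a recorded reason
(df = N−K ≥ 1). The optimiser is `scipy.optimize.least_squares` (TRF with
box constraints) rather than the historical Rosenbrock search; the
algorithm is incidental as long as the 10⁻⁴ objective convergence is met,
and TRF converges far past it. The shipped IBMS default function is the
mono-exponential f2a — the established per-patient selection for 3-point
schedules — with per-function overrides available.

SP-PBMS shares one parameter (default α of f3b) across patients: a bounded
1-D search over the shared value on its unconstrained scale, with
independent per-patient WLS fits inside. In evaluation mode the shared
value is fixed (α = 0.9632 for the published curve) and only the two
patient-specific parameters are fitted; the reported K is
13·2+1 = 27 in both modes because the shared value is data-estimated
upstream even when supplied.

On the individual-fit parameter limit: the literature states both
"K_max = N+1" and "K_max = N−2" in different places; these conflict, and
this package enforces df = N−K ≥ 1, i.e. K ≤ N−1, the weakest condition
under which a residual objective remains meaningful.

## Uncertainty propagation (IBMS / SP-PBMS)

TIA standard deviations come from deterministic frequency-based sampling:
X(s) = ½ + arcsin(sin(ωs+φ))/π on an even midpoint grid of n_evals points
over s ∈ (−π/2, π/2), defaults ω = 1028 and n_evals = 8193, with seeded
per-parameter phases. The same ω is used for every parameter, as
specified for this use (uncertainty propagation, not FAST sensitivity
indices, which would require distinct frequencies). The [0,1] values are
pushed through log-normal quantile functions whose log-scale moments match
each parameter's natural-scale mean and SD:

    μ_log = 2 ln m − ½ ln(m²+s²),  σ_log = √(ln(m²+s²) − 2 ln m).

The right-hand side of the σ expression is a *variance*; the square root
is required for the moment identities exp(μ+σ²/2) = m and
(exp(σ²)−1)exp(2μ+σ²) = s² to hold, and the package takes it. Parameter
SDs default to the WLS fit covariance (J′WJ)⁻¹; a parameter with
non-positive mean or unusable SD is held fixed with a warning. NLME
per-patient TIA SDs are deliberately not produced: the mixed-effects fit
reports population variability, not per-patient estimator uncertainty.
Fraction parameters, when sampled, use the same log-normal marginal (they
are fixed in the shipped SP-PBMS evaluation mode); draws exceeding 1 are
possible in principle and not clipped — a documented limitation.

## Metrics

RD_j = (TIA_j − TIA_MA)/TIA_MA in percent per patient;
RMSE_j = √(SD(RD)² + mean(RD)²). The SD uses the sample (n−1) denominator
by default — the field's standard — and the population-denominator variant
(under which RMSE ≡ √mean(RD²) exactly) is available via `ddof=0`; the
choice is recorded in the report metadata.

## Synthetic cohorts

The generator reproduces the study design: 13 patients; nominal scans at
(1.1±0.7) h, (20.7±2.3) h, (163.8±2.0) h; patient 1 gains one point at
66.1 h; patients 2–4 gain two points at (45.9±1.6) h and (68.7±1.7) h;
46 observations in total. Scan times are independent truncated normals
(>0, 100 retries then error). Truth defaults are a fixture choice of this
package, not published values: f3a with A₁ = 0.04, A₂ = 0.005 (fractions
of injected activity, kidney-like magnitudes), λ₁ = 0.02 h⁻¹, ω = 0.3 on
every parameter, σ_res = 0.15. What the generator does *not* emulate:
imaging physics (scatter, background, calibration), correlated random
effects, model misspecification (truth is always inside the candidate
family) and non-Gaussian residuals — so passing recovery tests demonstrate
the estimator's correctness under its own assumptions, not robustness to
real-data artefacts.

The recovery experiments fix their conditions once: 200 replicates for
fixed-effect bias and 100 cohorts for selection recovery, both at the
default design, with the candidate set {f2a, f3a, f3c, f4a} — the
jackknife-stable subset of the gate-passing family plus the IBMS
mono-exponential, with f3b omitted because it is statistically identical
to f3c here and would only split its weight. These sizes keep the full
suite within ordinary CI runtimes while leaving the stochastic acceptance
margins comfortably resolvable.

## Degenerate inputs and edge behaviour

* Single-patient cohorts fit with a warning; ω² is flagged unidentifiable.
* A candidate for which no start yields a finite objective (e.g. f5b,
  pinned to 0 at t = 0, on data with large early activity) returns a
  result flagged `converged_ = False` with infinite −2lnP and CV — never a
  silent success, never an exception mid-selection.
* Zero-variance designs (ω = 0, σ_res = 0) generate identical, noise-free
  patients and are used for exactness tests.
* All randomness (multi-start jitter, sampler phases, cohort generation)
  is seed-driven; identical runs are bit-identical.

## Known limitations

* Laplace/Gauss–Newton is an approximation; its accuracy is verified
  against quadrature only in the log-linear case, where it is exact.
* The outer surface can be multimodal; the data-driven start plus small
  multi-start finds the dominant basin in all tested scenarios, but hard
  data sets may need a larger `n_starts`.
* CV-based gating inherits the finite-difference Hessian's conditioning;
  a near-singular information matrix close to a variance boundary can
  report CV = ∞ and gate out an otherwise usable fit (conservative
  behaviour).
* No covariate models, correlated random effects, SAEM/FOCE-I variants or
  Bayesian posterior sampling; compartmental models are out of scope.
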