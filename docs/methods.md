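# Methods

## Model

The package implements one-step Bayesian meta-analysis of individual
participant survival data in which each trial's baseline log *cumulative*
hazard is a restricted cubic spline (RCS) of log time.  Working on the
cumulative-hazard scale makes the likelihood closed-form — no numerical
integration and no data expansion into risk sets — which is what makes a
patient-level Bayesian network analysis of thousands of patients practical.

For patient *i* in trial *j*:

    ln H_j(t_i | x_i) = s_j(ln t_i) + c_i'b_j + (c_i'α + u_j Σ_k c_ik)·ln t_i
                        − Σ_loops ω_L · c_i,k1(L) · c_i,k2(L)

with

- `s_j(x) = γ_j1 + γ_j2 u_0(x) + … + γ_j,p+2 u_p(x)` the trial's RCS
  baseline on orthogonalised basis functions;
- `c_i` the patient's treatment-contrast vector in the q basic parameters
  (entries −1/0/1, consistency-equation coding; the design reference arm is
  all zeros);
- `b_j = β` (fixed treatment effects, FTE) or `b_j = β_j ~ MVN(μ, T)`
  (random treatment effects, RTE);
- `α` the treatment–ln(time) interaction coefficients (zero under
  proportional hazards) and `u_j ~ N(0, σ_u²)` an optional trial-level
  deviation added to every interaction coefficient;
- `ω_L` an inconsistency offset per treatment loop, entering through the
  product of the two basic-contrast columns belonging to the loop — a
  covariate that is nonzero only in the loop-closing design.

The log likelihood of each patient is `ln(dη) + η − exp(η)` for an event
and `−exp(η)` for a right-censored time, where `dη` is the derivative of
the linear predictor with respect to ln t.  This is the exact density of
the observed *log* times; it differs from the time-scale density only by
the parameter-free Jacobian Σ_events ln t, which is the convention used
throughout (the Weibull cross-checks in the test suite include that term).
The likelihood is evaluated natively; the Poisson "zeros trick" that
general-purpose Gibbs samplers need for non-standard densities is retained
only as an algebraic identity in the tests, not as a production path.

`dη > 0` is required on event rows (the hazard must be positive where an
event occurred).  Rather than reparameterising γ, the likelihood returns
−∞ there and the sampler rejects; this follows the likelihood's natural
domain exactly.

### Spline basis

Raw basis: column 0 is `x = ln t`; column *k* is
`v_k(x) = (x−k_k)₊³ − λ_k (x−k_min)₊³ − (1−λ_k)(x−k_max)₊³` with
`λ_k = (k_max−k_k)/(k_max−k_min)` — the standard restricted-cubic form,
linear outside the boundary knots.  Boundary knots sit at the minimum and
maximum uncensored ln survival times of the trial; interior knots default
to centiles of the uncensored ln times (50 for one knot; 33/67 for two;
25/50/75 for three), computed as empirical quantiles with linear
interpolation.  Knots may also be supplied per trial (on the time or ln
scale); up to three interior knots are supported, since more tends to make
the curves unstable.

The basis (with intercept) is orthogonalised over the trial's own ln
times — all rows, censored included — by a QR factorisation with the
intercept first, which is Gram–Schmidt in exact arithmetic.  The intercept
column of the result is rescaled back to exactly one, and each remaining
column is signed so that its inner product with its raw source column is
positive; this removes QR's sign ambiguity and makes runs reproducible.
Orthogonalisation is purely a conditioning device: the recorded invertible
transform maps coefficients between bases, and the maximised likelihood is
invariant to the choice (verified to 1e−6 in the tests).  Analytic
derivatives of the raw columns are mapped through the same non-intercept
transform.

Times are accepted in any single unit and never rescaled; since knots live
on the ln-time scale, knot locations are unit-dependent and the caller must
keep units consistent across trials.

### Priors

Defaults (overridable in `PriorSpec`): γ ~ N(0, 10000); β, α and μ
~ N(0, 1000); ω ~ N(0, 10); σ_u half-normal with variance 1000;
T ~ Inverse-Wishart(V = I_q, k = q), the weakest proper choice with an
identity scale.  The N(0, 1000) reading for μ takes the stated 0.001 as a
precision, the convention of the Gibbs-sampling software tradition these
models come from; both readings are noted as defensible, and the choice is
exposed through `PriorSpec.mu_var`.

## Sampler

Adaptive blockwise random-walk Metropolis targeting the exact posterior:

- one block per trial for γ_j (mirroring the stratified baselines), one
  per trial for β_j in the RTE model, scalar blocks for each u_j, σ_u and
  each ω, and a single joint block for (β, α) in fixed-effect models with
  interactions — those two sets are strongly correlated (level and ln-t
  slope of the same covariate), so they share a proposal;
- proposal scales follow a Robbins–Monro recursion toward standard
  acceptance targets (0.44 scalar, 0.234 for larger blocks) during burn-in
  only; at three burn-in checkpoints each multi-dimensional block adopts
  the Cholesky factor of its empirical draw covariance as proposal shape.
  Nothing adapts after burn-in, so the stored chain is a valid Markov
  chain;
- in the RTE model μ and T are updated by their conjugate Gibbs steps
  (normal and inverse-Wishart respectively) each iteration;
- per-trial likelihood contributions are cached, so a block update only
  recomputes the trials it touches.

Initial values: γ_j from a least-squares fit of the Nelson–Aalen log
cumulative hazard on the trial's basis (falling back to a Weibull-style
linear fit with positive slope if the least-squares start violates hazard
positivity); treatment, interaction and inconsistency parameters at zero;
T at the identity; σ_u at 0.2.  Chains beyond the first jitter the start
point, shrinking the jitter until it is inside the likelihood support.
All randomness derives from `(seed, chain)` streams, so runs are
bit-reproducible.  Defaults are 2 chains with 20000 burn-in and 20000
stored iterations, mirroring a final-analysis configuration; the library
tests and the CLI's default preset use 2 × 2000/2000, and the calibration
studies in the test suite use 400–800 per phase, which the adaptive
proposals make adequate for the small networks involved there.

Convergence is summarised by split-chain potential scale reduction and
effective sample size (via arviz), flagging parameters above 1.05 — a
package default, chosen as a conventional screen rather than taken from
any reference analysis.  DIC is computed as `D̄ + pD` with
`pD = D̄ − D(θ̄)` at the posterior mean; a negative pD and a posterior
mean outside the likelihood support are reported, not raised.

## Analysis layer

- **Pairwise MA** is the network model restricted to one design; adding the
  interaction term gives the comparison-level global non-PH test.
- **Global Wald test of PH**: `W = m̂' V̂⁻¹ m̂` with `m̂`, `V̂` the posterior
  mean and covariance of the interaction block, df = block size, optionally
  including σ_u (testing a variance at its boundary is conservative; the
  df convention counts it as one parameter).  A singular V̂ falls back to a
  pseudo-inverse with a warning.
- **Direct/indirect separation**: one fit with ω frees the loop; the
  closing design identifies its comparison's direct effect as the
  consistency combination plus ω, and each indirect estimate differs from
  the corresponding direct one by ω with the loop's orientation.  Network
  estimates come from the ω-free fit.  All derived quantities are computed
  per draw, never by differencing posterior summaries.
- **Q decomposition**: per-trial estimates θ̂_ij with standard errors σ̂_ij
  are pooled per design by inverse variance (θ̂_j, with σ̂_j² the reciprocal
  total weight — the choice that makes Q = Q_inc + Q_het exact);
  Q compares trials with the network estimates, Q_het with their design
  pool, Q_inc the pools with the network.  df_het = Σ_j(n_j−1),
  df_inc = D − q* with q* the graph rank of the design comparisons.
  Per-trial inputs default to frequentist Cox fits; multiarm trials enter
  through their constituent reference-vs-arm contrasts without the matrix
  covariance adjustment (a documented approximation).
- **Ranking**: per draw, every treatment's effect versus the reference
  (reference = 0) is ranked ascending — smallest log hazard ratio is most
  effective — and tallied into a percentage table that is doubly
  stochastic (×100) by construction.

## Diagnostics module

Nelson–Aalen estimation, Cox fits and the Schoenfeld-residual PH test are
delegated to lifelines behind the module's own surface.  The Cox fits use
Efron tie handling (the library's convention; identical to Breslow in the
absence of ties, and the brute-force partial-likelihood oracle in the test
suite evaluates the same convention).  The Schoenfeld test's time transform
defaults to ln t so the screen aligns with the model's interaction
alternative — the transform any particular reference analysis used is
generally unstated, so this default is the package's own; a Kaplan–Meier
rank transform is available by flag.  Independent per-trial chi-squares
pool by addition with df equal to the number of trials.

## Synthetic-data generator

`simulate_network` draws from exactly the model the engine fits: the
cumulative hazard is multiplied by `exp(c'β_j + c'α ln t − δ·product)`, so
recovered parameters target the generating ones without approximation
bias, and event times come from inversion of `H(T) = E`, `E ~ Exp(1)` —
closed form for Weibull baselines (the ln-t drift only shifts the shape;
the effective shape must stay positive), bracketed bisection on ln t (tol
1e−10) for explicit spline baselines, which is unconditionally safe because
H is monotone.  Censoring is the minimum of an administrative horizon and
exponential dropout.  One global seed drives deterministic per-trial
substreams, so a trial's data are invariant to the presence of other
trials.

The default preset emulates a four-treatment chemo/radiotherapy survival
network: 15 trials in design proportions 6 : 5 : 3 : 1
(RT/CTRT, RT/CT+RT, RT/CT+S, CT+RT/CT+S), ≈1500 patients (≈48 per arm),
per-trial Weibull baselines with scales 0.08–0.18 and shapes 0.9–1.3
(median survival of a few years on a scale of years), a 10-year
administrative horizon with exponential dropout at rate 0.02/year
(roughly 70–80% events), true log hazard ratios (−0.21, +0.15, −0.40) —
magnitudes typical of the field — and, by default, proportional hazards,
no between-trial heterogeneity and no inconsistency.  The loop-closing
design is a *two-arm* CT+RT vs CT+S trial: in a three-arm closing design
the inconsistency product covariate is identically zero (multiarm trials
are internally consistent), so a two-arm design is what identifies ω and
makes the consistency machinery exercisable.

What the generator does *not* emulate: patient covariates and
treatment–covariate interactions, informative censoring, staggered accrual
or calendar-time effects, reporting or publication bias, and non-PH shapes
other than a log-linear drift of the hazard ratio.  Tests passing on these
synthetic networks therefore establish the correctness and calibration of
the machinery under its own assumptions, not robustness of the model to
real-data violations of them.

## Problem sizes in the test suite

The calibration and recovery studies run at sizes chosen to make their
Monte-Carlo tolerances meaningful: credible-interval coverage over 50
replicates of the full default network (2 × 2000/2000 chains); Wald
type-I error over 200 replicates of a reduced 4-trial star network
(60/arm); power against a drift of 0.5 over 6 trials of 300/arm;
inconsistency recovery at 500/arm with an injected offset of 0.5 and null
coverage over 20 consistent replicates.  Binomial bands at the chosen
replicate counts define the pass criteria.

## Known limitations

- No aggregate-data synthesis, patient-level covariates, time-dependent
  covariates, left truncation, restricted-mean-survival summaries, or
  fractional-polynomial/piecewise-exponential baselines.
- Loop inconsistency uses the product coding, which requires edge-disjoint
  loops; overlapping loops (node-splitting territory) are rejected rather
  than mis-parameterised.
- The multiarm covariance adjustment to Q is not implemented; multiarm
  trials contribute their constituent contrasts independently.
- Random-walk sampling is robust but not gradient-efficient; very large
  networks would benefit from a gradient-based sampler, which the
  differentiable likelihood permits off the hazard-positivity boundary.
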