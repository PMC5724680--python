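# rpnma — Bayesian IPD network meta-analysis of survival data with Royston–Parmar models

`rpnma` fits one-step Bayesian (network) meta-analysis models to
individual-participant time-to-event data.  It is aimed at meta-analysts in
oncology and other fields with long follow-up, where the Cox model's
proportional-hazards (PH) assumption is fragile and a Bayesian implementation
of the Cox model is computationally impractical for patient-level networks of
thousands of patients.

## The model

For patient *i* in trial *j* of a network with *q* + 1 treatments, the log
cumulative hazard is

```
ln H_j(t | x_ij) = s_j(ln t) + β₁·trt1_i + … + β_q·trtq_i
```

where `s_j(ln t) = γ_1 + γ_2 u_0(ln t) + … + γ_{p+2} u_p(ln t)` is a
trial-specific restricted cubic spline (RCS) in log time — piecewise cubic,
twice continuously differentiable, linear beyond boundary knots placed at
the extreme uncensored log survival times, with interior knots at centiles
of the uncensored times and Gram–Schmidt-orthogonalised basis functions
`u_0 … u_p` — and `trt1 … trtq` are treatment-contrast variables in
{−1, 0, 1} encoding each arm's effect versus its design reference through
the network consistency equations.  The exact individual log likelihood is

```
event:     ln(dη_ij) + η_ij − exp(η_ij)
censored:  −exp(η_ij)
```

with `dη` the derivative of the linear predictor in ln t.  On top of this
core the package provides:

- **fixed or random treatment effects** (`β_j ~ MVN(μ, T)` with an
  inverse-Wishart prior on the between-trial covariance `T`);
- **treatment–ln(time) interactions** — fixed, or varying by trial with a
  hierarchical deviation `u_j ~ N(0, σ_u²)` — and the approximate global
  Wald test of PH built from their posterior moments, plus trial-level
  shrinkage intervals `u_j ± 1.96·sd_j`;
- **loop inconsistency parameters** ω separating direct from indirect
  evidence in each treatment loop;
- **Cochran's Q decomposition** `Q = Q_inc + Q_het` into between-design
  (inconsistency) and within-design (heterogeneity) components;
- **DIC** (`D̄ + pD`) for model comparison and **posterior treatment
  ranking** (per-draw rank tallies);
- the pre-modelling screens that precede such an analysis: per-trial Cox
  fits, Schoenfeld-residual PH tests with chi-square pooling across trials,
  and Nelson–Aalen overlays for choosing spline knots;
- a **synthetic network generator** with known truth (Weibull or spline
  baselines, non-PH drift, heterogeneity, injected inconsistency,
  administrative plus dropout censoring).

Posterior sampling is adaptive blockwise random-walk Metropolis (one block
per trial baseline, covariance-adapted global blocks, conjugate Gibbs steps
for μ and T), deterministic given a seed.

## Worked example

```python
from rpnma import (ModelSpec, MCMCSettings, default_cervical_like_spec,
                   fit_nma, simulate_network)

spec = default_cervical_like_spec(seed=1)   # 15 trials, ~1500 patients
data, truth = simulate_network(spec)
fit = fit_nma(data, ModelSpec(network=spec.network),
              settings=MCMCSettings(chains=2, burnin=1500, iterations=1500,
                                    seed=3))
print(fit.summaries.loc["beta[RT:CTRT]"])
print(f"DIC = {fit.dic:.1f}")
```

prints (posterior mean log hazard ratio of chemoradiation vs radiotherapy
with 95% credible interval, against a generating value of −0.21):

```
mean    -0.192879
sd       0.094710
2.5%    -0.396028
50%     -0.188363
97.5%   -0.016034
Name: beta[RT:CTRT], dtype: float64
DIC = 4153.3
```

A log hazard ratio below zero favours the treatment over radiotherapy.  The
scripts in `examples/` walk through each capability — simulation, pairwise
meta-analysis, the NMA fits with DIC, the PH screens, inconsistency
separation, and the Q/ranking summaries — each printing the numbers it
computes and a line on how to read them.

A thin command line mirrors the workflow
(`rpnma simulate | ma | nma | diagnose | rank | qdecomp`); every output
table carries the run's seed and a configuration hash.  The default MCMC
preset is 2 chains × 2000 burn-in / 2000 stored iterations;
`--paper-settings` switches to 20000/20000 for final analyses.

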