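"""Model core: linear predictor, exact log likelihood and log priors.

Every model variant shares the same structure for patient i in trial j:

    ln H_j(t | x_ij) = s_j(ln t) + sum_k c_k * b_k
                       + sum_k c_k (alpha_k + u_j) ln t      [interactions]
                       - sum_loops omega * c_{k1} c_{k2}     [inconsistency]

where s_j is the trial's spline baseline (gamma coefficients on the
orthogonalised RCS basis), c is the patient's treatment-contrast vector in
the q basic parameters, b is the fixed treatment-effect vector beta (fixed
treatment effects, FTE) or the trial's own draw beta_trial[j] ~ MVN(mu, T)
(random treatment effects, RTE), alpha the treatment-ln(time) interaction
coefficients (proportional-hazards test), u_j an optional trial-level random
interaction deviation with u_j ~ N(0, sigma_u^2), and omega a loop
inconsistency parameter.

The individual log likelihood (on the ln-time scale) is

    event:    ln(d eta) + eta - exp(eta)
    censored: -exp(eta)

with d eta the derivative of the linear predictor w.r.t. ln t.  d eta <= 0 on
an event row means a locally negative hazard; the likelihood returns -inf so
samplers reject rather than raising.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .ipd import IPDDataset, NetworkSpec, ValidationError
from .spline import KnotSet, SplineBasis, orthogonalise, place_knots

__all__ = [
    "ModelSpec",
    "PriorSpec",
    "ParameterState",
    "ModelData",
    "build_contrasts",
    "linear_predictor",
    "log_likelihood",
    "pointwise_log_likelihood",
    "log_prior",
]

_LOG2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class ModelSpec:
    """Which variant of the NMA model to fit."""

    network: NetworkSpec
    knots: dict = field(default_factory=dict)  # trial_id -> KnotSet
    effect: str = "fixed"  # {"fixed", "random"}
    interactions: str = "none"  # {"none", "fixed", "random-by-trial"}
    inconsistency: tuple = ()  # loops (treatment triples) to parameterise

    def __post_init__(self):
        if self.effect not in ("fixed", "random"):
            raise ValueError(f"effect must be fixed|random, got {self.effect!r}")
        if self.interactions not in ("none", "fixed", "random-by-trial"):
            raise ValueError(f"bad interactions {self.interactions!r}")
        for loop in self.inconsistency:
            if tuple(loop) not in self.network.loops:
                raise ValueError(f"loop {loop} not declared in the network")
        # product coding is only defined for edge-disjoint loops
        loops = [set(l) for l in self.inconsistency]
        for i in range(len(loops)):
            for j in range(i + 1, len(loops)):
                if len(loops[i] & loops[j]) >= 2:
                    raise ValueError(
                        "inconsistency loops must be edge-disjoint "
                        f"({sorted(loops[i])} vs {sorted(loops[j])})"
                    )

    @property
    def q(self) -> int:
        return self.network.q


@dataclass(frozen=True)
class PriorSpec:
    """Prior variances (normal components are zero-mean).

    Defaults: gamma ~ N(0, 10000); beta, interaction coefficients and mu
    ~ N(0, 1000); omega ~ N(0, 10); sigma_u half-normal with variance 1000;
    T ~ Inverse-Wishart(I_q, q) in the random-effect model — the weakest
    proper choice with identity scale.
    """

    gamma_var: float = 10000.0
    beta_var: float = 1000.0
    beta_int_var: float = 1000.0
    omega_var: float = 10.0
    sigma_u_var: float = 1000.0
    mu_var: float = 1000.0
    iw_df: int | None = None  # defaults to q
    iw_scale: np.ndarray | None = None  # defaults to I_q


@dataclass
class ParameterState:
    """One point in parameter space.

    ``gamma`` maps trial_id to its spline coefficient vector (length p_j + 2,
    intercept first, on the orthogonalised basis).  ``beta`` (FTE) or
    ``beta_trial``/``mu``/``T`` (RTE) carry the treatment effects in the q
    basic contrasts; ``beta_int`` the treatment-ln(time) interactions;
    ``u``/``sigma_u`` the trial-level random interaction deviations; ``omega``
    maps loops to inconsistency offsets.
    """

    gamma: dict
    beta: np.ndarray | None = None
    beta_int: np.ndarray | None = None
    u: dict = field(default_factory=dict)
    sigma_u: float = 0.0
    omega: dict = field(default_factory=dict)
    beta_trial: dict = field(default_factory=dict)
    mu: np.ndarray | None = None
    T: np.ndarray | None = None


def build_contrasts(network: NetworkSpec, design, assigned: str) -> np.ndarray:
    """The q-vector of treatment-contrast values for one patient.

    The design's reference arm codes all zeros; any other arm codes its
    effect versus the design reference expressed in the basic contrasts via
    the consistency equations.  Entries are 0, 1 or -1 for networks whose
    basic contrasts form a tree rooted at the network reference.
    """
    d = design if hasattr(design, "reference") else network.design_for(design)
    if assigned not in d.treatments:
        raise ValidationError(f"{assigned!r} is not an arm of design {d.treatments}")
    return network.expression(assigned) - network.expression(d.reference)


def _loop_columns(network: NetworkSpec, loop) -> tuple[int, int]:
    """Indices (k1, k2) of the two basic contrasts whose product codes the loop.

    For a loop (A, B, C) whose edges include two basic contrasts, the product
    c_k1 * c_k2 is nonzero only for patients in the loop-closing design, which
    is what lets a single omega separate direct from indirect evidence.
    """
    members = set(loop)
    ks = [
        k for k, (a, b) in enumerate(network.basic_contrasts)
        if a in members and b in members
    ]
    if len(ks) != 2:
        raise ValidationError(
            f"loop {loop} must contain exactly two basic contrasts, found {len(ks)}"
        )
    return ks[0], ks[1]


# ---------------------------------------------------------------------------
# Assembled per-trial data with bases and contrast codes


@dataclass
class TrialData:
    trial_id: object
    basis: SplineBasis
    X: np.ndarray        # (n, m) gamma design [1, ortho]
    D: np.ndarray        # (n, m) its ln-t derivative
    lnt: np.ndarray      # (n,)
    event: np.ndarray    # (n,) bool
    C: np.ndarray        # (n, q) treatment contrasts
    sumc: np.ndarray     # (n,) row sums of C (coefficient of u_j)
    inc: np.ndarray      # (n, L) product covariates per parameterised loop

    @property
    def n(self) -> int:
        return len(self.lnt)


@dataclass
class ModelData:
    """IPD with per-trial spline bases and contrast codes attached."""

    spec: ModelSpec
    trials: list  # of TrialData
    loops: tuple  # loops actually parameterised, order fixes omega indexing

    @classmethod
    def assemble(cls, data: IPDDataset, spec: ModelSpec,
                 default_interior: int = 2) -> "ModelData":
        data.validate(spec.network)
        loops = tuple(tuple(l) for l in spec.inconsistency)
        loop_cols = [_loop_columns(spec.network, l) for l in loops]
        trials = []
        for tid in data.trial_ids:
            sub = data.trial(tid).df
            lnt = np.log(np.asarray(sub["time"], dtype=float))
            event = np.asarray(sub["event"], dtype=int) == 1
            knots = spec.knots.get(tid)
            if knots is None:
                n_int = default_interior
                while n_int > 0:
                    try:
                        knots = place_knots(sub, n_int)
                        break
                    except ValueError:
                        n_int -= 1
                else:
                    knots = place_knots(sub, 0)
            basis = orthogonalise(lnt, knots)
            design = spec.network.design_for(set(sub["treatment"]))
            codes = {t: build_contrasts(spec.network, design, t) for t in design.treatments}
            C = np.vstack([codes[t] for t in sub["treatment"]])
            inc = np.column_stack(
                [C[:, k1] * C[:, k2] for (k1, k2) in loop_cols]
            ) if loops else np.zeros((len(lnt), 0))
            trials.append(TrialData(
                trial_id=tid, basis=basis,
                X=basis.design(), D=basis.design_deriv(),
                lnt=lnt, event=event, C=C, sumc=C.sum(axis=1), inc=inc,
            ))
        return cls(spec=spec, trials=trials, loops=loops)

    @property
    def n(self) -> int:
        return sum(t.n for t in self.trials)


# ---------------------------------------------------------------------------
# Evaluation


def _trial_eta(state: ParameterState, spec: ModelSpec, td: TrialData,
               loops) -> tuple[np.ndarray, np.ndarray]:
    gamma = np.asarray(state.gamma[td.trial_id], dtype=float)
    eta = td.X @ gamma
    deta = td.D @ gamma
    b = (state.beta_trial[td.trial_id] if spec.effect == "random" else state.beta)
    if b is not None and td.C.shape[1]:
        eta = eta + td.C @ np.asarray(b, dtype=float)
    if spec.interactions != "none":
        slope = td.C @ np.asarray(state.beta_int, dtype=float)
        if spec.interactions == "random-by-trial":
            slope = slope + float(state.u.get(td.trial_id, 0.0)) * td.sumc
        eta = eta + slope * td.lnt
        deta = deta + slope
    for li, loop in enumerate(loops):
        w = float(state.omega.get(tuple(loop), 0.0))
        if w != 0.0:
            eta = eta - w * td.inc[:, li]
    return eta, deta


def linear_predictor(state: ParameterState, spec: ModelSpec, mdata: ModelData,
                     trial_id, ln_time: float, contrast: np.ndarray
                     ) -> tuple[float, float]:
    """(eta, d eta/d ln t) for one patient at an arbitrary time.

    Evaluates the trial's basis at ``ln_time`` through the recorded
    orthogonalisation transform, then adds the treatment, interaction and
    inconsistency terms for the supplied contrast vector.
    """
    td = next(t for t in mdata.trials if t.trial_id == trial_id)
    X, D = td.basis.evaluate([ln_time])
    gamma = np.asarray(state.gamma[trial_id], dtype=float)
    eta = float(X[0] @ gamma)
    deta = float(D[0] @ gamma)
    c = np.asarray(contrast, dtype=float)
    b = state.beta_trial[trial_id] if spec.effect == "random" else state.beta
    if b is not None and c.size:
        eta += float(c @ np.asarray(b, dtype=float))
    if spec.interactions != "none":
        slope = float(c @ np.asarray(state.beta_int, dtype=float))
        if spec.interactions == "random-by-trial":
            slope += float(state.u.get(trial_id, 0.0)) * float(c.sum())
        eta += slope * ln_time
        deta += slope
    for loop in mdata.loops:
        w = float(state.omega.get(tuple(loop), 0.0))
        if w != 0.0:
            k1, k2 = _loop_columns(spec.network, loop)
            eta -= w * c[k1] * c[k2]
    return eta, deta


def _loglik_terms(eta: np.ndarray, deta: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Per-patient log-likelihood contributions; -inf rows where deta<=0 on events."""
    out = -np.exp(eta)
    de = deta[event]
    lnde = np.where(de > 0.0, np.log(np.where(de > 0.0, de, 1.0)), -np.inf)
    out[event] = out[event] + lnde + eta[event]
    return out


def pointwise_log_likelihood(state: ParameterState, spec: ModelSpec,
                             mdata: ModelData) -> np.ndarray:
    """Vector of per-patient log-likelihood contributions, in data order."""
    parts = []
    for td in mdata.trials:
        eta, deta = _trial_eta(state, spec, td, mdata.loops)
        parts.append(_loglik_terms(eta, deta, td.event))
    return np.concatenate(parts)


def log_likelihood(state: ParameterState, spec: ModelSpec, mdata: ModelData) -> float:
    """Total exact log likelihood; -inf when any event row has deta <= 0."""
    total = 0.0
    for td in mdata.trials:
        eta, deta = _trial_eta(state, spec, td, mdata.loops)
        if np.any(deta[td.event] <= 0.0):
            return -np.inf
        total += float(np.sum(np.log(deta[td.event])) + np.sum(eta[td.event])
                       - np.sum(np.exp(eta)))
    return total


def _norm_logpdf(x, var) -> float:
    x = np.atleast_1d(np.asarray(x, dtype=float))
    return float(-0.5 * np.sum(x * x) / var - 0.5 * x.size * (_LOG2PI + math.log(var)))


def log_prior(state: ParameterState, spec: ModelSpec, priors: PriorSpec) -> float:
    """Sum of log prior densities (up to additive constants kept exact here)."""
    q = spec.q
    lp = 0.0
    for g in state.gamma.values():
        lp += _norm_logpdf(g, priors.gamma_var)
    if spec.effect == "fixed":
        if state.beta is not None:
            lp += _norm_logpdf(state.beta, priors.beta_var)
    else:
        T = np.asarray(state.T, dtype=float)
        if not np.all(np.isfinite(T)):
            return -np.inf
        try:
            chol = np.linalg.cholesky(T)
        except np.linalg.LinAlgError:
            return -np.inf
        mu = np.asarray(state.mu, dtype=float)
        lp += _norm_logpdf(mu, priors.mu_var)
        logdet = 2.0 * float(np.sum(np.log(np.diag(chol))))
        for bj in state.beta_trial.values():
            z = np.linalg.solve(chol, np.asarray(bj, dtype=float) - mu)
            lp += -0.5 * float(z @ z) - 0.5 * (q * _LOG2PI + logdet)
        df = priors.iw_df if priors.iw_df is not None else q
        scale = priors.iw_scale if priors.iw_scale is not None else np.eye(q)
        lp += float(stats.invwishart.logpdf(T, df=df, scale=scale))
    if spec.interactions != "none":
        lp += _norm_logpdf(state.beta_int, priors.beta_int_var)
        if spec.interactions == "random-by-trial":
            if state.sigma_u < 0:
                return -np.inf
            # half-normal: normal density folded onto the positive axis
            lp += _norm_logpdf(state.sigma_u, priors.sigma_u_var) + math.log(2.0)
            su2 = max(float(state.sigma_u) ** 2, 1e-300)
            for uj in state.u.values():
                lp += _norm_logpdf(uj, su2)
    for w in state.omega.values():
        lp += _norm_logpdf(w, priors.omega_var)
    return lp
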