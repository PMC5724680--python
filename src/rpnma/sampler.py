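"""Posterior sampling, convergence summaries and DIC.

The posterior is sampled by adaptive blockwise random-walk Metropolis: one
block per trial for the spline coefficients (mirroring the per-trial
stratified baseline), global blocks for treatment effects, interactions and
inconsistency parameters, scalar blocks for trial-level interaction
deviations, and — in the random-treatment-effect model — conjugate Gibbs
steps for the between-trial mean (normal) and covariance (inverse-Wishart).
Proposal scales adapt toward standard acceptance targets during burn-in only,
so the post-burn-in chain is a valid Markov chain targeting the exact
posterior.  Runs are deterministic given (seed, settings, data ordering).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import (ModelData, ModelSpec, ParameterState, PriorSpec,
                    log_likelihood)

__all__ = [
    "MCMCSettings",
    "ChainSet",
    "FitResult",
    "run_mcmc",
    "dic",
    "convergence_report",
    "summarise_fit",
]


@dataclass(frozen=True)
class MCMCSettings:
    """Sampler settings.  Defaults mirror the final-analysis configuration
    (2 chains, 20000 burn-in, 20000 stored iterations)."""

    chains: int = 2
    burnin: int = 20000
    iterations: int = 20000
    seed: int = 0
    prior_only: bool = False  # switch the likelihood off (prior-predictive checks)


#: small preset for interactive use and tests
PRESET_SMALL = MCMCSettings(chains=2, burnin=2000, iterations=2000)


# ---------------------------------------------------------------------------
# flat parameter layout


class ParamIndex:
    """Maps named parameter blocks to slices of a flat vector."""

    def __init__(self, mdata: ModelData):
        spec = mdata.spec
        q = spec.q
        self.blocks: list[tuple[tuple, slice]] = []  # random-walk blocks
        self.gibbs: dict[tuple, slice] = {}
        self.names: list[str] = []
        pos = 0

        def add(key, dim, names, gibbs=False):
            nonlocal pos
            sl = slice(pos, pos + dim)
            if gibbs:
                self.gibbs[key] = sl
            else:
                self.blocks.append((key, sl))
            self.names.extend(names)
            pos += dim
            return sl

        labels = spec.network.contrast_labels()
        self.gamma_sl = {}
        for td in mdata.trials:
            m = td.X.shape[1]
            self.gamma_sl[td.trial_id] = add(
                ("gamma", td.trial_id), m,
                [f"gamma[{td.trial_id}][{k}]" for k in range(m)])
        if spec.effect == "fixed":
            self.beta_sl = add(("beta",), q, [f"beta[{l}]" for l in labels])
        else:
            self.beta_trial_sl = {}
            for td in mdata.trials:
                self.beta_trial_sl[td.trial_id] = add(
                    ("beta_trial", td.trial_id), q,
                    [f"beta_trial[{td.trial_id}][{l}]" for l in labels])
            self.mu_sl = add(("mu",), q, [f"mu[{l}]" for l in labels], gibbs=True)
            tril = [(i, j) for i in range(q) for j in range(i + 1)]
            self.T_sl = add(("T",), len(tril),
                            [f"T[{i},{j}]" for i, j in tril], gibbs=True)
            self._tril = tril
        if spec.interactions != "none":
            self.beta_int_sl = add(("beta_int",), q, [f"beta_int[{l}]" for l in labels])
            if spec.interactions == "random-by-trial":
                self.u_sl = {}
                for td in mdata.trials:
                    self.u_sl[td.trial_id] = add(("u", td.trial_id), 1,
                                                 [f"u[{td.trial_id}]"])
                self.sigma_u_sl = add(("sigma_u",), 1, ["sigma_u"])
        self.omega_sl = {}
        for loop in mdata.loops:
            self.omega_sl[loop] = add(("omega", loop), 1,
                                      ["omega[" + ",".join(loop) + "]"])
        self.size = pos
        self.spec = spec
        self.q = q
        if spec.effect == "fixed" and spec.interactions != "none":
            # beta and beta_int are strongly correlated (level and ln-t slope
            # of the same covariate); sample them as one block with an
            # adapted full-covariance proposal
            merged = slice(self.beta_sl.start, self.beta_int_sl.stop)
            assert merged.stop - merged.start == 2 * q
            self.blocks = [(k, s) for k, s in self.blocks
                           if k not in (("beta",), ("beta_int",))]
            self.blocks.append((("beta+int",), merged))

    # -- packing helpers ---------------------------------------------------

    def pack_T(self, T: np.ndarray) -> np.ndarray:
        return np.array([T[i, j] for i, j in self._tril])

    def unpack_T(self, packed: np.ndarray) -> np.ndarray:
        T = np.zeros((self.q, self.q))
        for v, (i, j) in zip(packed, self._tril):
            T[i, j] = T[j, i] = v
        return T

    def state_from_flat(self, flat: np.ndarray, mdata: ModelData) -> ParameterState:
        spec = self.spec
        st = ParameterState(gamma={tid: flat[sl].copy()
                                   for tid, sl in self.gamma_sl.items()})
        if spec.effect == "fixed":
            st.beta = flat[self.beta_sl].copy()
        else:
            st.beta_trial = {tid: flat[sl].copy()
                             for tid, sl in self.beta_trial_sl.items()}
            st.mu = flat[self.mu_sl].copy()
            st.T = self.unpack_T(flat[self.T_sl])
        if spec.interactions != "none":
            st.beta_int = flat[self.beta_int_sl].copy()
            if spec.interactions == "random-by-trial":
                st.u = {tid: float(flat[sl][0]) for tid, sl in self.u_sl.items()}
                st.sigma_u = float(flat[self.sigma_u_sl][0])
        st.omega = {loop: float(flat[sl][0]) for loop, sl in self.omega_sl.items()}
        return st


# ---------------------------------------------------------------------------
# initial values


def default_inits(mdata: ModelData, chain: int, rng: np.random.Generator,
                  index: ParamIndex, jitter: float = 0.2) -> np.ndarray:
    """Starting point: per-trial spline coefficients from a least-squares fit
    of the Nelson-Aalen log cumulative hazard on the basis; treatment-effect,
    interaction and inconsistency parameters at 0; T at the identity.  Chains
    beyond the first are jittered (overdispersed), shrinking the jitter until
    the hazard-positivity constraint holds."""
    from .diagnostics import nelson_aalen

    flat = np.zeros(index.size)
    spec = mdata.spec
    for td in mdata.trials:
        na = nelson_aalen(np.exp(td.lnt), td.event.astype(int))
        lt = np.log(na.times)
        y = np.log(np.maximum(na.H, 1e-10))
        X, _ = td.basis.evaluate(lt)
        gamma, *_ = np.linalg.lstsq(X, y, rcond=None)
        if np.any(td.D[td.event] @ gamma <= 0.0):
            # fall back to a Weibull-style (linear in ln t) start
            A = np.column_stack([np.ones_like(lt), lt])
            ab, *_ = np.linalg.lstsq(A, y, rcond=None)
            a, b = float(ab[0]), max(float(ab[1]), 0.1)
            raw = np.zeros(index.gamma_sl[td.trial_id].stop
                           - index.gamma_sl[td.trial_id].start)
            raw[0], raw[1] = a, b
            gamma = td.basis.from_raw_coef(raw)
        flat[index.gamma_sl[td.trial_id]] = gamma
    if spec.effect == "random":
        flat[index.T_sl] = index.pack_T(np.eye(index.q))
    if spec.interactions == "random-by-trial":
        flat[index.sigma_u_sl] = 0.2
    if chain > 0 and jitter > 0:
        cand = flat.copy()
        cand += rng.normal(0.0, jitter, size=cand.size) * (np.abs(flat) * 0.5 + 0.5)
        if spec.interactions == "random-by-trial":
            cand[index.sigma_u_sl] = np.abs(cand[index.sigma_u_sl]) + 0.05
        if spec.effect == "random":
            cand[index.T_sl] = index.pack_T(np.eye(index.q))
        return cand
    return flat


# ---------------------------------------------------------------------------
# the sampler


class _Block:
    """One random-walk block with Robbins-Monro scale adaptation and, for
    multi-dimensional blocks, proposal-covariance adaptation from the
    burn-in draws (both frozen after burn-in)."""

    __slots__ = ("key", "sl", "dim", "log_scale", "sd", "L", "target", "t",
                 "n_acc", "w_n", "w_mean", "w_m2")

    def __init__(self, key, sl, init_sd):
        self.key = key
        self.sl = sl
        self.dim = sl.stop - sl.start
        self.log_scale = 0.0
        self.sd = np.full(self.dim, init_sd)
        self.L = None  # Cholesky factor of the adapted proposal covariance
        self.target = 0.44 if self.dim == 1 else (0.35 if self.dim < 5 else 0.25)
        self.t = 0
        self.n_acc = 0
        self.w_n = 0
        self.w_mean = np.zeros(self.dim)
        self.w_m2 = np.zeros((self.dim, self.dim))

    def step(self, rng):
        z = rng.standard_normal(self.dim)
        if self.L is not None:
            return math.exp(self.log_scale) * (self.L @ z)
        return math.exp(self.log_scale) * self.sd * z

    def adapt(self, accepted: bool):
        self.t += 1
        g = min(0.3, 3.0 / (10.0 + self.t) ** 0.6)
        self.log_scale += g * ((1.0 if accepted else 0.0) - self.target)

    def accumulate(self, x):
        self.w_n += 1
        delta = x - self.w_mean
        self.w_mean += delta / self.w_n
        self.w_m2 += np.outer(delta, x - self.w_mean)

    def refresh_proposal(self):
        if self.w_n <= max(self.dim + 2, 10):
            return
        cov = self.w_m2 / (self.w_n - 1)
        floor = 1e-8 + 1e-6 * np.abs(self.w_mean)
        if self.dim == 1:
            self.sd = np.maximum(np.sqrt(np.diag(cov)), floor)
            return
        first = self.L is None
        try:
            self.L = np.linalg.cholesky(
                cov + np.diag(np.maximum(1e-12, floor ** 2)))
            if first:
                # standard optimal scaling for Gaussian targets; later
                # Robbins-Monro updates refine it between checkpoints
                self.log_scale = math.log(2.38 / math.sqrt(self.dim))
        except np.linalg.LinAlgError:
            self.sd = np.maximum(np.sqrt(np.diag(cov)), floor)


class _NMASampler:
    def __init__(self, mdata: ModelData, priors: PriorSpec, settings: MCMCSettings):
        self.mdata = mdata
        self.spec = mdata.spec
        self.priors = priors
        self.settings = settings
        self.index = ParamIndex(mdata)
        self.J = len(mdata.trials)
        self.q = self.spec.q
        # which trials each block touches
        self.affected = {}
        all_trials = list(range(self.J))
        for key, sl in self.index.blocks:
            kind = key[0]
            if kind in ("gamma", "beta_trial", "u"):
                j = next(i for i, td in enumerate(mdata.trials)
                         if td.trial_id == key[1])
                self.affected[key] = [j]
            elif kind == "omega":
                li = list(mdata.loops).index(key[1])
                self.affected[key] = [i for i, td in enumerate(mdata.trials)
                                      if np.any(td.inc[:, li] != 0.0)]
            elif kind == "sigma_u":
                self.affected[key] = []
            else:  # beta, beta_int, beta+int
                self.affected[key] = all_trials

    # -- likelihood machinery with caches ----------------------------------

    def _off(self, flat, j):
        td = self.mdata.trials[j]
        idx = self.index
        spec = self.spec
        if spec.effect == "fixed":
            b = flat[idx.beta_sl]
        else:
            b = flat[idx.beta_trial_sl[td.trial_id]]
        off_eta = td.C @ b if self.q else np.zeros(td.n)
        off_deta = None
        if spec.interactions != "none":
            slope = td.C @ flat[idx.beta_int_sl]
            if spec.interactions == "random-by-trial":
                slope = slope + flat[idx.u_sl[td.trial_id]][0] * td.sumc
            off_eta = off_eta + slope * td.lnt
            off_deta = slope
        for li, loop in enumerate(self.mdata.loops):
            w = flat[idx.omega_sl[loop]][0]
            if w != 0.0:
                off_eta = off_eta - w * td.inc[:, li]
        if off_deta is None:
            off_deta = np.zeros(td.n)
        return off_eta, off_deta

    def _trial_ll(self, j, base_eta, base_deta, off_eta, off_deta):
        if self.settings.prior_only:
            return 0.0
        td = self.mdata.trials[j]
        deta = base_deta[td.event] + off_deta[td.event]
        if deta.size and np.min(deta) <= 0.0:
            return -np.inf
        eta = base_eta + off_eta
        ev = eta[td.event]
        return float(np.sum(np.log(deta)) + np.sum(ev) - np.sum(np.exp(eta)))

    def _refresh_all(self, flat):
        self.base_eta, self.base_deta, self.off_eta, self.off_deta, self.ll = \
            [], [], [], [], np.zeros(self.J)
        for j, td in enumerate(self.mdata.trials):
            g = flat[self.index.gamma_sl[td.trial_id]]
            be, bd = td.X @ g, td.D @ g
            oe, od = self._off(flat, j)
            self.base_eta.append(be)
            self.base_deta.append(bd)
            self.off_eta.append(oe)
            self.off_deta.append(od)
            self.ll[j] = self._trial_ll(j, be, bd, oe, od)

    # -- block-local log priors --------------------------------------------

    def _block_logprior(self, flat, key):
        idx = self.index
        pri = self.priors
        kind = key[0]
        if kind == "gamma":
            x = flat[idx.gamma_sl[key[1]]]
            return -0.5 * float(x @ x) / pri.gamma_var
        if kind == "beta":
            x = flat[idx.beta_sl]
            return -0.5 * float(x @ x) / pri.beta_var
        if kind == "beta+int":
            b = flat[idx.beta_sl]
            a = flat[idx.beta_int_sl]
            return (-0.5 * float(b @ b) / pri.beta_var
                    - 0.5 * float(a @ a) / pri.beta_int_var)
        if kind == "beta_trial":
            x = flat[idx.beta_trial_sl[key[1]]]
            mu = flat[idx.mu_sl]
            T = idx.unpack_T(flat[idx.T_sl])
            z = np.linalg.solve(np.linalg.cholesky(T), x - mu)
            return -0.5 * float(z @ z)
        if kind == "beta_int":
            x = flat[idx.beta_int_sl]
            return -0.5 * float(x @ x) / pri.beta_int_var
        if kind == "u":
            su = flat[idx.sigma_u_sl][0]
            x = flat[idx.u_sl[key[1]]][0]
            return -0.5 * (x / max(su, 1e-12)) ** 2
        if kind == "sigma_u":
            su = flat[idx.sigma_u_sl][0]
            if su <= 0.0:
                return -np.inf
            us = np.array([flat[idx.u_sl[tid]][0] for tid in idx.u_sl])
            return (-0.5 * su * su / pri.sigma_u_var
                    - us.size * math.log(su)
                    - 0.5 * float(us @ us) / (su * su))
        if kind == "omega":
            x = flat[idx.omega_sl[key[1]]][0]
            return -0.5 * x * x / pri.omega_var
        raise KeyError(key)

    # -- Gibbs steps (random-effect model) ---------------------------------

    def _gibbs_mu_T(self, flat, rng):
        idx = self.index
        pri = self.priors
        q = self.q
        B = np.vstack([flat[idx.beta_trial_sl[td.trial_id]]
                       for td in self.mdata.trials])
        T = idx.unpack_T(flat[idx.T_sl])
        Tinv = np.linalg.inv(T)
        P = self.J * Tinv + np.eye(q) / pri.mu_var
        cov = np.linalg.inv(P)
        mean = cov @ (Tinv @ B.sum(axis=0))
        mu = mean + np.linalg.cholesky(cov) @ rng.standard_normal(q)
        flat[idx.mu_sl] = mu
        resid = B - mu
        scale0 = pri.iw_scale if pri.iw_scale is not None else np.eye(q)
        df0 = pri.iw_df if pri.iw_df is not None else q
        Tnew = stats.invwishart.rvs(df=df0 + self.J,
                                    scale=scale0 + resid.T @ resid,
                                    random_state=rng)
        flat[idx.T_sl] = idx.pack_T(np.atleast_2d(Tnew))

    # -- main loop ----------------------------------------------------------

    def run_chain(self, chain: int) -> tuple[np.ndarray, np.ndarray]:
        s = self.settings
        rng = np.random.default_rng([s.seed % (2**31), chain])
        # shrink the overdispersion jitter until the start point is inside
        # the hazard-positivity support
        jitter = 0.2
        for _ in range(30):
            flat = default_inits(self.mdata, chain, rng, self.index, jitter)
            self._refresh_all(flat)
            if np.all(np.isfinite(self.ll)):
                break
            jitter *= 0.5
        else:
            raise RuntimeError("initial values outside the likelihood support")
        init_sd = {"gamma": 0.05, "beta": 0.05, "beta_trial": 0.05,
                   "beta_int": 0.05, "beta+int": 0.05, "u": 0.05,
                   "sigma_u": 0.1, "omega": 0.1}
        blocks = [_Block(key, sl, init_sd[key[0]]) for key, sl in self.index.blocks]
        n_store = s.iterations
        draws = np.empty((n_store, self.index.size))
        dev = np.empty(n_store)
        checkpoints = ({s.burnin // 3, (2 * s.burnin) // 3, s.burnin - 1}
                       if s.burnin >= 60 else set())
        for it in range(s.burnin + s.iterations):
            for blk in blocks:
                key, sl = blk.key, blk.sl
                old = flat[sl].copy()
                lp_old = self._block_logprior(flat, key)
                flat[sl] = old + blk.step(rng)
                lp_new = self._block_logprior(flat, key)
                if not np.isfinite(lp_new):
                    accept = False
                else:
                    js = self.affected[key]
                    new_parts = []
                    d_ll = 0.0
                    for j in js:
                        if key[0] == "gamma":
                            g = flat[sl]
                            td = self.mdata.trials[j]
                            be, bd = td.X @ g, td.D @ g
                            oe, od = self.off_eta[j], self.off_deta[j]
                        else:
                            be, bd = self.base_eta[j], self.base_deta[j]
                            oe, od = self._off(flat, j)
                        llj = self._trial_ll(j, be, bd, oe, od)
                        new_parts.append((j, be, bd, oe, od, llj))
                        d_ll += llj - self.ll[j]
                    logr = d_ll + lp_new - lp_old
                    accept = np.isfinite(logr) and math.log(rng.random()) < logr
                if accept:
                    blk.n_acc += 1
                    for j, be, bd, oe, od, llj in new_parts:
                        self.base_eta[j], self.base_deta[j] = be, bd
                        self.off_eta[j], self.off_deta[j] = oe, od
                        self.ll[j] = llj
                else:
                    flat[sl] = old
                if it < s.burnin:
                    blk.adapt(accept)
            if self.spec.effect == "random":
                self._gibbs_mu_T(flat, rng)
                # mu/T enter the beta_trial offsets only through priors; caches valid
            if it < s.burnin:
                for blk in blocks:
                    blk.accumulate(flat[blk.sl])
                if it in checkpoints:
                    for blk in blocks:
                        blk.refresh_proposal()
            else:
                k = it - s.burnin
                draws[k] = flat
                dev[k] = -2.0 * float(self.ll.sum())
        dead = [b.key for b in blocks if b.n_acc == 0 and b.t >= 200]
        if dead:
            raise RuntimeError(
                f"no proposal accepted for parameter block(s) {dead}; "
                "posterior appears unreachable from the initial values")
        return draws, dev


@dataclass
class ChainSet:
    """Post burn-in posterior draws for all chains."""

    draws: np.ndarray            # (n_chains, n_iter, n_params)
    deviance: np.ndarray         # (n_chains, n_iter)
    names: list
    index: ParamIndex
    mdata: ModelData
    settings: MCMCSettings

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_iter(self) -> int:
        return self.draws.shape[1]

    def get(self, name: str) -> np.ndarray:
        """Draws for one named scalar parameter, shape (chains, iterations)."""
        return self.draws[:, :, self.names.index(name)]

    def stacked(self, names) -> np.ndarray:
        """Pooled draws (all chains) for several parameters, shape (N, k)."""
        cols = [self.names.index(n) for n in names]
        return self.draws[:, :, cols].reshape(-1, len(cols))

    def state_at(self, chain: int, iteration: int) -> ParameterState:
        return self.index.state_from_flat(self.draws[chain, iteration], self.mdata)

    def posterior_mean_state(self) -> ParameterState:
        return self.index.state_from_flat(
            self.draws.reshape(-1, self.draws.shape[-1]).mean(axis=0), self.mdata)

    def to_long_dataframe(self) -> pd.DataFrame:
        """Plain long format (chain, iteration, parameter, value) for export."""
        recs = []
        for c in range(self.n_chains):
            df = pd.DataFrame(self.draws[c], columns=self.names)
            df.insert(0, "iteration", np.arange(self.n_iter))
            df.insert(0, "chain", c)
            recs.append(df.melt(id_vars=["chain", "iteration"],
                                var_name="parameter", value_name="value"))
        return pd.concat(recs, ignore_index=True)


def run_mcmc(spec_or_mdata, data=None, priors: PriorSpec | None = None,
             settings: MCMCSettings | None = None) -> ChainSet:
    """Sample the posterior of an NMA model.

    Accepts either an assembled :class:`ModelData`, or a
    :class:`~rpnma.model.ModelSpec` together with an
    :class:`~rpnma.ipd.IPDDataset`.
    """
    if isinstance(spec_or_mdata, ModelData):
        mdata = spec_or_mdata
    else:
        mdata = ModelData.assemble(data, spec_or_mdata)
    priors = priors or PriorSpec()
    settings = settings or MCMCSettings()
    if settings.chains < 1:
        raise ValueError("need at least one chain")
    sampler = _NMASampler(mdata, priors, settings)
    all_draws, all_dev = [], []
    for c in range(settings.chains):
        d, v = sampler.run_chain(c)
        all_draws.append(d)
        all_dev.append(v)
    return ChainSet(draws=np.stack(all_draws), deviance=np.stack(all_dev),
                    names=sampler.index.names, index=sampler.index,
                    mdata=mdata, settings=settings)


def dic(chains: ChainSet, spec: ModelSpec | None = None,
        mdata: ModelData | None = None) -> tuple[float, float, float]:
    """Deviance information criterion: (dbar, pd, dic) with dic = dbar + pd.

    dbar is the posterior mean deviance D = -2 log L; pd = dbar - D(thetabar)
    evaluated at the posterior mean of the parameters.  A negative pd is
    legitimate (flagged with a warning, not an error); a posterior-mean state
    outside the likelihood support is reported the same way and yields NaN
    effective-parameter and DIC values.
    """
    mdata = mdata or chains.mdata
    spec = spec or mdata.spec
    dbar = float(chains.deviance.mean())
    mean_state = chains.posterior_mean_state()
    ll_at_mean = log_likelihood(mean_state, spec, mdata)
    if not np.isfinite(ll_at_mean):
        warnings.warn("posterior-mean state lies outside the likelihood support; "
                      "pD and DIC are undefined")
        return dbar, float("nan"), float("nan")
    pd_ = dbar - (-2.0 * ll_at_mean)
    if pd_ < 0:
        warnings.warn(f"negative effective number of parameters pD={pd_:.2f}")
    return dbar, pd_, dbar + pd_


def convergence_report(chains: ChainSet, threshold: float = 1.05) -> pd.DataFrame:
    """Split-chain potential scale reduction and effective sample size.

    Parameters whose draws are constant have an undefined statistic and are
    reported as such rather than flagged.
    """
    import arviz as az

    if chains.n_chains < 2:
        raise ValueError("convergence diagnostics need >= 2 chains")
    rows = []
    data = {n: chains.draws[:, :, i] for i, n in enumerate(chains.names)}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        idata = az.convert_to_dataset(data)
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    for n in chains.names:
        arr = data[n]
        if np.allclose(arr, arr.flat[0]):
            rows.append({"parameter": n, "rhat": np.nan, "ess": np.nan,
                         "status": "undefined (constant draws)"})
            continue
        r = float(rhat[n].values)
        e = float(ess[n].values)
        rows.append({"parameter": n, "rhat": r, "ess": e,
                     "status": "flagged" if (np.isfinite(r) and r > threshold) else "ok"})
    return pd.DataFrame(rows)


@dataclass
class FitResult:
    """Posterior summaries plus model-fit statistics for one model run."""

    summaries: pd.DataFrame  # index parameter; mean, sd, 2.5%, 50%, 97.5%
    dbar: float
    pd: float
    chains: ChainSet
    diagnostics: pd.DataFrame | None = None

    @property
    def dic(self) -> float:
        return self.dbar + self.pd


def _summary_frame(samples: dict) -> pd.DataFrame:
    rows = {}
    for name, x in samples.items():
        x = np.asarray(x).ravel()
        lo, med, hi = np.percentile(x, [2.5, 50.0, 97.5])
        rows[name] = {"mean": x.mean(), "sd": x.std(ddof=1),
                      "2.5%": lo, "50%": med, "97.5%": hi}
    return pd.DataFrame(rows).T


def summarise_fit(chains: ChainSet, derived: dict | None = None,
                  diagnostics: bool = True) -> FitResult:
    """Build a :class:`FitResult` from a chain set.

    ``derived`` maps names to per-draw arrays computed by the caller (derived
    contrasts are always computed per draw, never by differencing summaries).
    """
    samples = {n: chains.draws[:, :, i] for i, n in enumerate(chains.names)}
    if derived:
        samples.update(derived)
    summ = _summary_frame(samples)
    dbar, pd_, _ = dic(chains)
    diag = convergence_report(chains) if (diagnostics and chains.n_chains >= 2) else None
    return FitResult(summaries=summ, dbar=dbar, pd=pd_, chains=chains,
                     diagnostics=diag)
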