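"""Analysis layer: pairwise MA, NMA fits, PH Wald tests, consistency checks,
heterogeneity decomposition and treatment ranking."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ipd import Design, IPDDataset, NetworkSpec, ValidationError
from .model import ModelData, ModelSpec, PriorSpec, _loop_columns
from .sampler import ChainSet, FitResult, MCMCSettings, run_mcmc, summarise_fit

__all__ = [
    "WaldResult",
    "QDecomposition",
    "fit_pairwise_ma",
    "fit_nma",
    "wald_global_nonph",
    "separate_direct_indirect",
    "q_decomposition",
    "cox_trial_estimates",
    "rank_treatments",
    "shrinkage_intervals",
]


@dataclass(frozen=True)
class WaldResult:
    statistic: float
    df: int
    p_value: float
    parameters: tuple

    def __post_init__(self):
        if self.statistic < 0:
            raise ValueError("Wald statistic must be non-negative")


def fit_pairwise_ma(data: IPDDataset, reference: str | None = None,
                    effect: str = "fixed", interactions: str = "none",
                    priors: PriorSpec | None = None,
                    settings: MCMCSettings | None = None,
                    knots: dict | None = None) -> FitResult:
    """One-step meta-analysis of a single two-treatment comparison.

    All trials must share one design; the model stratifies the spline
    baseline by trial with a single (or random) treatment effect, and a
    treatment-ln(time) interaction when ``interactions != 'none'`` provides
    the global non-PH test for the comparison.
    """
    arms_per_trial = {tid: frozenset(data.trial(tid).df["treatment"])
                      for tid in data.trial_ids}
    designs = set(arms_per_trial.values())
    if len(designs) != 1:
        raise ValidationError(
            f"pairwise MA needs a single design, found {sorted(map(sorted, designs))}")
    arms = sorted(designs.pop())
    if len(arms) != 2:
        raise ValidationError(f"pairwise MA needs exactly two treatments, got {arms}")
    ref = reference if reference is not None else arms[0]
    if ref not in arms:
        raise ValidationError(f"reference {ref!r} is not one of the arms {arms}")
    other = next(a for a in arms if a != ref)
    network = NetworkSpec(treatments=(ref, other), reference=ref,
                          designs=(Design((ref, other), ref),))
    spec = ModelSpec(network=network, knots=knots or {}, effect=effect,
                     interactions=interactions)
    chains = run_mcmc(spec, data, priors, settings)
    return summarise_fit(chains)


def _derived_contrasts(chains: ChainSet) -> dict:
    """Per-draw derived comparisons between every non-reference treatment pair."""
    net = chains.mdata.spec.network
    if chains.mdata.spec.effect == "random":
        base = chains.stacked([f"mu[{l}]" for l in net.contrast_labels()])
    else:
        base = chains.stacked([f"beta[{l}]" for l in net.contrast_labels()])
    out = {}
    exprs = {t: net.expression(t) for t in net.treatments}
    trts = list(net.treatments)
    for i, a in enumerate(trts):
        for b in trts[i + 1:]:
            vec = exprs[b] - exprs[a]
            if np.count_nonzero(vec) > 1 or a != net.reference:
                out[f"derived[{a}:{b}]"] = base @ vec
    return out


def fit_nma(data: IPDDataset, spec: ModelSpec,
            priors: PriorSpec | None = None,
            settings: MCMCSettings | None = None) -> FitResult:
    """One-step NMA fit with derived contrasts summarised per draw."""
    _check_connected(data, spec.network)
    chains = run_mcmc(spec, data, priors, settings)
    return summarise_fit(chains, derived=_derived_contrasts(chains))


def _check_connected(data: IPDDataset, network: NetworkSpec) -> None:
    present = [frozenset(data.trial(tid).df["treatment"]) for tid in data.trial_ids]
    nodes = set().union(*present) if present else set()
    if not nodes:
        raise ValidationError("empty dataset")
    reach = {next(iter(nodes))}
    changed = True
    while changed:
        changed = False
        for s in present:
            if s & reach and not s <= reach:
                reach |= s
                changed = True
    if reach != nodes:
        raise ValidationError(
            f"network is disconnected: {sorted(nodes - reach)} unreachable")


def wald_global_nonph(fit: FitResult | ChainSet,
                      include_variance: bool = False) -> WaldResult:
    """Approximate global Wald test that all treatment-ln(time) interactions
    are simultaneously zero.

    W = m' V^-1 m with m the posterior means and V the posterior covariance
    of the interaction block (plus sigma_u when ``include_variance`` and the
    interactions are random-by-trial; testing a variance at its boundary is
    conservative).  df = size of the tested block.
    """
    chains = fit.chains if isinstance(fit, FitResult) else fit
    spec = chains.mdata.spec
    if spec.interactions == "none":
        raise ValueError("model has no treatment-ln(time) interactions to test")
    if chains.n_iter * chains.n_chains < 100:
        raise ValueError("need >= 100 draws for the Wald test")
    labels = spec.network.contrast_labels()
    names = [f"beta_int[{l}]" for l in labels]
    if include_variance:
        if spec.interactions != "random-by-trial":
            raise ValueError("include_variance requires random-by-trial interactions")
        names.append("sigma_u")
    X = chains.stacked(names)
    m = X.mean(axis=0)
    V = np.cov(X, rowvar=False).reshape(len(names), len(names))
    try:
        sol = np.linalg.solve(V, m)
    except np.linalg.LinAlgError:
        warnings.warn("singular posterior covariance; using pseudo-inverse")
        sol = np.linalg.pinv(V) @ m
    W = float(m @ sol)
    df = len(names)
    return WaldResult(statistic=W, df=df,
                      p_value=float(stats.chi2.sf(W, df)), parameters=tuple(names))


def separate_direct_indirect(data: IPDDataset, spec: ModelSpec,
                             priors: PriorSpec | None = None,
                             settings: MCMCSettings | None = None) -> pd.DataFrame:
    """Direct, indirect and network estimates for each comparison in a loop.

    Fits the model once with the loop's inconsistency parameter omega (from
    which direct and indirect evidence separate, the indirect differing from
    the direct by omega per the loop orientation) and once without it (the
    network estimate).  Returns a forest-plot-ready frame
    (comparison, source in {direct, indirect, network}, estimate, lower,
    upper) computed per draw.
    """
    if not spec.inconsistency:
        raise ValidationError("no loop: model spec carries no inconsistency loop")
    loop = tuple(spec.inconsistency[0])
    net = spec.network
    k1, k2 = _loop_columns(net, loop)
    mdata = ModelData.assemble(data, spec)
    li = list(mdata.loops).index(loop)
    if not any(np.any(td.inc[:, li] != 0.0) for td in mdata.trials):
        raise ValidationError(f"loop {loop} is not closed by the data's designs")
    chains_w = run_mcmc(mdata, priors=priors, settings=settings)
    from dataclasses import replace as _dc_replace
    spec_free = _dc_replace(spec, inconsistency=())
    chains_f = run_mcmc(spec_free, data, priors, settings)

    labels = net.contrast_labels()
    prefix = "mu" if spec.effect == "random" else "beta"
    bw = chains_w.stacked([f"{prefix}[{labels[k1]}]", f"{prefix}[{labels[k2]}]"])
    om = chains_w.stacked(["omega[" + ",".join(loop) + "]"]).ravel()
    bf = chains_f.stacked([f"{prefix}[{labels[k1]}]", f"{prefix}[{labels[k2]}]"])
    comp1, comp2 = labels[k1], labels[k2]
    a1, b1 = net.basic_contrasts[k1]
    a2, b2 = net.basic_contrasts[k2]
    comp3 = f"{b1}:{b2}"
    rows = []

    def add(comparison, source, draws):
        lo, med, hi = np.percentile(draws, [2.5, 50.0, 97.5])
        rows.append({"comparison": comparison, "source": source,
                     "estimate": float(np.mean(draws)), "lower": float(lo),
                     "upper": float(hi)})

    # the closing design directly identifies (b2 vs b1) + omega
    add(comp1, "direct", bw[:, 0])
    add(comp1, "indirect", bw[:, 0] - om)
    add(comp1, "network", bf[:, 0])
    add(comp2, "direct", bw[:, 1])
    add(comp2, "indirect", bw[:, 1] + om)
    add(comp2, "network", bf[:, 1])
    add(comp3, "direct", bw[:, 1] - bw[:, 0] + om)
    add(comp3, "indirect", bw[:, 1] - bw[:, 0])
    add(comp3, "network", bf[:, 1] - bf[:, 0])
    out = pd.DataFrame(rows)
    lo, med, hi = np.percentile(om, [2.5, 50.0, 97.5])
    out.attrs["omega"] = {"mean": float(om.mean()), "lower": float(lo),
                          "upper": float(hi), "loop": loop}
    return out


@dataclass(frozen=True)
class QDecomposition:
    """Cochran-type Q with its inconsistency/heterogeneity split.

    Q compares every trial estimate with its design's network estimate; Qinc
    compares the pooled design estimates with the network estimates; Qhet
    compares trial estimates with their own design pool.  Q = Qinc + Qhet
    holds exactly under inverse-variance pooling.
    """

    q_total: float
    q_inc: float
    q_het: float
    df_total: int
    df_inc: int
    df_het: int
    p_total: float
    p_inc: float
    p_het: float
    per_design: pd.DataFrame


def q_decomposition(trial_estimates: pd.DataFrame,
                    network_estimates: dict) -> QDecomposition:
    """Decompose Q into between-design (inconsistency) and within-design
    (heterogeneity) components.

    ``trial_estimates`` needs columns design, trial, theta, se (per-trial
    treatment effect estimates with standard errors, one comparison per
    design); ``network_estimates`` maps design -> NMA estimate of that
    design's comparison.  Degrees of freedom: df_het = sum_j (n_j - 1),
    df_inc = D - q* with D the number of designs and q* the number of basic
    parameters identified by them (graph rank of the comparisons), and
    df_total their sum.
    """
    df = trial_estimates
    need = {"design", "trial", "theta", "se"}
    if not need <= set(df.columns):
        raise ValueError(f"trial_estimates must have columns {sorted(need)}")
    if (df["se"] <= 0).any():
        raise ValueError("standard errors must be positive")
    designs = list(dict.fromkeys(df["design"]))
    for d in designs:
        if d not in network_estimates:
            raise ValueError(f"no network estimate for design {d!r}")
    q_total = q_inc = q_het = 0.0
    df_het = 0
    rows = []
    for d in designs:
        sub = df[df["design"] == d]
        w = 1.0 / sub["se"].to_numpy() ** 2
        th = sub["theta"].to_numpy()
        pooled = float(np.sum(w * th) / np.sum(w))
        pooled_var = 1.0 / float(np.sum(w))
        thN = float(network_estimates[d])
        qt = float(np.sum(w * (th - thN) ** 2))
        qh = float(np.sum(w * (th - pooled) ** 2))
        qi = (pooled - thN) ** 2 / pooled_var
        q_total += qt
        q_het += qh
        q_inc += qi
        df_het += len(sub) - 1
        rows.append({"design": d, "n_trials": len(sub), "theta_pooled": pooled,
                     "se_pooled": float(np.sqrt(pooled_var)), "theta_network": thN,
                     "q": qt, "q_het": qh, "q_inc": qi})
    # rank of the comparison graph = vertices - connected components
    edges = [tuple(str(d).split(":")) if isinstance(d, str) and ":" in str(d) else None
             for d in designs]
    if all(e is not None and len(e) == 2 for e in edges):
        nodes = {v for e in edges for v in e}
        parent = {v: v for v in nodes}

        def find(v):
            while parent[v] != v:
                parent[v] = parent[parent[v]]
                v = parent[v]
            return v

        for a, b in edges:
            parent[find(a)] = find(b)
        q_star = len(nodes) - len({find(v) for v in nodes})
    else:
        q_star = len(designs)  # conservative: each design its own parameter
    df_inc = max(len(designs) - q_star, 0)
    df_total = df_het + df_inc
    def _p(q, k):
        return float(stats.chi2.sf(q, k)) if k > 0 else float("nan")
    return QDecomposition(
        q_total=q_total, q_inc=q_inc, q_het=q_het,
        df_total=df_total, df_inc=df_inc, df_het=df_het,
        p_total=_p(q_total, df_total), p_inc=_p(q_inc, df_inc),
        p_het=_p(q_het, df_het), per_design=pd.DataFrame(rows))


def cox_trial_estimates(data: IPDDataset, network: NetworkSpec) -> pd.DataFrame:
    """Per-trial frequentist Cox estimates feeding the Q decomposition.

    Two-arm trials give one (theta, se) for their comparison; multiarm trials
    enter through their constituent non-reference-vs-reference contrasts
    (the exact multiarm covariance adjustment is not applied — a documented
    approximation).
    """
    from .diagnostics import cox_fit

    rows = []
    for tid in data.trial_ids:
        sub = data.trial(tid)
        design = network.design_for(set(sub.df["treatment"]))
        ref = design.reference
        for arm in design.treatments:
            if arm == ref:
                continue
            two = IPDDataset(sub.df[sub.df["treatment"].isin([ref, arm])]
                             .reset_index(drop=True))
            theta, se, _ = cox_fit(two, reference=ref)
            rows.append({"design": f"{ref}:{arm}", "trial": tid,
                         "theta": theta, "se": se})
    return pd.DataFrame(rows)


def network_design_estimates(fit: FitResult, network: NetworkSpec,
                             designs) -> dict:
    """Posterior-mean NMA estimate of each design's comparison.

    ``designs`` is an iterable of 'ref:arm' strings as produced by
    :func:`cox_trial_estimates`.
    """
    out = {}
    chains = fit.chains
    prefix = "mu" if chains.mdata.spec.effect == "random" else "beta"
    base = chains.stacked(
        [f"{prefix}[{l}]" for l in network.contrast_labels()])
    exprs = {t: network.expression(t) for t in network.treatments}
    for d in designs:
        a, b = str(d).split(":")
        vec = exprs[b] - exprs[a]
        out[d] = float((base @ vec).mean())
    return out


def rank_treatments(chains: ChainSet, network: NetworkSpec | None = None
                    ) -> pd.DataFrame:
    """Posterior rank percentages: per draw, rank all treatments by their
    effect vs the reference (smallest log hazard ratio = rank 1 = most
    effective) and tally.  Rows (treatments) and columns (ranks) each sum
    to 100%."""
    network = network or chains.mdata.spec.network
    prefix = "mu" if chains.mdata.spec.effect == "random" else "beta"
    base = chains.stacked([f"{prefix}[{l}]" for l in network.contrast_labels()])
    exprs = np.vstack([network.expression(t) for t in network.treatments])
    effects = base @ exprs.T  # (draws, treatments); reference column is 0
    order = np.argsort(effects, axis=1, kind="stable")
    n_draws, n_trt = effects.shape
    counts = np.zeros((n_trt, n_trt))
    for r in range(n_trt):
        idx, cnt = np.unique(order[:, r], return_counts=True)
        counts[idx, r] += cnt
    pct = 100.0 * counts / n_draws
    return pd.DataFrame(pct, index=list(network.treatments),
                        columns=[f"rank {r + 1}" for r in range(n_trt)])


def shrinkage_intervals(chains: ChainSet) -> pd.DataFrame:
    """Posterior shrinkage summaries of the per-trial PH departures u_j.

    Returns (trial, mean, sd, lower, upper) with the interval mean +/- 1.96 sd
    — the display data for the trial-level non-PH plot.
    """
    spec = chains.mdata.spec
    if spec.interactions != "random-by-trial":
        raise ValueError("shrinkage intervals need random-by-trial interactions")
    rows = []
    for td in chains.mdata.trials:
        x = chains.stacked([f"u[{td.trial_id}]"]).ravel()
        m, s = float(x.mean()), float(x.std(ddof=1))
        rows.append({"trial": td.trial_id, "mean": m, "sd": s,
                     "lower": m - 1.96 * s, "upper": m + 1.96 * s})
    return pd.DataFrame(rows)
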