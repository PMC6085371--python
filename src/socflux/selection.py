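"""Model scoring and validation: DIC, pooled weighted DIC, model likelihood,
and within/out-of-sample agreement statistics.

For each study the deviance information criterion is computed from the
posterior chain as DIC = D_bar + p_D with D_bar the posterior mean deviance
and p_D = D_bar - D(theta_bar) the effective number of parameters.  Study
DICs are pooled across a collection by weighting with the number of data
points, and models are compared through the likelihood
L = exp(-0.5 * (DIC_w - DIC_min)), selecting models with L > 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .bayes import MCMCConfig, ObservationSet, PosteriorChain, StudyDesign, run_mcmc
from .models import ModelSpec, get_model, params_valid

__all__ = [
    "DicScore",
    "EvalStats",
    "dic",
    "weighted_dic",
    "model_likelihood",
    "selected_models",
    "within_sample_eval",
    "validate_fixed",
    "validate_random",
    "model_selection_table",
]

LIKELIHOOD_THRESHOLD = 0.5


@dataclass(frozen=True)
class DicScore:
    """Per-study DIC decomposition."""

    mean_deviance: float       # D_bar
    effective_parameters: float  # p_D
    dic: float

    def __iter__(self):  # allows d_bar, p_d, dic = dic(...)
        return iter((self.mean_deviance, self.effective_parameters, self.dic))


@dataclass(frozen=True)
class EvalStats:
    """OLS agreement between modeled (x) and observed (y) values."""

    slope: float
    r_squared: float
    p_value: float
    intercept: float
    n: int


def dic(chain: PosteriorChain, obs: ObservationSet,
        model: str | ModelSpec | None = None, dt: float = 0.25) -> DicScore:
    """DIC from a posterior chain: D_bar + p_D.

    D_bar is the average of -2 log P(Z | theta) over the retained samples;
    p_D = D_bar + 2 log P(Z | theta_bar) with theta_bar the sample mean,
    whose likelihood is re-evaluated by a forward run.  theta_bar can fall
    outside the joint prior support for bounded non-convex posteriors; it is
    evaluated anyway with a warning.

    On strongly ridged posteriors the posterior-mean plugin can fall so far
    off the ridge that p_D turns negative — an impossible effective
    parameter count that would reward the most weakly identified model.  In
    that degenerate case p_D falls back to the maximum-likelihood plugin,
    D_bar - min(D), which is nonnegative by construction; a warning is
    emitted.
    """
    if chain.n_samples == 0:
        raise ValueError("empty chain")
    spec = get_model(model) if isinstance(model, str) else (model or get_model(chain.model))
    deviances = -2.0 * chain.log_likelihoods
    d_bar = float(np.mean(deviances))
    theta_bar = chain.samples.mean(axis=0)
    values = dict(zip(chain.parameter_names, theta_bar))
    if not params_valid(spec, values):
        warnings.warn(
            f"posterior mean of {spec.name} falls outside the joint prior "
            "support; DIC evaluated there regardless", stacklevel=2)
    design = StudyDesign(spec, obs.with_sd_fallback())
    ll_bar = design.log_likelihood_theta(theta_bar, dt=dt)
    p_d = d_bar + 2.0 * ll_bar
    if p_d < 0.0:
        warnings.warn(
            f"{spec.name}: posterior-mean deviance exceeds the mean deviance "
            f"(p_D = {p_d:.2f} < 0, a ridged posterior); falling back to the "
            "maximum-likelihood plugin", stacklevel=2)
        p_d = d_bar - float(np.min(deviances))
    return DicScore(mean_deviance=d_bar, effective_parameters=p_d,
                    dic=d_bar + p_d)


def weighted_dic(per_study_dic, per_study_n) -> float:
    """Pooled DIC across studies, weighted by data-point counts:
    sum(DIC_i * n_i) / sum(n_i)."""
    d = np.asarray(per_study_dic, dtype=float)
    n = np.asarray(per_study_n, dtype=float)
    if d.size == 0 or d.size != n.size:
        raise ValueError("need equal, nonzero numbers of DICs and counts")
    if np.any(n < 1):
        raise ValueError("data-point counts must be >= 1")
    return float(np.sum(d * n) / np.sum(n))


def model_likelihood(dic_w_by_model: dict) -> dict:
    """Likelihood of each model given the data, relative to the best:
    L = exp(-0.5 * (DIC_w - DIC_min)).  The minimal-DIC model gets L = 1;
    ties all get L = 1."""
    if len(dic_w_by_model) < 2:
        raise ValueError("need at least two models to compare")
    dic_min = min(dic_w_by_model.values())
    return {m: float(np.exp(-0.5 * (d - dic_min)))
            for m, d in dic_w_by_model.items()}


def selected_models(likelihoods: dict,
                    threshold: float = LIKELIHOOD_THRESHOLD) -> set:
    """Models whose likelihood given the data exceeds the threshold."""
    return {m for m, L in likelihoods.items() if L > threshold}


def within_sample_eval(modeled, observed) -> EvalStats:
    """OLS regression of observed on modeled values pooled over studies and
    series (the agreement regression plotted against the 1:1 line)."""
    x = np.asarray(modeled, dtype=float)
    y = np.asarray(observed, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 modeled/observed pairs")
    if np.ptp(x) == 0:
        raise ValueError("modeled values have zero variance")
    res = stats.linregress(x, y)
    return EvalStats(slope=float(res.slope), r_squared=float(res.rvalue ** 2),
                     p_value=float(res.pvalue), intercept=float(res.intercept),
                     n=int(x.size))


def _modeled_observed_pairs(spec: ModelSpec, values: dict,
                            obs: ObservationSet, dt: float):
    design = StudyDesign(spec, obs.with_sd_fallback())
    modeled = design.modeled_series(values, dt=dt)
    xs, ys = [], []
    for nm, x in modeled.items():
        xs.append(x)
        ys.append(obs.values(nm))
    return np.concatenate(xs), np.concatenate(ys)


def validate_fixed(train_obs: ObservationSet, validation_obs: ObservationSet,
                   model: str | ModelSpec = "interactive",
                   config: MCMCConfig | None = None,
                   chain: PosteriorChain | None = None) -> EvalStats:
    """Fixed-parameter validation: calibrate on one substrate amount, then
    predict the same soil under a different amount with the parameters held
    fixed, and regress observed on predicted.

    ``chain`` may supply an existing fit for ``train_obs``; otherwise the
    model is calibrated here.
    """
    spec = model if isinstance(model, ModelSpec) else get_model(model)
    if abs(train_obs.soc - validation_obs.soc) > 1e-6 * max(train_obs.soc, 1.0):
        raise ValueError("fixed-mode validation requires the same soil "
                         "(equal SOC stock)")
    if abs(train_obs.added_c - validation_obs.added_c) < 1e-12:
        raise ValueError("fixed-mode validation requires a different "
                         "added-C amount")
    if chain is None:
        chain = run_mcmc(spec, train_obs, config or MCMCConfig())
    dt = (config or MCMCConfig()).dt
    x, y = _modeled_observed_pairs(spec, chain.mle, validation_obs, dt)
    return within_sample_eval(x, y)


def stratified_split(collection: list, split_seed: int,
                     n_strata: int = 4) -> tuple[list, list]:
    """Random half-split of studies stratified by added-C fraction quartile.

    Falls back to a simple random split (with a warning) when the collection
    is too small to stratify.
    """
    rng = np.random.default_rng(split_seed)
    if len(collection) < 4:
        raise ValueError("need at least 4 studies to split")
    fracs = np.array([o.added_fraction for o in collection])
    if len(collection) < 2 * n_strata:
        warnings.warn("too few studies to stratify; using a simple random "
                      "split", stacklevel=2)
        order = rng.permutation(len(collection))
        half = len(collection) // 2
        return ([collection[i] for i in order[:half]],
                [collection[i] for i in order[half:]])
    edges = np.quantile(fracs, np.linspace(0, 1, n_strata + 1))
    strata = np.clip(np.searchsorted(edges, fracs, side="right") - 1,
                     0, n_strata - 1)
    g1, g2 = [], []
    for s in range(n_strata):
        idx = np.flatnonzero(strata == s)
        idx = idx[rng.permutation(idx.size)]
        half = idx.size // 2
        g1.extend(collection[i] for i in idx[:half])
        g2.extend(collection[i] for i in idx[half:])
    return g1, g2


def validate_random(collection: list, split_seed: int,
                    model: str | ModelSpec = "interactive",
                    config: MCMCConfig | None = None) -> EvalStats:
    """Random-mode validation: half the studies (stratified by added-C
    fraction) tune the prior settings, the other half are then fitted under
    those settings and their fitted predictions regressed on observations.

    The models are study-specific, so "training" fixes hyper-settings — the
    prior boxes are narrowed to the envelope of the training-group point
    estimates (widened 2x each way) — rather than parameter values.
    """
    spec = model if isinstance(model, ModelSpec) else get_model(model)
    config = config or MCMCConfig()
    g1, g2 = stratified_split(collection, split_seed)
    mles = []
    for obs in g1:
        ch = run_mcmc(spec, obs, config)
        mles.append([ch.mle[n] for n in spec.parameter_names])
    mles = np.array(mles)
    tuned = {}
    for j, name in enumerate(spec.parameter_names):
        lo0, hi0 = spec.parameter_bounds[name]
        tuned[name] = (max(lo0, mles[:, j].min() / 2.0),
                       min(hi0, mles[:, j].max() * 2.0))
    cfg2 = MCMCConfig(n_iterations=config.n_iterations,
                      step_divisor=config.step_divisor,
                      burn_in_fraction=config.burn_in_fraction,
                      adapt_interval=config.adapt_interval,
                      n_init_draws=config.n_init_draws,
                      anneal_temperature=config.anneal_temperature,
                      seed=config.seed, dt=config.dt, bounds=tuned)
    xs, ys = [], []
    for obs in g2:
        ch = run_mcmc(spec, obs, cfg2)
        x, y = _modeled_observed_pairs(spec, ch.mle, obs, config.dt)
        xs.append(x)
        ys.append(y)
    return within_sample_eval(np.concatenate(xs), np.concatenate(ys))


def model_selection_table(studies: list, chains: dict,
                          dt: float = 0.25) -> pd.DataFrame:
    """Pooled comparison table across models (one row per model): number of
    parameters, agreement regression (slope, R^2, P), weighted DIC and model
    likelihood.

    ``chains`` maps model name -> {study_id -> PosteriorChain}.
    """
    by_id = {o.study_id: o for o in studies}
    rows = {}
    dicw = {}
    for model_name, per_study in chains.items():
        spec = get_model(model_name)
        dics, ns, xs, ys = [], [], [], []
        for sid, ch in per_study.items():
            obs = by_id[sid]
            dics.append(dic(ch, obs, spec, dt=dt).dic)
            ns.append(obs.n_points)
            x, y = _modeled_observed_pairs(spec, ch.mle, obs, dt)
            xs.append(x)
            ys.append(y)
        ev = within_sample_eval(np.concatenate(xs), np.concatenate(ys))
        dicw[model_name] = weighted_dic(dics, ns)
        rows[model_name] = {
            "model": model_name,
            "n_parameters": spec.n_parameters,
            "slope": ev.slope, "r_squared": ev.r_squared,
            "p_value": ev.p_value, "dic_w": dicw[model_name],
        }
    lmap = model_likelihood(dicw) if len(dicw) >= 2 else {m: 1.0 for m in dicw}
    for m in rows:
        rows[m]["likelihood"] = lmap[m]
        rows[m]["selected"] = lmap[m] > LIKELIHOOD_THRESHOLD
    return pd.DataFrame(list(rows.values())).set_index("model")
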