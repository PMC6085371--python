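"""Self-contained synthetic-collection experiments.

These are the package's end-to-end checks with known ground truth: fit
synthetic collections generated by the interactive model and measure (i)
how well the pooled weighted-mean net SOC change recovers the generator
truth, (ii) how often DIC-based selection identifies the generating model
among the four candidates, and (iii) the frequentist coverage of the 95%
posterior intervals.  They are used by the acceptance tests and the
acceptance script; problem sizes are arguments so callers choose their
scale.
"""

from __future__ import annotations

import warnings

import numpy as np

from .bayes import MCMCConfig, run_mcmc
from .fluxes import fluxes_for_params, standardized_summary
from .models import MODEL_NAMES
from .selection import dic, weighted_dic
from .synthesis import EffectSize, weighted_mean_ci
from .synthetic import SynthConfig, generate_collection

__all__ = ["net_change_recovery", "selection_race", "coverage_experiment"]


def net_change_recovery(n_studies: int = 20, n_iterations: int = 10_000,
                        noise_cv: float = 0.0, seed: int = 1,
                        horizon_days: float = 365.0,
                        max_posterior_samples: int = 200) -> dict:
    """Fit every study of a synthetic collection and compare the pooled
    weighted-mean net change (% of added C, one-year horizon) against the
    generator truth pooled with the same weights.

    Returns the fitted chains as well, so callers can reuse them (e.g. for
    the scenario synthesis) without refitting.
    """
    rng = np.random.default_rng(seed)
    studies = generate_collection(SynthConfig(
        n_studies=n_studies, noise_cv=noise_cv,
        seed=int(rng.integers(2**31 - 1))))
    effects, true_nets, weights, chains = [], [], [], {}
    for s in studies:
        obs = s.observations
        chain = run_mcmc("interactive", obs, MCMCConfig(
            n_iterations=n_iterations, seed=int(rng.integers(2**31 - 1))))
        chains[obs.study_id] = (chain, obs, s.true_params)
        fs = standardized_summary(chain, "interactive", obs,
                                  horizon_days=horizon_days,
                                  max_samples=max_posterior_samples,
                                  seed=int(rng.integers(2**31 - 1)))
        eff = EffectSize.from_posterior(
            obs.study_id, "net", fs.mean("net"),
            max(fs.percent_sd["net"], 1e-9), obs.n_replicates,
            obs.nc_category)
        effects.append(eff)
        weights.append(eff.weight)
        true_nets.append(fluxes_for_params(
            "interactive", s.true_params, obs.soc, obs.added_c,
            horizon_days=horizon_days)["net_pct"])
    pooled = weighted_mean_ci(effects)
    w = np.asarray(weights)
    truth_pooled = float(np.sum(w * np.asarray(true_nets)) / np.sum(w))
    return {
        "n_studies": n_studies,
        "estimate": pooled.mean,
        "ci": (pooled.ci_low, pooled.ci_high),
        "truth": truth_pooled,
        "abs_error": abs(pooled.mean - truth_pooled),
        "effects": effects,
        "chains": chains,
    }


def selection_race(n_runs: int = 10, n_studies: int = 6,
                   n_iterations: int = 4000, noise_cv: float = 0.05,
                   seed: int = 1) -> dict:
    """Generate collections from the interactive model and let the four
    models compete on pooled weighted DIC; returns the fraction of runs the
    interactive model attains the minimum."""
    rng = np.random.default_rng(seed)
    wins = 0
    winners = []
    for _ in range(n_runs):
        studies = generate_collection(SynthConfig(
            n_studies=n_studies, noise_cv=noise_cv,
            seed=int(rng.integers(2**31 - 1))))
        dicw = {}
        for model in MODEL_NAMES:
            dics, ns = [], []
            for s in studies:
                obs = s.observations
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        chain = run_mcmc(model, obs, MCMCConfig(
                            n_iterations=n_iterations,
                            seed=int(rng.integers(2**31 - 1))))
                        dics.append(dic(chain, obs, model).dic)
                except Exception:
                    dics.append(1e6)  # a model that cannot fit loses
                ns.append(obs.n_points)
            dicw[model] = weighted_dic(dics, ns)
        best = min(dicw, key=dicw.get)
        winners.append(best)
        wins += best == "interactive"
    return {"n_runs": n_runs, "n_studies": n_studies,
            "fraction_interactive_best": wins / n_runs, "winners": winners}


def coverage_experiment(n_replicates: int = 20, n_iterations: int = 10_000,
                        noise_cv: float = 0.05, seed: int = 1) -> dict:
    """Per-parameter frequentist coverage of the 95% posterior intervals
    over seeded single-study replicates with 5% observation noise."""
    rng = np.random.default_rng(seed)
    names = None
    hits = None
    for _ in range(n_replicates):
        s = generate_collection(SynthConfig(
            n_studies=1, noise_cv=noise_cv,
            seed=int(rng.integers(2**31 - 1))))[0]
        chain = run_mcmc("interactive", s.observations, MCMCConfig(
            n_iterations=n_iterations, seed=int(rng.integers(2**31 - 1))))
        iv = chain.interval(0.95)
        if names is None:
            names = list(chain.parameter_names)
            hits = {n: 0 for n in names}
        for n in names:
            lo, hi = iv[n]
            hits[n] += lo <= s.true_params[n] <= hi
    coverage = {n: hits[n] / n_replicates for n in names}
    return {"n_replicates": n_replicates, "coverage": coverage,
            "min_coverage": min(coverage.values())}
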