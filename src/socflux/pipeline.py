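"""End-to-end driver: synthetic data (or a study directory) -> per-study
fits -> model selection -> standardized fluxes -> synthesis -> scenario
experiment, with every artifact written as CSV under one output directory.

All randomness flows from the single configured master seed.  A failing
study is recorded and skipped; the run then reports partial failure instead
of aborting.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bayes import MCMCConfig, run_mcmc
from .fluxes import standardized_summary
from .io import load_collection, save_collection
from .models import MODEL_NAMES
from .scenarios import Scenario, experiment_synthesis
from .selection import model_selection_table
from .synthesis import EffectSize, group_synthesis, synthesis_frame, weighted_mean_ci
from .synthetic import SynthConfig, generate_collection

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger("socflux")

FLUX_METRICS = ("replenishment", "priming", "net")


@dataclass
class PipelineConfig:
    """Structured configuration for one pipeline run."""

    input_dir: str | None = None        # read studies from here if given,
    n_studies: int = 6                  # ...else generate this many
    noise_cv: float = 0.05
    models: tuple[str, ...] = MODEL_NAMES
    n_iterations: int = 10_000
    horizon_days: float = 365.0
    scenarios: tuple[str, ...] = ("step", "gradual")
    seed: int = 0
    dt_fit: float = 0.25
    max_posterior_samples: int = 200

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("models", "scenarios"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["models"] = list(self.models)
        d["scenarios"] = list(self.scenarios)
        return d


@dataclass
class PipelineResult:
    out_dir: Path
    tables: dict = field(default_factory=dict)
    failures: dict = field(default_factory=dict)
    chains: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.failures


def _fit_all(studies, config: PipelineConfig, rng: np.random.Generator,
             failures: dict) -> dict:
    """{model: {study_id: chain}}; per-study seeds drawn from the master rng."""
    chains: dict = {m: {} for m in config.models}
    for obs in studies:
        for model in config.models:
            seed = int(rng.integers(0, 2**31 - 1))
            t0 = time.perf_counter()
            try:
                ch = run_mcmc(model, obs, MCMCConfig(
                    n_iterations=config.n_iterations, seed=seed,
                    dt=config.dt_fit))
            except Exception as exc:  # record and continue with the rest
                failures[f"fit/{model}/{obs.study_id}"] = str(exc)
                log.warning("fit failed for %s under %s: %s",
                            obs.study_id, model, exc)
                continue
            chains[model][obs.study_id] = ch
            log.info("fit %s under %s: %.1fs, acceptance %.2f",
                     obs.study_id, model, time.perf_counter() - t0,
                     ch.acceptance_rate)
    return chains


def run_pipeline(config: PipelineConfig, out_dir) -> PipelineResult:
    """Run every stage and write the report tables; see the module docstring."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = PipelineResult(out_dir=out)
    rng = np.random.default_rng(config.seed)

    # --- studies ---------------------------------------------------------
    if config.input_dir:
        studies = load_collection(config.input_dir)
    else:
        synth = generate_collection(SynthConfig(
            n_studies=config.n_studies, noise_cv=config.noise_cv,
            seed=config.seed))
        save_collection(synth, out / "studies")
        studies = [s.observations for s in synth]

    # --- per-study fits --------------------------------------------------
    chains = _fit_all(studies, config, rng, result.failures)
    result.chains = chains
    chain_dir = out / "chains"
    for model, per_study in chains.items():
        (chain_dir / model).mkdir(parents=True, exist_ok=True)
        for sid, ch in per_study.items():
            ch.to_csv(chain_dir / model / f"{sid}.csv")

    # --- model selection -------------------------------------------------
    fitted_models = [m for m in config.models if chains[m]]
    if len(fitted_models) >= 2:
        sel = model_selection_table(
            studies, {m: chains[m] for m in fitted_models}, dt=config.dt_fit)
        sel.to_csv(out / "model_selection.csv")
        result.tables["model_selection"] = sel
        best_model = sel["dic_w"].idxmin()
    else:
        best_model = fitted_models[0] if fitted_models else None
    if best_model is None:
        result.failures["select"] = "no model produced any fit"
        return result

    # --- standardized fluxes (best model) --------------------------------
    by_id = {o.study_id: o for o in studies}
    flux_frames, effects = [], {m: [] for m in FLUX_METRICS}
    for sid, ch in chains[best_model].items():
        obs = by_id[sid]
        try:
            fs = standardized_summary(
                ch, best_model, obs, horizon_days=config.horizon_days,
                max_samples=config.max_posterior_samples, dt=config.dt_fit,
                seed=config.seed)
        except Exception as exc:
            result.failures[f"fluxes/{sid}"] = str(exc)
            continue
        flux_frames.append(fs.to_frame())
        for metric in FLUX_METRICS:
            effects[metric].append(EffectSize.from_posterior(
                sid, metric, fs.mean(metric),
                max(fs.percent_sd[metric], 1e-9), n=obs.n_replicates,
                nc_category=obs.nc_category))
    if flux_frames:
        fluxes = pd.concat(flux_frames, ignore_index=True)
        fluxes.to_csv(out / "fluxes.csv", index=False)
        result.tables["fluxes"] = fluxes

    # --- synthesis -------------------------------------------------------
    synth_rows = {}
    group_frames = []
    for metric, es in effects.items():
        if not es:
            continue
        synth_rows[metric] = weighted_mean_ci(es)
        per_group, _ = group_synthesis(es)
        gf = synthesis_frame(per_group)
        gf.insert(0, "metric", metric)
        group_frames.append(gf)
    if synth_rows:
        overall = synthesis_frame(synth_rows).rename(columns={"group": "metric"})
        overall.to_csv(out / "synthesis.csv", index=False)
        result.tables["synthesis"] = overall
    if group_frames:
        grouped = pd.concat(group_frames, ignore_index=True)
        grouped.to_csv(out / "synthesis_by_category.csv", index=False)
        result.tables["synthesis_by_category"] = grouped

    # --- scenario experiment (interactive fits only) ----------------------
    if "interactive" in chains and chains["interactive"] and config.scenarios:
        fitted = [(sid, ch, by_id[sid].nc_category, by_id[sid].n_replicates)
                  for sid, ch in chains["interactive"].items()]
        rows = []
        for kind in config.scenarios:
            try:
                res, es = experiment_synthesis(
                    fitted, Scenario(kind=kind),
                    max_samples=min(config.max_posterior_samples, 100),
                    dt=config.dt_fit, seed=config.seed)
            except Exception as exc:
                result.failures[f"scenario/{kind}"] = str(exc)
                continue
            rows.append({"scenario": kind, **res.to_dict()})
        if rows:
            scen = pd.DataFrame(rows)
            scen.to_csv(out / "scenario_synthesis.csv", index=False)
            result.tables["scenario_synthesis"] = scen

    # --- manifest --------------------------------------------------------
    with open(out / "manifest.json", "w") as fh:
        json.dump({
            "socflux_version": __version__,
            "config": config.to_dict(),
            "best_model": best_model,
            "n_studies": len(studies),
            "failures": result.failures,
        }, fh, indent=2, sort_keys=True)
    return result
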