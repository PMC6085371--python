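"""Synthetic incubation-study generator with known ground truth.

Emulates the statistical structure of the collected isotope-labeling
incubations: a one-time labeled-C addition at t=0 amounting to (mostly)
under 10% of the SOC stock, at least three observation times spanning at
least 28 days, three cumulative-CO2 series with reported SDs, and substrate
N:C categories {none, low, high} whose effect is embedded as known truth —
the replenishment coefficient r rises and the priming coefficient K_p falls
with increasing substrate N:C, so the category ordering of the true net SOC
change (high > low > none) is available for recovery tests.

Noise is applied multiplicatively to the *increments* of each cumulative
series (then re-accumulated), which preserves monotonicity without the
upward bias that noising-then-sorting cumulative values would introduce.
The emitted series is the mean of ``n_replicates`` jars (increment noise
CV/sqrt(R)); the SD column is the across-replicate SD of a single jar's
cumulative value, floored at 1% of the added C — the mean +/- SD convention
of published incubation tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bayes import ObservationSet
from .models import validate_params

__all__ = ["SynthConfig", "SyntheticStudy", "generate_study",
           "generate_collection"]

# true-parameter sampling ranges for the interactive generator; interior of
# the fitting priors, at magnitudes typical of incubation studies
# (substrate turnover of weeks, old SOC of years)
_BASE_RANGES = {
    "K_N": (0.02, 0.08),       # d^-1
    "K_O": (5e-5, 5e-4),       # d^-1
    "p": (0.8, 1.2),
    "f_N": (0.005, 0.02),
}
# r rises and c_p (priming strength; K_p = c_p / SOC) falls with N:C class
_R_BY_CATEGORY = {"none": (0.30, 0.40), "low": (0.40, 0.50),
                  "high": (0.50, 0.60)}
_CP_BY_CATEGORY = {"none": (3e-3, 6e-3), "low": (1.5e-3, 3e-3),
                   "high": (5e-4, 1.5e-3)}


@dataclass
class SynthConfig:
    """Generator settings; the defaults are the study conditions every
    pipeline test assumes."""

    n_studies: int = 20
    model: str = "interactive"
    noise_cv: float = 0.05
    seed: int = 0
    obs_interval_d: float = 7.0
    duration_d: float = 70.0
    soc_range: tuple[float, float] = (5.0, 30.0)   # mg C g^-1 soil
    # added C as a fraction of SOC: with prob. 3/4 a draw below 8%, else up
    # to 20%, so over two-thirds of studies sit under 10% of the stock
    added_frac_major: tuple[float, float] = (0.01, 0.08)
    added_frac_minor: tuple[float, float] = (0.08, 0.20)
    major_prob: float = 0.75
    category_mix: dict = field(default_factory=lambda: {
        "none": 1 / 3, "low": 1 / 3, "high": 1 / 3})
    n_replicates: int = 3

    def __post_init__(self):
        if self.n_studies < 1:
            raise ValueError("need at least one study")
        if self.noise_cv < 0:
            raise ValueError("noise CV must be nonnegative")
        if self.duration_d < 28.0:
            raise ValueError("incubations must span at least 28 days "
                             "(selection criterion)")
        if self.duration_d / self.obs_interval_d < 3:
            raise ValueError("need at least 3 observation times "
                             "(selection criterion)")
        if self.model != "interactive":
            raise NotImplementedError("the generator currently embeds truth "
                                      "for the interactive model only")
        s = sum(self.category_mix.values())
        if abs(s - 1.0) > 1e-9:
            raise ValueError("category mix must sum to 1")


@dataclass
class SyntheticStudy:
    """One generated study: observations plus its generating truth."""

    observations: ObservationSet
    true_params: dict[str, float]
    seed: int


def _draw_true_params(rng: np.random.Generator, category: str,
                      soc: float) -> dict[str, float]:
    p = {k: float(rng.uniform(*rg)) for k, rg in _BASE_RANGES.items()}
    p["r"] = float(rng.uniform(*_R_BY_CATEGORY[category]))
    c_p = rng.uniform(*_CP_BY_CATEGORY[category])
    p["K_p"] = float(c_p / soc)   # priming % of added roughly SOC-independent
    validate_params("interactive", p)
    return p


def generate_study(config: SynthConfig, rng: np.random.Generator,
                   study_id: str = "synth-1",
                   category: str | None = None) -> SyntheticStudy:
    """Generate one study: draw truth, simulate the paired incubation, noise
    the increments, and package a validated ObservationSet."""
    from .bayes import StudyDesign  # local import to avoid cycle at import time

    if category is None:
        cats = list(config.category_mix)
        category = cats[rng.choice(len(cats),
                                   p=list(config.category_mix.values()))]
    soc = float(rng.uniform(*config.soc_range))
    major = rng.random() < config.major_prob
    frac = float(rng.uniform(*(config.added_frac_major if major
                               else config.added_frac_minor)))
    added = frac * soc
    truth = _draw_true_params(rng, category, soc)

    times = np.arange(config.obs_interval_d, config.duration_d + 1e-9,
                      config.obs_interval_d)
    shell = ObservationSet(study_id, soc=soc, added_c=added,
                           nc_category=category,
                           n_replicates=config.n_replicates,
                           series={nm: np.c_[times, np.zeros_like(times),
                                             np.ones_like(times)]
                                   for nm in ("old_control", "old_treatment",
                                              "new_treatment")})
    design = StudyDesign("interactive", shell)
    clean = design.modeled_series(truth, dt=0.05)
    series = {}
    # the reported series is the mean of n_replicates jars, each with
    # multiplicative increment-level noise of CV noise_cv; the SD column is
    # the across-replicate SD of a single jar's cumulative value (increment
    # variances accumulate), floored at 1% of the added C — the convention
    # of published incubation tables (mean +/- SD over replicates)
    cv_mean = config.noise_cv / np.sqrt(max(config.n_replicates, 1))
    for nm, z in clean.items():
        inc = np.diff(z, prepend=0.0)
        noisy = np.maximum(
            inc * (1.0 + cv_mean * rng.standard_normal(inc.size)), 0.0)
        zn = np.cumsum(noisy) if config.noise_cv > 0 else z
        sd = np.maximum(config.noise_cv * np.sqrt(np.cumsum(inc ** 2)),
                        0.01 * added)
        series[nm] = np.c_[times, zn, sd]
    obs = ObservationSet(study_id, soc=soc, added_c=added,
                         nc_category=category,
                         n_replicates=config.n_replicates, series=series)
    problems = obs.criteria_violations()
    if problems:   # the design above should make this unreachable
        raise ValueError(f"generated study violates selection criteria: "
                         + "; ".join(problems))
    return SyntheticStudy(observations=obs, true_params=truth,
                          seed=int(rng.integers(0, 2**31 - 1)))


def generate_collection(config: SynthConfig) -> list[SyntheticStudy]:
    """Reproducibly generate ``config.n_studies`` studies.

    Per-study generators are spawned from the master seed, so the i-th study
    is identical no matter how many studies are requested.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_studies)
    studies = []
    for i, child in enumerate(children):
        # each study draws everything (incl. its N:C category, with the
        # configured mix as probabilities) from its own spawned generator,
        # so study i is independent of how many studies are requested
        rng = np.random.default_rng(child)
        studies.append(generate_study(config, rng,
                                      study_id=f"synth-{i + 1:03d}"))
    return studies


def manifest(studies: list[SyntheticStudy], config: SynthConfig) -> dict:
    """JSON-serializable record of seeds and truths for test assertions."""
    return {
        "config": {
            "n_studies": config.n_studies, "model": config.model,
            "noise_cv": config.noise_cv, "seed": config.seed,
            "duration_d": config.duration_d,
            "obs_interval_d": config.obs_interval_d,
        },
        "studies": {
            s.observations.study_id: {
                "soc": s.observations.soc,
                "added_c": s.observations.added_c,
                "nc_category": s.observations.nc_category,
                "n_replicates": s.observations.n_replicates,
                "true_params": s.true_params,
            } for s in studies
        },
    }
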