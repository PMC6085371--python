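"""Bayesian calibration of a decomposition model to one incubation study.

Each study supplies three cumulative-CO2 series (mg C g^-1 soil): emission
from old SOC in the control jar, from old SOC under substrate addition, and
from the added labeled substrate.  The likelihood is Gaussian in the
cumulative values with the reported measurement SDs; priors are independent
uniforms over the parameter bounds, so the Metropolis acceptance ratio
reduces to the likelihood ratio.

The sampler is an adaptive Metropolis scheme: the walk starts from a
maximum-a-posteriori point located by screening prior draws and polishing
the best with a derivative-free simplex search; proposals are multivariate
Gaussian steps whose covariance is refreshed from the accumulated burn-in
history and whose global scale is tuned to keep acceptance between 0.2 and
0.5, with reflection at the prior bounds.  All adaptation happens during
burn-in only and is frozen afterwards, so the retained (post-burn-in) chain
is a valid Metropolis sample.  The classical uniform-window proposal
(theta_new = theta_old + d * (max - min) / D) is exposed as :func:`propose`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernels
from .models import ModelSpec, get_model

__all__ = [
    "SERIES_NAMES",
    "ObservationSet",
    "MCMCConfig",
    "PosteriorChain",
    "ChainDiagnosticError",
    "log_likelihood",
    "propose",
    "run_mcmc",
    "posterior_predictive",
    "StudyDesign",
]

SERIES_NAMES = ("old_control", "old_treatment", "new_treatment")

MIN_DURATION_D = 28.0
MIN_POINTS = 3


class ChainDiagnosticError(RuntimeError):
    """The sampler could not reach a workable acceptance rate."""


@dataclass
class ObservationSet:
    """One study's observed cumulative CO2 emission series plus metadata.

    ``series`` maps each of :data:`SERIES_NAMES` to an (n, 3) array of
    (time_d, cumulative mean, SD), all in mg C g^-1 soil.
    """

    study_id: str
    soc: float                      # initial SOC stock, mg C g^-1 soil
    added_c: float                  # one-time substrate addition, mg C g^-1 soil
    nc_category: str = "none"       # substrate N:C class: none | low | high
    n_replicates: int = 3
    series: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        if self.nc_category not in ("none", "low", "high"):
            raise ValueError(f"unknown N:C category {self.nc_category!r}")
        if self.soc <= 0:
            raise ValueError("SOC must be positive")
        if self.added_c < 0:
            raise ValueError("added C must be nonnegative")
        clean = {}
        for name, arr in self.series.items():
            if name not in SERIES_NAMES:
                raise ValueError(f"unknown series {name!r}")
            arr = np.atleast_2d(np.asarray(arr, dtype=float))
            if arr.shape[1] != 3:
                raise ValueError("each series needs columns (time_d, mean, sd)")
            clean[name] = arr[np.argsort(arr[:, 0])]
        self.series = clean

    def times(self, name: str) -> np.ndarray:
        return self.series[name][:, 0]

    def values(self, name: str) -> np.ndarray:
        return self.series[name][:, 1]

    def sds(self, name: str) -> np.ndarray:
        return self.series[name][:, 2]

    @property
    def n_points(self) -> int:
        return sum(arr.shape[0] for arr in self.series.values())

    @property
    def added_fraction(self) -> float:
        """Added C as a fraction of the SOC stock."""
        return self.added_c / self.soc

    def criteria_violations(self) -> list[str]:
        """Check against the study-selection rules: control + labeled-addition
        treatments present; > 2 time points per series; span >= 28 days; and
        basic data sanity (increasing times, nondecreasing cumulative values,
        positive SDs)."""
        out = []
        for name in SERIES_NAMES:
            if name not in self.series:
                out.append(f"missing series {name!r} (control and labeled "
                           "addition treatments are both required)")
                continue
            arr = self.series[name]
            t, z, sd = arr[:, 0], arr[:, 1], arr[:, 2]
            if arr.shape[0] < MIN_POINTS:
                out.append(f"{name}: needs more than 2 time points, "
                           f"got {arr.shape[0]}")
            if t.size and t[-1] < MIN_DURATION_D:
                out.append(f"{name}: minimum duration not met "
                           f"(last observation at day {t[-1]:g} < 28)")
            if np.any(np.diff(t) <= 0):
                out.append(f"{name}: observation times not strictly increasing")
            if np.any(np.diff(z) < 0):
                out.append(f"{name}: cumulative emission decreases")
            finite_sd = sd[np.isfinite(sd)]
            if np.any(finite_sd < 0):
                out.append(f"{name}: negative SD")
        return out

    def with_sd_fallback(self) -> "ObservationSet":
        """Replace missing/zero SDs with max(5% of the mean, 1% of added C)."""
        patched = {}
        warned = False
        for name, arr in self.series.items():
            arr = arr.copy()
            sd = arr[:, 2]
            bad = ~np.isfinite(sd) | (sd <= 0)
            if np.any(bad):
                floor = np.maximum(0.05 * arr[:, 1], 0.01 * max(self.added_c, 1e-12))
                arr[bad, 2] = floor[bad]
                warned = True
            patched[name] = arr
        if warned:
            warnings.warn(
                f"study {self.study_id}: missing or zero SDs replaced by "
                "max(5% of mean, 1% of added C)", stacklevel=2)
        return replace(self, series=patched)


@dataclass
class MCMCConfig:
    """Sampler settings.  ``n_iterations`` is the total chain length; the
    first ``burn_in_fraction`` is discarded and is the only phase in which
    the proposal is adapted.  ``step_divisor`` sets the initial proposal
    widths as (upper - lower) / D before covariance adaptation takes over."""

    n_iterations: int = 50_000
    step_divisor: float = 5.0
    burn_in_fraction: float = 0.5
    adapt_interval: int = 250
    n_init_draws: int = 512  # prior draws screened for the starting point
    anneal_temperature: float = 1.0  # burn-in start temperature (1 = none)
    seed: int = 0
    dt: float = 0.25    # RK4 step for likelihood evaluations, day
    bounds: dict[str, tuple[float, float]] | None = None  # override priors

    def __post_init__(self):
        if self.n_iterations < 1000:
            raise ValueError("n_iterations must be at least 1000")
        if self.step_divisor <= 0:
            raise ValueError("step_divisor must be positive")
        if not 0.0 < self.burn_in_fraction < 1.0:
            raise ValueError("burn_in_fraction must be in (0, 1)")


@dataclass
class PosteriorChain:
    """Post-burn-in Metropolis samples for one study and model."""

    model: str
    parameter_names: tuple[str, ...]
    samples: np.ndarray             # (n_retained, k)
    log_likelihoods: np.ndarray     # (n_retained,)
    acceptance_rate: float          # over the full chain
    proposal_widths: np.ndarray     # frozen per-parameter widths after burn-in
    seed: int

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def mle(self) -> dict[str, float]:
        """Retained sample with the largest likelihood (the point estimate)."""
        i = int(np.argmax(self.log_likelihoods))
        return dict(zip(self.parameter_names, self.samples[i]))

    @property
    def mle_log_likelihood(self) -> float:
        return float(np.max(self.log_likelihoods))

    def mean(self) -> dict[str, float]:
        return dict(zip(self.parameter_names, self.samples.mean(axis=0)))

    def interval(self, level: float = 0.95) -> dict[str, tuple[float, float]]:
        a = 100 * (1 - level) / 2
        lo = np.percentile(self.samples, a, axis=0)
        hi = np.percentile(self.samples, 100 - a, axis=0)
        return {n: (float(l), float(h))
                for n, l, h in zip(self.parameter_names, lo, hi)}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.samples, columns=list(self.parameter_names))
        df["log_likelihood"] = self.log_likelihoods
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, model: str) -> "PosteriorChain":
        df = pd.read_csv(path)
        names = tuple(c for c in df.columns if c != "log_likelihood")
        return cls(model=model, parameter_names=names,
                   samples=df[list(names)].to_numpy(float),
                   log_likelihoods=df["log_likelihood"].to_numpy(float),
                   acceptance_rate=float("nan"),
                   proposal_widths=np.full(len(names), np.nan), seed=-1)


class StudyDesign:
    """Precompiled mapping from a parameter vector to the modeled series.

    Encodes one study's geometry for the compiled likelihood: the union
    observation-time grid, per-point (condition, CO2 ledger, time) indices,
    the affine initial-state map y0 = b + A theta (the initial-fraction
    parameters enter linearly through the SOC partition), and the selection
    of theta coordinates forming each condition's kernel parameters.
    """

    def __init__(self, model: str | ModelSpec, obs: ObservationSet,
                 extra_times=None):
        spec = model if isinstance(model, ModelSpec) else get_model(model)
        self.spec = spec
        self.obs = obs
        names = spec.parameter_names
        k = len(names)
        nc = len(spec.compartments)
        ns = 2 * nc + 2

        def idx(*keys):
            return np.array([names.index(x) for x in keys], dtype=np.int64)

        if spec.name == "conventional":
            self.ctl_sel = idx("K_N", "K_L_ctl", "K_R_ctl", "a_LN", "a_RN",
                               "a_LR_ctl", "a_RL_ctl")
            self.trt_sel = idx("K_N", "K_L_trt", "K_R_trt", "a_LN", "a_RN",
                               "a_LR_trt", "a_RL_trt")
            self.constraints = np.array([[names.index("a_LN"),
                                          names.index("a_RN")]], dtype=np.int64)
        elif spec.name == "interactive":
            self.ctl_sel = self.trt_sel = idx("K_N", "K_O", "r", "K_p", "p")
            self.constraints = np.empty((0, 2), dtype=np.int64)
        elif spec.name == "michaelis_menten":
            self.ctl_sel = self.trt_sel = idx("V_N", "V_O", "K_N", "K_O",
                                              "mu_B", "eps")
            self.constraints = np.array([[names.index("f_N"),
                                          names.index("f_B")]], dtype=np.int64)
        else:
            self.ctl_sel = self.trt_sel = idx("mu_N", "mu_O", "mu_B", "K_B",
                                              "eps")
            self.constraints = np.array([[names.index("f_N"),
                                          names.index("f_B")]], dtype=np.int64)

        # affine initial state: native SOC partitioned by initial fractions,
        # labeled substrate in the new pool of the treatment run
        soc, added = obs.soc, obs.added_c
        b_ctl = np.zeros(ns)
        A_ctl = np.zeros((ns, k))
        if spec.name == "conventional":
            # unlabeled L = f_L*soc, R = (1 - f_L)*soc
            A_ctl[nc + 1, names.index("f_L")] = soc
            b_ctl[nc + 2] = soc
            A_ctl[nc + 2, names.index("f_L")] = -soc
        elif spec.name == "interactive":
            A_ctl[nc + 0, names.index("f_N")] = soc
            b_ctl[nc + 1] = soc
            A_ctl[nc + 1, names.index("f_N")] = -soc
        else:
            A_ctl[nc + 0, names.index("f_N")] = soc
            b_ctl[nc + 1] = soc
            A_ctl[nc + 1, names.index("f_N")] = -soc
            A_ctl[nc + 1, names.index("f_B")] = -soc
            A_ctl[nc + 2, names.index("f_B")] = soc
        b_trt = b_ctl.copy()
        A_trt = A_ctl.copy()
        b_trt[0] += added

        self.b_ctl, self.A_ctl = b_ctl, A_ctl
        self.b_trt, self.A_trt = b_trt, A_trt

        # observation-point bookkeeping on the union time grid
        all_t = [obs.times(nm) for nm in SERIES_NAMES if nm in obs.series]
        if extra_times is not None:
            all_t.append(np.asarray(extra_times, dtype=float))
        self.t_union = np.unique(np.concatenate(all_t)) if all_t else np.array([0.0])
        sim_id, col, tidx, zs, sds = [], [], [], [], []
        col_l, col_n = 2 * nc, 2 * nc + 1
        for nm in SERIES_NAMES:
            if nm not in obs.series:
                continue
            arr = obs.series[nm]
            for t, z, sd in arr:
                sim_id.append(0 if nm == "old_control" else 1)
                col.append(col_l if nm == "new_treatment" else col_n)
                tidx.append(int(np.searchsorted(self.t_union, t)))
                zs.append(z)
                sds.append(sd)
        self.obs_sim = np.array(sim_id, dtype=np.int64)
        self.obs_col = np.array(col, dtype=np.int64)
        self.obs_tidx = np.array(tidx, dtype=np.int64)
        self.obs_z = np.array(zs, dtype=float)
        self.obs_sd = np.array(sds, dtype=float)
        self.need_ctl = int("old_control" in obs.series)

    def theta_vector(self, values: dict) -> np.ndarray:
        return np.array([values[n] for n in self.spec.parameter_names], float)

    def log_likelihood_theta(self, theta: np.ndarray, dt: float = 0.25) -> float:
        """Compiled-likelihood evaluation for one parameter vector."""
        return float(_kernels._loglik_design(
            self.spec.kernel_id, np.asarray(theta, float), self.ctl_sel,
            self.trt_sel, self.b_ctl, self.A_ctl, self.b_trt, self.A_trt,
            self.t_union, dt, self.obs_sim, self.obs_col, self.obs_tidx,
            self.obs_z, self.obs_sd, self.need_ctl))

    def modeled_series(self, values: dict, times=None,
                       dt: float = 0.25) -> dict[str, np.ndarray]:
        """Forward-simulate the modeled counterparts of the observed series.

        If `times` is given, every series is evaluated on that grid instead
        of its own observation times.
        """
        theta = self.theta_vector(values)
        nc = len(self.spec.compartments)
        grid = (np.unique(np.asarray(times, dtype=float))
                if times is not None else self.t_union)
        out_states = {}
        for cond, (sel, b, A) in (("ctl", (self.ctl_sel, self.b_ctl, self.A_ctl)),
                                  ("trt", (self.trt_sel, self.b_trt, self.A_trt))):
            if cond == "ctl" and not self.need_ctl:
                continue
            kp = theta[sel]
            y0 = b + A @ theta
            buf = np.empty((grid.size, y0.size))
            status = _kernels.integrate(self.spec.kernel_id, kp, y0, 0.0, grid,
                                        dt, np.empty(0), np.empty(0), 0, buf)
            if status != 0:
                raise RuntimeError("simulation diverged for this parameter set")
            out_states[cond] = buf
        result = {}
        for nm in self.obs.series:
            cond = "ctl" if nm == "old_control" else "trt"
            colx = 2 * nc if nm == "new_treatment" else 2 * nc + 1
            states = out_states[cond][:, colx]
            tt = grid if times is not None else self.obs.times(nm)
            result[nm] = np.interp(tt, grid, states)
        return result


def log_likelihood(traj_treatment, obs: ObservationSet,
                   traj_control=None) -> float:
    """Gaussian log-likelihood (up to an additive constant) of the observed
    series given simulated trajectories:
    -sum_i sum_t [Z_i(t) - X_i(t)]^2 / (2 sigma_i(t)^2).

    `traj_treatment` supplies the old-C (unlabeled) and new-C (labeled)
    cumulative CO2 under addition; `traj_control` the old-C control series.
    """
    obs = obs.with_sd_fallback() if any(
        not np.isfinite(a[:, 2]).all() or (a[:, 2] <= 0).any()
        for a in obs.series.values()) else obs
    total = 0.0
    for nm, arr in obs.series.items():
        t, z, sd = arr[:, 0], arr[:, 1], arr[:, 2]
        if nm == "old_control":
            if traj_control is None:
                raise ValueError("old_control series present but no control "
                                 "trajectory given")
            x = traj_control.series_at(traj_control.co2_unlabeled, t)
        elif nm == "old_treatment":
            x = traj_treatment.series_at(traj_treatment.co2_unlabeled, t)
        else:
            x = traj_treatment.series_at(traj_treatment.co2_labeled, t)
        total -= float(np.sum((z - x) ** 2 / (2.0 * sd ** 2)))
    return total


def propose(theta_old: np.ndarray, bounds: np.ndarray, D: float,
            rng: np.random.Generator) -> np.ndarray:
    """One uniform-window proposal with reflection at the prior bounds.

    theta_new = theta_old + d (theta_max - theta_min) / D, d ~ U(-0.5, 0.5)
    per coordinate; coordinates leaving the box are mirrored back inside.
    """
    bounds = np.asarray(bounds, dtype=float)
    lo, hi = bounds[:, 0], bounds[:, 1]
    d = rng.uniform(-0.5, 0.5, size=theta_old.shape)
    new = theta_old + d * (hi - lo) / D
    span = hi - lo
    with np.errstate(invalid="ignore"):
        for _ in range(4):  # a |step| <= span/2 needs at most one reflection
            below = new < lo
            new[below] = 2 * lo[below] - new[below]
            above = new > hi
            new[above] = 2 * hi[above] - new[above]
            if not (below.any() or above.any()):
                break
    return np.clip(new, lo, hi)


def _find_start(design: "StudyDesign", lo: np.ndarray, hi: np.ndarray,
                config: "MCMCConfig", rng: np.random.Generator) -> np.ndarray:
    """Locate a high-likelihood starting point for the walk.

    Screens a batch of prior draws (half uniform, half log-uniform on
    parameters spanning several decades, so small rate constants are actually
    visited) and polishes the best few with derivative-free simplex descent.
    The burn-in is discarded, so this only shortens convergence; it does not
    change the sampled posterior.
    """
    from scipy.optimize import minimize

    k = lo.size
    # parameters spanning decades are screened log-uniformly (with a floor of
    # hi * 1e-6 when the lower bound is zero) so that small rate constants,
    # priming coefficients and initial fractions are actually visited
    log_lo = np.where(lo > 0, lo, hi * 1e-6)
    log_scale = (hi > 0) & (hi / log_lo > 1e2)
    log_lo = np.where(log_scale, log_lo, 1.0)

    # the start only needs the right basin, not precision: evaluate the
    # screening/polish likelihood on a coarser integration grid
    dt_init = max(config.dt, 0.5)

    def neg_ll(t):
        if np.any(t < lo) or np.any(t > hi):
            return 1e300
        if any(t[i] + t[j] > 1.0 for i, j in design.constraints):
            return 1e300
        v = design.log_likelihood_theta(t, dt=dt_init)
        return -v if np.isfinite(v) else 1e300

    # optimize in log space for decade-spanning parameters: it equalizes the
    # coordinate scales and straightens the likelihood valley
    def to_x(t):
        x = t.copy()
        x[log_scale] = np.log(np.maximum(t[log_scale], log_lo[log_scale]))
        return x

    def to_theta(x):
        t = x.copy()
        t[log_scale] = np.exp(np.clip(x[log_scale], np.log(log_lo[log_scale]),
                                      np.log(hi[log_scale])))
        return np.clip(t, lo, hi)

    def f_x(x):
        return neg_ll(to_theta(x))

    n = max(config.n_init_draws, 8)
    cands = []
    for i in range(n):
        t = rng.uniform(lo, hi)
        if i % 2 and log_scale.any():
            t[log_scale] = np.exp(rng.uniform(np.log(log_lo[log_scale]),
                                              np.log(hi[log_scale])))
        f = neg_ll(t)
        if f < 1e300:
            cands.append((f, t))
    cands.sort(key=lambda ft: ft[0])
    best_f, best_t = (cands[0] if cands else (1e300, (lo + hi) / 2))
    for f0, t0 in cands[:3]:
        x = to_x(t0)
        fv = f0
        for _ in range(2):  # simplex restarts escape collapsed simplices
            res = minimize(f_x, x, method="Nelder-Mead",
                           options={"maxfev": 150 * k, "xatol": 1e-12,
                                    "fatol": 1e-10})
            if res.fun >= fv - max(1e-8, 1e-3 * abs(fv)):
                x, fv = res.x, min(res.fun, fv)
                break
            x, fv = res.x, res.fun
        if fv < best_f:
            best_f, best_t = fv, to_theta(x)
    return np.asarray(best_t, dtype=float)


def run_mcmc(model: str | ModelSpec, obs: ObservationSet,
             config: MCMCConfig | None = None) -> PosteriorChain:
    """Calibrate one model to one study; returns the post-burn-in chain.

    Uniform priors over the model's parameter bounds (or ``config.bounds``
    overrides).  Deterministic given ``config.seed``.
    """
    spec = model if isinstance(model, ModelSpec) else get_model(model)
    config = config or MCMCConfig()
    problems = obs.criteria_violations()
    if problems:
        raise ValueError(f"study {obs.study_id} fails selection criteria: "
                         + "; ".join(problems))
    obs = obs.with_sd_fallback()
    design = StudyDesign(spec, obs)
    bounds = spec.bounds_array()
    if config.bounds:
        for n, (lo, hi) in config.bounds.items():
            bounds[spec.parameter_names.index(n)] = (lo, hi)
    lo, hi = np.ascontiguousarray(bounds[:, 0]), np.ascontiguousarray(bounds[:, 1])
    S = int(config.n_iterations)
    burn = int(S * config.burn_in_fraction)
    rng = np.random.default_rng(config.seed)
    theta0 = _find_start(design, lo, hi, config, rng)
    kernel_seed = int(rng.integers(0, 2**31 - 1))
    # initial diagonal proposal widths: the chain starts at the screened MAP,
    # so size the first steps by the starting point's own magnitudes rather
    # than the (often far wider) prior box
    w0 = np.minimum(np.maximum(0.1 * np.abs(theta0), 1e-6 * (hi - lo)),
                    (hi - lo) / config.step_divisor)
    chain, lls, nacc, widths = _kernels.run_chain(
        spec.kernel_id, lo, hi, design.constraints, design.ctl_sel,
        design.trt_sel, design.b_ctl, design.A_ctl, design.b_trt, design.A_trt,
        design.t_union, config.dt, design.obs_sim, design.obs_col,
        design.obs_tidx, design.obs_z, design.obs_sd, design.need_ctl,
        S, burn,
        # guarantee a dozen adaptation windows even for short chains
        min(config.adapt_interval, max(50, burn // 12)),
        w0, config.anneal_temperature, kernel_seed, theta0)
    acc_rate = nacc / S
    if not np.isfinite(lls[burn:]).any() or acc_rate < 0.01:
        raise ChainDiagnosticError(
            f"acceptance rate {acc_rate:.4f} after adaptation; revise the "
            "parameter bounds or the step divisor")
    return PosteriorChain(
        model=spec.name, parameter_names=spec.parameter_names,
        samples=chain[burn:], log_likelihoods=lls[burn:],
        acceptance_rate=acc_rate, proposal_widths=widths,
        seed=config.seed)


def posterior_predictive(chain: PosteriorChain, model: str | ModelSpec,
                         obs: ObservationSet, quantiles=(0.025, 0.975),
                         times=None, max_samples: int = 500,
                         dt: float = 0.25,
                         seed: int = 0) -> dict[str, dict]:
    """Per-series quantile bands of the simulated cumulative CO2 over the
    posterior samples.

    Returns {series: {"times": t, q: band_array, ...}}.
    """
    quantiles = tuple(quantiles)
    if any(not 0.0 < q < 1.0 for q in quantiles):
        raise ValueError("quantiles must lie strictly inside (0, 1)")
    if chain.n_samples == 0:
        raise ValueError("empty chain")
    spec = model if isinstance(model, ModelSpec) else get_model(model)
    design = StudyDesign(spec, obs.with_sd_fallback())
    if chain.n_samples > max_samples:
        rng = np.random.default_rng(seed)
        rows = rng.choice(chain.n_samples, size=max_samples, replace=False)
    else:
        rows = np.arange(chain.n_samples)
    sims: dict[str, list[np.ndarray]] = {nm: [] for nm in obs.series}
    for i in rows:
        values = dict(zip(chain.parameter_names, chain.samples[i]))
        modeled = design.modeled_series(values, times=times, dt=dt)
        for nm, x in modeled.items():
            sims[nm].append(x)
    out = {}
    for nm, stack in sims.items():
        arr = np.vstack(stack)
        tt = (np.unique(np.asarray(times, float)) if times is not None
              else obs.times(nm))
        entry = {"times": tt}
        for q in quantiles:
            entry[q] = np.quantile(arr, q, axis=0)
        out[nm] = entry
    return out
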