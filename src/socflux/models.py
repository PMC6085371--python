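"""Forward simulation of four soil-carbon decomposition models.

The models share a common experimental template: a one-time addition of
isotope-labeled fresh substrate ("new C") to a soil whose pre-existing stock
("old C") is unlabeled, followed by incubation during which cumulative CO2
emission is partitioned by isotopic source.

* ``conventional`` — first-order kinetics with a new pool N feeding labile (L)
  and recalcitrant (R) SOC pools that exchange with each other.  Priming can
  only be represented by giving treatment and control different rate
  parameters.
* ``interactive`` — a two-pool extension of the introductory carbon balance
  model (ICBM): the old-pool decay rate is ``K_O + K_p * N**p``, so fresh
  substrate directly accelerates old-C decomposition (the priming term), and a
  fraction ``r`` of decomposed new C replenishes the old pool.
* ``michaelis_menten`` — explicit microbial biomass B; substrate uptake is
  Michaelis-Menten in the substrate, scaled by B.
* ``reverse_michaelis_menten`` — uptake is first-order in substrate and
  saturating in microbial biomass.

Units are mg C g^-1 soil and days throughout.  Isotope bookkeeping is exact:
each compartment carries a labeled and an unlabeled mass, and cumulative CO2
is ledgered per label, so labeled C in pools plus labeled CO2 always equals
the labeled input.
"""

from __future__ import annotations


from dataclasses import dataclass, field

import numpy as np

from . import _kernels

__all__ = [
    "ModelSpec",
    "PoolState",
    "Forcing",
    "Trajectory",
    "MODELS",
    "MODEL_NAMES",
    "get_model",
    "DivergenceError",
    "ConvergenceError",
    "conventional_condition",
    "validate_params",
    "params_valid",
    "initial_pool_state",
    "simulate",
    "steady_state",
    "closed_form_new_pool",
    "DEFAULT_DT",
]

DEFAULT_DT = 0.05  # day; fixed RK4 step


class DivergenceError(RuntimeError):
    """The integrator produced a non-finite state for this parameter set."""


class ConvergenceError(RuntimeError):
    """An iterative computation failed to reach its tolerance."""


@dataclass(frozen=True)
class ModelSpec:
    """Static description of one model: fit-level parameters and pools."""

    name: str
    parameter_names: tuple[str, ...]
    parameter_bounds: dict[str, tuple[float, float]]
    compartments: tuple[str, ...]
    kernel_id: int

    @property
    def n_parameters(self) -> int:
        return len(self.parameter_names)

    def bounds_array(self) -> np.ndarray:
        return np.array([self.parameter_bounds[n] for n in self.parameter_names])


_RATE = (1e-5, 1.0)        # first-order / turnover rates, d^-1
_VMAX = (1e-3, 10.0)       # MM maximum assimilation rates, d^-1
_KM = (1e-3, 100.0)        # Michaelis constants, mg C g^-1 soil
_FRAC = (0.0, 1.0)

MODELS: dict[str, ModelSpec] = {
    "conventional": ModelSpec(
        name="conventional",
        # shared {K_N, a_LN, a_RN, f_L} + per-condition {K_L, K_R, a_LR, a_RL}
        parameter_names=(
            "K_N", "a_LN", "a_RN", "f_L",
            "K_L_ctl", "K_R_ctl", "a_LR_ctl", "a_RL_ctl",
            "K_L_trt", "K_R_trt", "a_LR_trt", "a_RL_trt",
        ),
        parameter_bounds={
            "K_N": _RATE, "a_LN": _FRAC, "a_RN": _FRAC, "f_L": _FRAC,
            "K_L_ctl": _RATE, "K_R_ctl": _RATE, "a_LR_ctl": _FRAC, "a_RL_ctl": _FRAC,
            "K_L_trt": _RATE, "K_R_trt": _RATE, "a_LR_trt": _FRAC, "a_RL_trt": _FRAC,
        },
        compartments=("N", "L", "R"),
        kernel_id=_kernels.CONVENTIONAL,
    ),
    "interactive": ModelSpec(
        name="interactive",
        parameter_names=("K_N", "K_O", "r", "K_p", "p", "f_N"),
        parameter_bounds={
            "K_N": _RATE, "K_O": _RATE, "r": _FRAC,
            "K_p": (0.0, 1.0), "p": (0.01, 2.0), "f_N": _FRAC,
        },
        compartments=("N", "O"),
        kernel_id=_kernels.INTERACTIVE,
    ),
    "michaelis_menten": ModelSpec(
        name="michaelis_menten",
        parameter_names=("V_N", "V_O", "K_N", "K_O", "mu_B", "eps", "f_N", "f_B"),
        parameter_bounds={
            "V_N": _VMAX, "V_O": _VMAX, "K_N": _KM, "K_O": _KM,
            "mu_B": _RATE, "eps": _FRAC, "f_N": _FRAC, "f_B": _FRAC,
        },
        compartments=("N", "O", "B"),
        kernel_id=_kernels.MICHAELIS,
    ),
    "reverse_michaelis_menten": ModelSpec(
        name="reverse_michaelis_menten",
        parameter_names=("mu_N", "mu_O", "mu_B", "K_B", "eps", "f_N", "f_B"),
        parameter_bounds={
            "mu_N": _RATE, "mu_O": _RATE, "mu_B": _RATE, "K_B": _KM,
            "eps": _FRAC, "f_N": _FRAC, "f_B": _FRAC,
        },
        compartments=("N", "O", "B"),
        kernel_id=_kernels.REVERSE_MM,
    ),
}

MODEL_NAMES = tuple(MODELS)

# parameter names of a single experimental condition of the conventional model
CONVENTIONAL_CONDITION_NAMES = ("K_N", "K_L", "K_R", "a_LN", "a_RN", "a_LR", "a_RL", "f_L")


def get_model(name: str) -> ModelSpec:
    try:
        return MODELS[name]
    except KeyError:
        raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}") from None


def conventional_condition(values: dict, condition: str) -> dict:
    """Extract the 8-parameter single-condition set from the 12-parameter
    fit-level vector of the conventional model.

    Treatment and control share {K_N, a_LN, a_RN, f_L}; each condition has its
    own {K_L, K_R, a_LR, a_RL}.
    """
    if condition not in ("control", "treatment"):
        raise ValueError("condition must be 'control' or 'treatment'")
    suf = "_ctl" if condition == "control" else "_trt"
    return {
        "K_N": values["K_N"], "a_LN": values["a_LN"], "a_RN": values["a_RN"],
        "f_L": values["f_L"],
        "K_L": values["K_L" + suf], "K_R": values["K_R" + suf],
        "a_LR": values["a_LR" + suf], "a_RL": values["a_RL" + suf],
    }


def params_valid(model: str | ModelSpec, values: dict) -> bool:
    """Joint constraints beyond the per-parameter boxes."""
    spec = model if isinstance(model, ModelSpec) else get_model(model)
    name = spec.name
    if name == "conventional":
        if "a_LN" in values and "a_RN" in values:
            if values["a_LN"] + values["a_RN"] > 1.0:
                return False
    elif name in ("michaelis_menten", "reverse_michaelis_menten"):
        if values["f_N"] + values["f_B"] > 1.0:
            return False
    return True


def validate_params(model: str | ModelSpec, values: dict) -> None:
    """Raise ValueError if a fit-level parameter set is out of bounds or
    violates a joint constraint."""
    spec = model if isinstance(model, ModelSpec) else get_model(model)
    missing = set(spec.parameter_names) - set(values)
    if missing:
        raise ValueError(f"missing parameters for {spec.name}: {sorted(missing)}")
    for n in spec.parameter_names:
        lo, hi = spec.parameter_bounds[n]
        v = values[n]
        if not np.isfinite(v) or v < lo or v > hi:
            raise ValueError(f"{spec.name} parameter {n}={v} outside [{lo}, {hi}]")
    if not params_valid(spec, values):
        raise ValueError(f"{spec.name} parameters violate a joint constraint")


def _kernel_params(name: str, v: dict) -> np.ndarray:
    if name == "conventional":
        keys = ("K_N", "K_L", "K_R", "a_LN", "a_RN", "a_LR", "a_RL")
    elif name == "interactive":
        keys = ("K_N", "K_O", "r", "K_p", "p")
    elif name == "michaelis_menten":
        keys = ("V_N", "V_O", "K_N", "K_O", "mu_B", "eps")
    else:
        keys = ("mu_N", "mu_O", "mu_B", "K_B", "eps")
    return np.array([v[k] for k in keys], dtype=float)


@dataclass
class PoolState:
    """Labeled and unlabeled carbon mass per compartment (mg C g^-1 soil)."""

    model: str
    labeled: dict[str, float]
    unlabeled: dict[str, float]

    def __post_init__(self):
        comps = get_model(self.model).compartments
        for d in (self.labeled, self.unlabeled):
            if tuple(d) != comps:
                missing = set(comps) - set(d)
                extra = set(d) - set(comps)
                if missing or extra:
                    raise ValueError(
                        f"compartments do not match model {self.model}: "
                        f"missing {sorted(missing)}, unexpected {sorted(extra)}")
        for d in (self.labeled, self.unlabeled):
            for c, m in d.items():
                if m < 0:
                    raise ValueError(f"negative mass in compartment {c}: {m}")

    @property
    def total(self) -> float:
        return sum(self.labeled.values()) + sum(self.unlabeled.values())

    def to_vector(self) -> np.ndarray:
        comps = get_model(self.model).compartments
        vals = [self.labeled[c] for c in comps] + [self.unlabeled[c] for c in comps]
        return np.array(vals + [0.0, 0.0], dtype=float)  # + CO2 ledgers


def initial_pool_state(model: str, values: dict, soc: float, added: float) -> PoolState:
    """Build the incubation initial state from study metadata.

    The native soil stock `soc` is unlabeled and partitioned by the model's
    initial-fraction parameters; the added substrate (all labeled) enters the
    new-C pool.  For control runs pass ``added=0``.
    """
    if soc < 0 or added < 0:
        raise ValueError("soc and added must be nonnegative")
    name = get_model(model).name
    if name == "conventional":
        fL = values["f_L"]
        lab = {"N": added, "L": 0.0, "R": 0.0}
        unl = {"N": 0.0, "L": fL * soc, "R": (1.0 - fL) * soc}
    elif name == "interactive":
        fN = values["f_N"]
        lab = {"N": added, "O": 0.0}
        unl = {"N": fN * soc, "O": (1.0 - fN) * soc}
    else:
        fN, fB = values["f_N"], values["f_B"]
        if fN + fB > 1.0:
            raise ValueError("f_N + f_B must not exceed 1")
        lab = {"N": added, "O": 0.0, "B": 0.0}
        unl = {"N": fN * soc, "B": fB * soc, "O": (1.0 - fN - fB) * soc}
    return PoolState(model=name, labeled=lab, unlabeled=unl)


@dataclass
class Forcing:
    """External carbon inputs.

    ``impulses`` are one-time additions ``(time_d, amount, labeled)``; the
    continuous rate is piecewise-linear through ``(rate_times, rates)`` in
    mg C g^-1 soil d^-1 and is routed to the new-C pool of the label chosen
    by ``continuous_labeled``.
    """

    impulses: list[tuple[float, float, bool]] = field(default_factory=list)
    rate_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    rates: np.ndarray = field(default_factory=lambda: np.empty(0))
    continuous_labeled: bool = False

    def __post_init__(self):
        self.rate_times = np.asarray(self.rate_times, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rate_times.shape != self.rates.shape:
            raise ValueError("rate_times and rates must have equal length")
        if np.any(self.rates < 0):
            raise ValueError("continuous input rate must be nonnegative")
        for t, a, _ in self.impulses:
            if a < 0:
                raise ValueError("impulse amounts must be nonnegative")
            if t < 0:
                raise ValueError("impulse times must be nonnegative")

    def rate_at(self, t: float) -> float:
        if self.rate_times.size == 0:
            return 0.0
        return float(np.interp(t, self.rate_times, self.rates))

    def cumulative_input(self, t: float) -> float:
        """Exact integral of all inputs over [0, t] (impulses at s<=t included)."""
        tot = sum(a for s, a, _ in self.impulses if s <= t)
        if self.rate_times.size:
            # integral of the piecewise-linear rate: trapezoid over knots
            ts = self.rate_times
            grid = np.unique(np.concatenate([ts[ts < t], [0.0, t]]))
            grid = grid[(grid >= 0.0) & (grid <= t)]
            vals = np.interp(grid, ts, self.rates)
            tot += float(np.trapezoid(vals, grid))
        return tot


@dataclass
class Trajectory:
    """Solution of one simulation: states at the requested output times."""

    model: str
    times: np.ndarray
    states: np.ndarray  # (n_times, n_state); layout per _kernels docstring
    initial: PoolState
    forcing: Forcing

    @property
    def compartments(self) -> tuple[str, ...]:
        return get_model(self.model).compartments

    def _nc(self) -> int:
        return len(self.compartments)

    def labeled_pool(self, comp: str) -> np.ndarray:
        return self.states[:, self.compartments.index(comp)]

    def unlabeled_pool(self, comp: str) -> np.ndarray:
        return self.states[:, self._nc() + self.compartments.index(comp)]

    def total_pool(self, comp: str) -> np.ndarray:
        return self.labeled_pool(comp) + self.unlabeled_pool(comp)

    @property
    def co2_labeled(self) -> np.ndarray:
        """Cumulative CO2 emitted from labeled (added-substrate) carbon."""
        return self.states[:, 2 * self._nc()]

    @property
    def co2_unlabeled(self) -> np.ndarray:
        """Cumulative CO2 emitted from unlabeled (old SOC) carbon."""
        return self.states[:, 2 * self._nc() + 1]

    @property
    def co2_total(self) -> np.ndarray:
        return self.co2_labeled + self.co2_unlabeled

    @property
    def labeled_pool_total(self) -> np.ndarray:
        return self.states[:, : self._nc()].sum(axis=1)

    @property
    def unlabeled_pool_total(self) -> np.ndarray:
        return self.states[:, self._nc(): 2 * self._nc()].sum(axis=1)

    @property
    def total_carbon(self) -> np.ndarray:
        """Soil pools only (excludes already-respired CO2)."""
        return self.labeled_pool_total + self.unlabeled_pool_total

    def series_at(self, series: np.ndarray, t) -> np.ndarray | float:
        """Linear interpolation of a stored series onto time(s) t."""
        t = np.asarray(t, dtype=float)
        if np.any(t < self.times[0] - 1e-9) or np.any(t > self.times[-1] + 1e-9):
            raise ValueError("time outside the simulated span")
        out = np.interp(t, self.times, series)
        return float(out) if out.ndim == 0 else out

    def mass_balance_residual(self) -> np.ndarray:
        """(pools + cumulative CO2) - (initial pools + cumulative inputs)."""
        init = self.initial.total
        inputs = np.array([self.forcing.cumulative_input(t) for t in self.times])
        return self.total_carbon + self.co2_total - init - inputs

    def to_frame(self):
        """Tidy long-format export (columns: time_d, series, value)."""
        import pandas as pd

        rows = {}
        for c in self.compartments:
            rows[f"pool_{c}_labeled"] = self.labeled_pool(c)
            rows[f"pool_{c}_unlabeled"] = self.unlabeled_pool(c)
        rows["co2_labeled"] = self.co2_labeled
        rows["co2_unlabeled"] = self.co2_unlabeled
        frames = [
            pd.DataFrame({"time_d": self.times, "series": k, "value": v})
            for k, v in rows.items()
        ]
        return pd.concat(frames, ignore_index=True)


def _forcing_arrays(forcing: Forcing | None):
    if forcing is None or forcing.rate_times.size == 0:
        return np.empty(0), np.empty(0), 0
    return forcing.rate_times, forcing.rates, int(forcing.continuous_labeled)


def simulate(model: str | ModelSpec, params: dict, initial_state: PoolState,
             forcing: Forcing | None = None, times=None,
             dt: float = DEFAULT_DT) -> Trajectory:
    """Integrate one model with fixed-step RK4 and return its trajectory.

    `params` is a single-condition parameter dict (for the conventional model
    use :func:`conventional_condition` to slice the 12-parameter fit vector).
    Output states are linearly interpolated from the integration grid onto
    `times` (days, sorted, >= 0).
    """
    spec = model if isinstance(model, ModelSpec) else get_model(model)
    if initial_state.model != spec.name:
        raise ValueError(
            f"initial state is for model {initial_state.model!r}, not {spec.name!r}")
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("times must be a non-empty 1-D sequence")
    if np.any(np.diff(times) < 0) or times[0] < 0:
        raise ValueError("times must be sorted and nonnegative")
    forcing = forcing if forcing is not None else Forcing()

    y0 = initial_state.to_vector()
    nc = len(spec.compartments)
    kp = _kernel_params(spec.name, params)
    f_ts, f_rs, lab_in = _forcing_arrays(forcing)

    t_end = times[-1]
    events = sorted({t for t, a, _ in forcing.impulses if 0 < t <= t_end})
    for t, a, labeled in forcing.impulses:
        if t > t_end:
            raise ValueError("impulse time beyond the simulation window")
        if t == 0:
            y0[0 if labeled else nc] += a

    seg_bounds = [0.0] + events + [t_end]
    out = np.empty((times.size, y0.size))
    y = y0.copy()
    for a, b in zip(seg_bounds[:-1], seg_bounds[1:]):
        sel = (times > a + 1e-12) & (times <= b + 1e-12) if a > 0 else (times <= b + 1e-12)
        t_seg = times[sel]
        # always integrate to the segment end so impulses land on the right state
        t_out = t_seg if (t_seg.size and abs(t_seg[-1] - b) < 1e-12) \
            else np.append(t_seg, b)
        buf = np.empty((t_out.size, y0.size))
        status = _kernels.integrate(spec.kernel_id, kp, y, float(a), t_out, dt,
                                    f_ts, f_rs, lab_in, buf)
        if status != 0:
            raise DivergenceError(
                f"{spec.name} simulation diverged (non-finite state); "
                "parameter set rejected at this step size")
        out[sel] = buf[: t_seg.size]
        y = buf[-1].copy()
        for t, amt, labeled in forcing.impulses:
            if abs(t - b) < 1e-12 and t > 0:
                y[0 if labeled else nc] += amt
    return Trajectory(model=spec.name, times=times, states=out,
                      initial=initial_state, forcing=forcing)


def steady_state(model: str | ModelSpec, params: dict,
                 constant_input_rate: float, tol: float = 1e-10) -> PoolState:
    """Equilibrium pools under a constant input (interactive model).

    Solved algebraically: N* = I / K_N and O* = r I / (K_O + K_p N*^p); the
    residual of the right-hand side is verified against `tol`.  The returned
    state holds the equilibrium mass as unlabeled (native) carbon.
    """
    spec = model if isinstance(model, ModelSpec) else get_model(model)
    if spec.name != "interactive":
        raise NotImplementedError("steady_state is provided for the interactive model")
    if constant_input_rate < 0:
        raise ValueError("input rate must be nonnegative")
    I = float(constant_input_rate)
    if I == 0.0:
        return PoolState("interactive", {"N": 0.0, "O": 0.0}, {"N": 0.0, "O": 0.0})
    K_N, K_O, r, K_p, p = (params["K_N"], params["K_O"], params["r"],
                           params["K_p"], params["p"])
    n_star = I / K_N
    denom = K_O + K_p * n_star ** p
    o_star = r * I / denom
    resid = max(abs(I - K_N * n_star), abs(r * K_N * n_star - denom * o_star))
    if not np.isfinite(o_star) or resid > tol * max(1.0, I):
        raise ConvergenceError(f"steady state residual {resid:.3e} exceeds tolerance")
    return PoolState("interactive", {"N": 0.0, "O": 0.0},
                     {"N": n_star, "O": o_star})


def closed_form_new_pool(N0: float, K_N: float, t) -> np.ndarray | float:
    """Analytic decay of an isolated new-C pool, ``N0 * exp(-K_N t)``.

    Serves as the exact oracle for validating the numerical integrator.
    """
    if N0 < 0:
        raise ValueError("N0 must be nonnegative")
    if K_N <= 0:
        raise ValueError("K_N must be positive")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be nonnegative")
    out = N0 * np.exp(-K_N * t_arr)
    return float(out) if out.ndim == 0 else out
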