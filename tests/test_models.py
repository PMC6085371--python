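"""Forward-model tests: closed forms, conservation, linear-algebra oracles,
and qualitative invariants of the four decomposition models."""

import numpy as np
import pytest
from scipy.linalg import expm

from socflux.models import (DEFAULT_DT, MODEL_NAMES, MODELS, DivergenceError,
                            Forcing, PoolState, closed_form_new_pool,
                            get_model, initial_pool_state, simulate,
                            steady_state, validate_params)

RNG = np.random.default_rng(20240915)


def draw_params(model, rng):
    """A random valid parameter set at incubation-realistic magnitudes."""
    if model == "conventional":
        a_LN, a_RN = rng.uniform(0.05, 0.45, 2)
        return {"K_N": rng.uniform(0.02, 0.1), "K_L": rng.uniform(0.005, 0.05),
                "K_R": rng.uniform(1e-4, 1e-3), "a_LN": a_LN, "a_RN": a_RN,
                "a_LR": rng.uniform(0, 0.3), "a_RL": rng.uniform(0, 0.3),
                "f_L": rng.uniform(0.05, 0.3)}
    if model == "interactive":
        return {"K_N": rng.uniform(0.02, 0.1), "K_O": rng.uniform(5e-5, 5e-4),
                "r": rng.uniform(0.2, 0.6), "K_p": rng.uniform(0, 2e-3),
                "p": rng.uniform(0.5, 1.5), "f_N": rng.uniform(0, 0.05)}
    if model == "michaelis_menten":
        return {"V_N": rng.uniform(0.1, 1.0), "V_O": rng.uniform(0.01, 0.1),
                "K_N": rng.uniform(5, 50), "K_O": rng.uniform(20, 100),
                "mu_B": rng.uniform(0.005, 0.05), "eps": rng.uniform(0.2, 0.6),
                "f_N": rng.uniform(0, 0.05), "f_B": rng.uniform(0.01, 0.05)}
    return {"mu_N": rng.uniform(0.05, 0.5), "mu_O": rng.uniform(1e-4, 1e-3),
            "mu_B": rng.uniform(0.005, 0.05), "K_B": rng.uniform(0.5, 5),
            "eps": rng.uniform(0.2, 0.6), "f_N": rng.uniform(0, 0.05),
            "f_B": rng.uniform(0.01, 0.05)}


def test_model_registry_matches_published_parameter_counts():
    counts = {name: MODELS[name].n_parameters for name in MODEL_NAMES}
    assert counts == {"conventional": 12, "interactive": 6,
                      "michaelis_menten": 8, "reverse_michaelis_menten": 7}
    for spec in MODELS.values():
        b = spec.bounds_array()
        assert np.all(np.isfinite(b)) and np.all(b[:, 0] < b[:, 1])


def test_closed_form_new_pool_values_and_errors():
    assert closed_form_new_pool(1.0, 0.01, 100.0) == pytest.approx(np.exp(-1))
    assert closed_form_new_pool(3.5, 0.2, 0.0) == 3.5
    with pytest.raises(ValueError):
        closed_form_new_pool(1.0, 0.01, -1.0)
    with pytest.raises(ValueError):
        closed_form_new_pool(1.0, 0.0, 1.0)


def test_interactive_control_decays_exponentially_without_new_carbon():
    # no new C anywhere: the priming term is disabled and the old pool is a
    # pure exponential regardless of K_p
    p = {"K_N": 0.02, "K_O": 0.001, "r": 0.4, "K_p": 0.7, "p": 1.0, "f_N": 0.0}
    st = PoolState("interactive", {"N": 0.0, "O": 0.0}, {"N": 0.0, "O": 10.0})
    tr = simulate("interactive", p, st, times=[0.0, 365.0])
    assert tr.unlabeled_pool("O")[-1] == pytest.approx(10 * np.exp(-0.365),
                                                      abs=1e-6)


def test_solver_matches_isolated_new_pool_closed_form():
    for _ in range(20):
        n0 = RNG.uniform(0.1, 5.0)
        k = RNG.uniform(1e-3, 0.5)
        t = RNG.uniform(1.0, 300.0)
        p = {"K_N": k, "K_O": 1e-4, "r": 0.0, "K_p": 0.0, "p": 1.0, "f_N": 0.0}
        st = PoolState("interactive", {"N": n0, "O": 0.0}, {"N": 0.0, "O": 0.0})
        tr = simulate("interactive", p, st, times=[0.0, t])
        assert tr.labeled_pool("N")[-1] == pytest.approx(
            closed_form_new_pool(n0, k, t), abs=1e-8)


@pytest.mark.parametrize("model", MODEL_NAMES)
def test_mass_balance_under_random_parameters(model):
    """Pools + cumulative CO2 - inputs - initial state closes to < 1e-6."""
    for trial in range(5):
        rng = np.random.default_rng(hash((model, trial)) % 2**31)
        cond = draw_params(model, rng)
        st = initial_pool_state(model, cond, soc=rng.uniform(5, 25),
                                added=rng.uniform(0.2, 2.0))
        tr = simulate(model, cond, st, times=np.linspace(0, 365, 12))
        assert np.abs(tr.mass_balance_residual()).max() < 1e-6


def test_mass_balance_with_continuous_input_and_midrun_impulse():
    p = {"K_N": 0.05, "K_O": 2e-4, "r": 0.4, "K_p": 1e-3, "p": 1.0, "f_N": 0.01}
    st = initial_pool_state("interactive", p, soc=10.0, added=1.0)
    forcing = Forcing(impulses=[(0.0, 0.5, True), (100.0, 0.7, False)],
                      rate_times=np.array([0.0, 365.0]),
                      rates=np.array([8e-4, 9e-4]))
    tr = simulate("interactive", p, st, forcing=forcing,
                  times=np.linspace(0, 365, 25))
    assert np.abs(tr.mass_balance_residual()).max() < 1e-6
    # the impulse is visible in the total-carbon series
    total = tr.total_carbon
    i_before = np.searchsorted(tr.times, 100.0) - 1
    assert total[i_before + 1] > total[i_before]


def _linear_matrix_interactive(p):
    """State matrix of the interactive model with K_p = 0 (ICBM limit),
    including the CO2 ledger rows."""
    K_N, K_O, r = p["K_N"], p["K_O"], p["r"]
    A = np.zeros((6, 6))
    A[0, 0] = -K_N
    A[1, 0] = r * K_N
    A[1, 1] = -K_O
    A[2, 2] = -K_N
    A[3, 2] = r * K_N
    A[3, 3] = -K_O
    A[4, 0] = (1 - r) * K_N
    A[4, 1] = K_O
    A[5, 2] = (1 - r) * K_N
    A[5, 3] = K_O
    return A


def test_rk4_matches_matrix_exponential_on_linear_interactive_model():
    p = {"K_N": 0.05, "K_O": 3e-4, "r": 0.35, "K_p": 0.0, "p": 1.0,
         "f_N": 0.02}
    st = initial_pool_state("interactive", p, soc=12.0, added=0.8)
    times = np.linspace(0, 365, 8)
    tr = simulate("interactive", p, st, times=times, dt=DEFAULT_DT)
    A = _linear_matrix_interactive(p)
    y0 = st.to_vector()
    exact = np.array([expm(A * t) @ y0 for t in times])
    assert np.abs(tr.states - exact).max() < 1e-6


def test_rk4_matches_matrix_exponential_on_conventional_model():
    p = {"K_N": 0.06, "K_L": 0.02, "K_R": 5e-4, "a_LN": 0.3, "a_RN": 0.2,
         "a_LR": 0.1, "a_RL": 0.15, "f_L": 0.2}
    st = initial_pool_state("conventional", p, soc=15.0, added=1.2)
    A = np.zeros((8, 8))
    K = {"N": p["K_N"], "L": p["K_L"], "R": p["K_R"]}
    for off in (0, 3):  # labeled block then unlabeled block
        A[off + 0, off + 0] = -K["N"]
        A[off + 1, off + 0] = K["N"] * p["a_LN"]
        A[off + 1, off + 1] = -K["L"]
        A[off + 1, off + 2] = K["R"] * p["a_LR"]
        A[off + 2, off + 0] = K["N"] * p["a_RN"]
        A[off + 2, off + 1] = K["L"] * p["a_RL"]
        A[off + 2, off + 2] = -K["R"]
        co2 = 6 if off == 0 else 7
        A[co2, off + 0] = K["N"] * (1 - p["a_LN"] - p["a_RN"])
        A[co2, off + 1] = K["L"] * (1 - p["a_RL"])
        A[co2, off + 2] = K["R"] * (1 - p["a_LR"])
    times = np.linspace(0, 365, 8)
    tr = simulate("conventional", p, st, times=times, dt=DEFAULT_DT)
    exact = np.array([expm(A * t) @ st.to_vector() for t in times])
    assert np.abs(tr.states - exact).max() < 1e-6


@pytest.mark.parametrize("model", MODEL_NAMES)
def test_totals_invariant_under_label_redistribution(model):
    """Moving mass between the labeled and unlabeled ledgers of the same
    compartment leaves every total (pools and CO2) unchanged."""
    rng = np.random.default_rng(5)
    cond = draw_params(model, rng)
    st1 = initial_pool_state(model, cond, soc=10.0, added=1.0)
    # shift all native new-pool mass into the labeled ledger
    lab = dict(st1.labeled)
    unl = dict(st1.unlabeled)
    lab["N"] += unl["N"]
    unl["N"] = 0.0
    st2 = PoolState(model, lab, unl)
    times = np.linspace(0, 180, 7)
    t1 = simulate(model, cond, st1, times=times)
    t2 = simulate(model, cond, st2, times=times)
    for comp in t1.compartments:
        assert t1.total_pool(comp) == pytest.approx(t2.total_pool(comp),
                                                    abs=1e-9)
    assert t1.co2_total == pytest.approx(t2.co2_total, abs=1e-9)


def test_conventional_label_additivity_is_exact():
    """For the fully linear model, simulating the labeled and unlabeled
    subsystems separately and summing equals simulating them together."""
    rng = np.random.default_rng(6)
    p = draw_params("conventional", rng)
    times = np.linspace(0, 200, 9)
    both = simulate("conventional", p,
                    initial_pool_state("conventional", p, soc=10.0, added=1.0),
                    times=times)
    only_lab = simulate("conventional", p,
                        PoolState("conventional",
                                  {"N": 1.0, "L": 0.0, "R": 0.0},
                                  {"N": 0.0, "L": 0.0, "R": 0.0}),
                        times=times)
    only_unl = simulate("conventional", p,
                        initial_pool_state("conventional", p, soc=10.0,
                                           added=0.0), times=times)
    assert both.total_carbon == pytest.approx(
        only_lab.total_carbon + only_unl.total_carbon, abs=1e-9)


def test_old_carbon_co2_monotone_in_priming_coefficient():
    base = {"K_N": 0.05, "K_O": 2e-4, "r": 0.4, "p": 1.0, "f_N": 0.01}
    times = np.linspace(0, 365, 30)
    prev = None
    for kp in (0.0, 5e-4, 2e-3, 1e-2):
        p = dict(base, K_p=kp)
        st = initial_pool_state("interactive", p, soc=10.0, added=1.0)
        co2_old = simulate("interactive", p, st, times=times).co2_unlabeled
        if prev is not None:
            assert np.all(co2_old >= prev - 1e-12)
        prev = co2_old


@pytest.mark.parametrize("model", MODEL_NAMES)
def test_pools_stay_nonnegative(model):
    rng = np.random.default_rng(9)
    cond = draw_params(model, rng)
    st = initial_pool_state(model, cond, soc=8.0, added=0.5)
    tr = simulate(model, cond, st, times=np.linspace(0, 365, 20))
    assert tr.states.min() >= -1e-12


def test_steady_state_algebraic_fixed_point():
    p = {"K_N": 0.02, "K_O": 1e-4, "r": 0.4, "K_p": 0.0, "p": 1.0, "f_N": 0.0}
    ss = steady_state("interactive", p, 8e-4)
    assert ss.unlabeled["N"] == pytest.approx(0.04)
    assert ss.unlabeled["O"] == pytest.approx(3.2)


def test_steady_state_with_priming_agrees_with_long_integration():
    p = {"K_N": 0.02, "K_O": 1e-4, "r": 0.4, "K_p": 5e-3, "p": 1.0,
         "f_N": 0.0}
    I = 8e-4
    ss = steady_state("interactive", p, I)
    forcing = Forcing(rate_times=np.array([0.0, 1e5]),
                      rates=np.array([I, I]))
    st = PoolState("interactive", {"N": 0.0, "O": 0.0}, {"N": 0.0, "O": 0.0})
    tr = simulate("interactive", p, st, forcing=forcing,
                  times=[0.0, 1e5], dt=0.5)
    assert tr.unlabeled_pool("N")[-1] + tr.labeled_pool("N")[-1] == \
        pytest.approx(ss.unlabeled["N"], rel=1e-6)
    assert tr.unlabeled_pool("O")[-1] + tr.labeled_pool("O")[-1] == \
        pytest.approx(ss.unlabeled["O"], rel=1e-4)
    # residual derivative at the returned state
    kO = p["K_O"] + p["K_p"] * ss.unlabeled["N"] ** p["p"]
    dO = p["r"] * p["K_N"] * ss.unlabeled["N"] - kO * ss.unlabeled["O"]
    assert abs(dO) < 1e-10


def test_steady_state_zero_input_and_wrong_model():
    ss = steady_state("interactive", {"K_N": 0.02, "K_O": 1e-4, "r": 0.4,
                                      "K_p": 0.0, "p": 1.0, "f_N": 0.0}, 0.0)
    assert ss.total == 0.0
    with pytest.raises(NotImplementedError):
        steady_state("michaelis_menten", {}, 1e-3)


def test_input_validation_and_divergence():
    p = {"K_N": 0.05, "K_O": 2e-4, "r": 0.4, "K_p": 1e-3, "p": 1.0,
         "f_N": 0.01}
    st_wrong = PoolState("conventional", {"N": 1, "L": 0, "R": 0},
                         {"N": 0, "L": 5, "R": 5})
    with pytest.raises(ValueError, match="initial state"):
        simulate("interactive", p, st_wrong, times=[0, 10])
    st = initial_pool_state("interactive", p, 10.0, 1.0)
    with pytest.raises(ValueError):
        simulate("interactive", p, st, times=[10, 5])  # unsorted
    with pytest.raises(ValueError):
        validate_params("interactive", dict(p, K_O=2.0))  # out of bounds
    # a Michaelis-Menten set whose effective uptake rate is far beyond the
    # stable step size must be flagged, not silently returned
    bad = {"V_N": 10.0, "V_O": 10.0, "K_N": 1e-3, "K_O": 1e-3,
           "mu_B": 0.9, "eps": 0.5, "f_N": 0.3, "f_B": 0.6}
    st_mm = PoolState("michaelis_menten",
                      {"N": 1.0, "O": 0.0, "B": 0.0},
                      {"N": 3.0, "O": 1.0, "B": 30.0})
    with pytest.raises(DivergenceError):
        simulate("michaelis_menten", bad, st_mm, times=np.linspace(0, 365, 5))
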