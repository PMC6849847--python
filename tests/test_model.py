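"""Simulator correctness: closed forms, conservation, oracles, invariants."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from trlkin import default_parameters
from trlkin.meals import study_day_schedule
from trlkin.model import (
    GLY_INDEX,
    LEU_INDEX,
    N_GLY,
    N_LEU,
    N_TRACEE,
    TRACEE_IDS,
    TRACEE_INDEX,
    SystemState,
    Trajectories,
    _propagate,
    aggregate_observables,
    basal_steady_state,
    build_glycerol_system,
    build_leucine_system,
    build_tracee_system,
    derivatives,
    initial_state,
    run_study,
    zero_state,
)
from trlkin.tracers import default_doses


# --- propagator against closed forms ---------------------------------------

def test_single_compartment_decays_to_e_minus_one_after_one_day():
    A = np.array([[-1.0]])  # 1 pool/day
    out = _propagate(A, np.array([10.0]), 0.0, np.array([24.0]))
    assert out[0, 0] == pytest.approx(10.0 * np.exp(-1.0), rel=1e-12)


def test_closed_two_compartment_exchange_conserves_mass():
    A = np.array([[-2.0, 3.0], [2.0, -3.0]])
    out = _propagate(A, np.array([5.0, 1.0]), 0.0, np.linspace(1, 48, 9))
    assert np.allclose(out.sum(axis=1), 6.0, rtol=1e-12)


def test_constant_input_reaches_analytic_steady_state():
    A = np.array([[-4.0]])
    u = np.array([8.0])  # per day; steady state u/k = 2
    out = _propagate(A, np.array([0.0]), 0.0, np.array([24.0 * 10]), u_const=u)
    assert out[0, 0] == pytest.approx(2.0, rel=1e-10)


# --- derivatives as a pure function -----------------------------------------

def test_null_tracer_state_is_invariant(params):
    state = initial_state(params)  # tracers all zero before the bolus
    d = derivatives(state, params, study_day_schedule("fed"), t=1.0)
    assert np.all(d.leu == 0.0)
    assert np.all(d.gly == 0.0)


def test_tracee_derivatives_vanish_at_basal_steady_state(params):
    x = basal_steady_state(params)
    state = SystemState(0.0, x, np.zeros(N_LEU), np.zeros(N_GLY), params)
    d = derivatives(state, params, study_day_schedule("fasted"), t=5.0)
    kinetic = [TRACEE_INDEX[c] for c in TRACEE_IDS]
    assert np.allclose(d.tracee[kinetic], 0.0, atol=1e-9 * np.max(x))


# --- full-model simulation properties ---------------------------------------

def test_mass_conservation_in_closed_variant():
    # all loss constants zero, equal composition ratios (no lipolytic
    # shedding), no production, no meals: total mass is conserved
    overrides = {n: 0.0 for n in (
        "k_2_0", "k_3_0", "k_5_0", "k_6_0", "k_14_0", "k_15_0",
        "k_16_0", "k_17_0", "k_18_0", "k_19_0",
        "pr_apob100_vldl1", "pr_apob100_vldl2", "basal_apob48")}
    overrides.update({n: 20.0 for n in (
        "ratio_v1_new", "ratio_v1_rem", "ratio_v2_new", "ratio_v2_rem",
        "ratio_cm_new", "ratio_cm_rem", "ratio_vldl1_b48",
        "ratio_vldl2_b48", "ratio_basal_48")})
    p = default_parameters(**overrides)
    A, _, _ = build_tracee_system(p)
    x0 = np.zeros(N_TRACEE)
    x0[TRACEE_INDEX[1]] = 100.0
    x0[TRACEE_INDEX[13]] = 40.0
    x0[TRACEE_INDEX[7]] = 2.0
    x0[TRACEE_INDEX[20]] = 0.8
    out = _propagate(A, x0, 0.0, np.linspace(0, 24, 25))
    kinetic = [TRACEE_INDEX[c] for c in TRACEE_IDS]
    totals = out[:, kinetic].sum(axis=1)
    assert np.allclose(totals, totals[0], rtol=1e-6)


def test_hepatic_subsystem_flat_under_constant_secretion_no_meal(params):
    times = np.linspace(0, 24, 13)
    traj = run_study(params, "fasted", times)
    for comps in ([1, 2, 3], [4, 5, 6], [7, 8, 9], [10, 11, 12]):
        series = traj.tracee_series(comps)
        assert np.allclose(series, series[0], rtol=1e-8)


def test_tg_mirrors_protein_in_single_ratio_special_case():
    r = 20.0
    p = default_parameters(**{n: r for n in (
        "ratio_v1_new", "ratio_v1_rem", "ratio_v2_new", "ratio_v2_rem",
        "ratio_cm_new", "ratio_cm_rem", "ratio_vldl1_b48",
        "ratio_vldl2_b48", "ratio_basal_48")})
    times = np.linspace(0, 24, 9)
    traj = run_study(p, "fed", times)
    for pc in (1, 2, 3, 4, 5, 6):
        np.testing.assert_allclose(
            traj.tracee_series(pc + 6),
            traj.tracee_series(pc) * r / 1000.0, rtol=1e-9)
    for pc in range(13, 20):
        np.testing.assert_allclose(
            traj.tracee_series(pc + 7),
            traj.tracee_series(pc) * r / 1000.0, rtol=1e-9)


def test_nonnegative_masses_and_tracer_bounds(truth_normal, study_times):
    traj = run_study(truth_normal.params, "fed", study_times)
    assert np.all(traj.tracee >= -1e-9)
    assert np.all(traj.leu >= -1e-12)
    assert np.all(traj.gly >= -1e-12)
    obs = aggregate_observables(traj)
    for name, series in obs.items():
        if name.startswith("ttr"):
            assert np.all(series >= 0.0)
            assert np.all(series <= 1.0)


def test_glycerol_label_structurally_absent_from_apob48_tg(truth_normal,
                                                           study_times):
    traj = run_study(truth_normal.params, "fed", study_times)
    for i in range(len(study_times)):
        state = traj.state_at(i)
        for cid in range(20, 27):
            assert state.tracer_by_id(cid) == 0.0
    assert not (set(range(20, 27)) & set(GLY_INDEX))


def test_meal_absorption_accumulator_matches_configured_meal(params):
    traj = run_study(params, "fed", np.array([0.0, 24.0]))
    absorbed = traj.tracee[-1, TRACEE_INDEX["abs_tg"]]
    assert absorbed == pytest.approx(0.95 * 68.5, rel=1e-12)


# --- independent ODE-solver oracle ------------------------------------------

def test_matrix_exponential_path_matches_stiff_ode_solver(truth_normal):
    """Dual-route check: exact propagation vs adaptive LSODA integration."""
    p = truth_normal.params
    schedule = study_day_schedule("fed")
    x0 = initial_state(p)
    for dose in default_doses(p["body_weight"]):
        from trlkin.tracers import apply_bolus
        x0 = apply_bolus(x0, dose)

    def pack(s):
        return np.concatenate([s.tracee, s.leu, s.gly])

    def unpack(v, t):
        return SystemState(t, v[:N_TRACEE], v[N_TRACEE:N_TRACEE + N_LEU],
                           v[N_TRACEE + N_LEU:], p)

    def rhs(t, v):
        d = derivatives(unpack(v, t), p, schedule, t)
        return pack(d) / 24.0  # rates are per day, t in hours

    t_eval = np.array([1.0, 2.5, 4.0, 6.0])
    sol = solve_ivp(rhs, (0.0, 6.0), pack(x0), method="LSODA",
                    rtol=1e-10, atol=1e-12, t_eval=t_eval, max_step=0.05)
    assert sol.success
    traj = run_study(p, "fed", t_eval)
    exact = np.concatenate([traj.tracee, traj.leu, traj.gly], axis=1)
    scale = np.max(np.abs(exact), axis=0) + 1e-9
    assert np.max(np.abs(exact - sol.y.T) / scale) < 1e-5


# --- observable aggregation --------------------------------------------------

def _toy_trajectories(params, tracee_vals, leu_vals):
    times = np.array([0.0])
    tracee = np.zeros((1, N_TRACEE))
    for cid, v in tracee_vals.items():
        tracee[0, TRACEE_INDEX[cid]] = v
    leu = np.zeros((1, N_LEU))
    for cid, v in leu_vals.items():
        leu[0, LEU_INDEX[cid]] = v
    return Trajectories(times, tracee, leu, np.zeros((1, N_GLY)), params)


def test_ttr_is_summed_tracer_over_summed_tracee(params):
    traj = _toy_trajectories(params, {16: 2.0, 17: 2.0}, {16: 0.2, 17: 0.0})
    assert traj.ttr([16, 17], [16, 17])[0] == pytest.approx(0.05)


def test_ttr_zero_when_no_tracer_and_one_when_fully_labelled(params):
    traj = _toy_trajectories(params, {16: 2.0, 17: 1.0}, {})
    assert traj.ttr([16, 17], [16, 17])[0] == 0.0
    traj = _toy_trajectories(params, {16: 3.0}, {16: 3.0})
    assert traj.ttr([16], [16])[0] == pytest.approx(1.0)


def test_tracer_with_zero_tracee_is_flagged(params):
    from trlkin.model import InconsistentStateError
    traj = _toy_trajectories(params, {}, {16: 0.5})
    with pytest.raises(InconsistentStateError):
        traj.ttr([16, 17], [16, 17])
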