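"""Non-steady-state dynamics of the integrated model and its simulator.

The governing equations are first-order mass-action kinetics over the
compartment graph: for each compartment ``i``,

    dx_i/dt = sum_j k(i,j) x_j + u_i(t) - sum_j k(j,i) x_i - k(0,i) x_i

with external inputs ``u`` from constant apoB100/basal-apoB48 secretion
and boxcar dietary-fat fluxes.  Tracer species follow the same rate
constants as tracee (trace doses do not perturb the kinetics), and label
enters the secretion-entry compartments from the terminal delay stages
with fixed route shares.  The system is therefore linear time-invariant
with piecewise-constant inputs, and trajectories are computed *exactly*
by matrix-exponential propagation over the piecewise-constant segments —
no integration tolerance is involved.  ``derivatives`` exposes the raw
right-hand side so that a general-purpose ODE solver can serve as an
independent cross-check.

State is carried in three vectors:

* tracee masses (apoB in mg, TG and dietary lipid in g) for compartments
  1-26, 48, 49, 51-53 plus three running integrals (absorbed TG,
  secreted apoB48-TG, secreted apoB48);
* d3-leucine tracer: free label in 27-33 (mg leucine) and protein-bound
  label in 1-6 and 13-19 (mg apoB equivalents) plus loss/incorporation
  accumulators;
* d5-glycerol tracer: free label in 38-41 and TG-bound label in 7-12.
  No slot exists for glycerol label in the apoB48-TG compartments 20-26:
  enterocytes lack glycerol kinase, so that label path is structurally
  zero.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import expm

from . import meals as meals_mod
from . import tracers as tracers_mod
from .meals import DaySchedule, default_previous_day, study_day_schedule
from .params import SubjectParameters, tg_transfer_efficiencies
from .structure import (
    APOB100_EDGES,
    APOB48_EDGES,
    APOB100_TG_OFFSET,
    APOB48_TG_OFFSET,
)

__all__ = [
    "SystemState",
    "Trajectories",
    "SimulationError",
    "derivatives",
    "simulate",
    "run_study",
    "initial_state",
    "aggregate_observables",
    "TG_MG_PER_MMOL",
]

#: triglyceride molar mass for mass -> mmol conversion (g per mmol)
TG_MG_PER_MMOL = 0.885


class SimulationError(RuntimeError):
    """Raised when trajectory propagation produces a non-finite state."""


class InconsistentStateError(RuntimeError):
    """Tracer present in a pool whose tracee mass is zero."""


# ---------------------------------------------------------------------------
# state-vector layouts
# ---------------------------------------------------------------------------

TRACEE_IDS: tuple[int, ...] = tuple(range(1, 27)) + (48, 49, 51, 52, 53)
ACC_ABSORBED, ACC_B48TG_SEC, ACC_B48_SEC = "abs_tg", "sec_b48tg", "sec_b48"
TRACEE_ACCS = (ACC_ABSORBED, ACC_B48TG_SEC, ACC_B48_SEC)
TRACEE_INDEX: dict[int | str, int] = {
    **{cid: i for i, cid in enumerate(TRACEE_IDS)},
    **{name: len(TRACEE_IDS) + j for j, name in enumerate(TRACEE_ACCS)},
}
N_TRACEE = len(TRACEE_INDEX)

LEU_FREE_IDS = (27, 28, 29, 30, 31, 32, 33)
LEU_PROTEIN_IDS = (1, 2, 3, 4, 5, 6, 13, 14, 15, 16, 17, 18, 19)
LEU_ACCS = ("leu_loss", "leu_inc_b48", "leu_inc_b100")
LEU_INDEX: dict[int | str, int] = {
    **{cid: i for i, cid in enumerate(LEU_FREE_IDS + LEU_PROTEIN_IDS)},
    **{name: len(LEU_FREE_IDS) + len(LEU_PROTEIN_IDS) + j
       for j, name in enumerate(LEU_ACCS)},
}
N_LEU = len(LEU_INDEX)

GLY_FREE_IDS = (38, 39, 40, 41)
GLY_TG_IDS = (7, 8, 9, 10, 11, 12)
GLY_ACCS = ("gly_loss", "gly_inc_tg")
GLY_INDEX: dict[int | str, int] = {
    **{cid: i for i, cid in enumerate(GLY_FREE_IDS + GLY_TG_IDS)},
    **{name: len(GLY_FREE_IDS) + len(GLY_TG_IDS) + j
       for j, name in enumerate(GLY_ACCS)},
}
N_GLY = len(GLY_INDEX)


# ---------------------------------------------------------------------------
# matrix assembly
# ---------------------------------------------------------------------------

def _kinetic_edge_rates(params: SubjectParameters) -> dict[tuple[int, int], float]:
    """All protein + mirrored TG edge rate constants (pools/day)."""
    rc = params.rate_constants()
    return dict(rc.values)


def _apply_kinetic_edges(A: np.ndarray, ix, params: SubjectParameters,
                         protein_edges, tg_offset: int | None,
                         rates=None, eff=None) -> None:
    """Add the linked delipidation-cascade rates to a rate matrix.

    Protein edges transfer mass fully.  When ``tg_offset`` is given the
    mirrored TG edges are added instead: the fractional outflow constant is
    identical (the linkage constraint) but transfers deliver only the TG
    transfer efficiency of that edge; the shed remainder leaves the system.
    """
    rates = rates if rates is not None else _kinetic_edge_rates(params)
    eff = eff if eff is not None else tg_transfer_efficiencies(params.ratios)
    for frm, to in protein_edges:
        k = rates[(frm, to)]
        if tg_offset is None:
            f, t = frm, to
            e = 1.0
        else:
            f = frm + tg_offset
            t = to + tg_offset if to else 0
            e = eff.get((frm, to), 1.0)
        A[ix[f], ix[f]] -= k
        if t != 0:
            A[ix[t], ix[f]] += k * e


def build_tracee_system(params: SubjectParameters):
    """Assemble (A, u_basal, e_meal) for the tracee subsystem.

    ``A`` is the rate matrix (per day), ``u_basal`` the constant input
    vector (secretion, per day) and ``e_meal`` the unit input direction of
    the dietary-fat flux (to be scaled by the boxcar flux in g/day).
    """
    ix = TRACEE_INDEX
    A = np.zeros((N_TRACEE, N_TRACEE))
    u = np.zeros(N_TRACEE)
    v = params.values

    rates = _kinetic_edge_rates(params)
    eff = tg_transfer_efficiencies(params.ratios)
    _apply_kinetic_edges(A, ix, params, APOB100_EDGES, None, rates, eff)
    _apply_kinetic_edges(A, ix, params, APOB48_EDGES, None, rates, eff)
    _apply_kinetic_edges(A, ix, params, APOB100_EDGES, APOB100_TG_OFFSET, rates, eff)
    _apply_kinetic_edges(A, ix, params, APOB48_EDGES, APOB48_TG_OFFSET, rates, eff)

    # dietary lipid routing
    r = params.routing
    s_cm, s_v1, s_v2 = r.tg_shares
    k_gut = v["k_gut"]
    k_fast, k_slow = v["k_stage_fast"], v["k_stage_slow"]
    for route_id, frac in ((49, s_cm * r.cm_fast_frac),
                           (51, s_cm * (1.0 - r.cm_fast_frac)),
                           (52, s_v1), (53, s_v2)):
        A[ix[route_id], ix[48]] += k_gut * frac
    A[ix[48], ix[48]] -= k_gut
    # staging pools release TG into the route's TG entry compartment and
    # apoB48 protein in proportion (1000/ratio converts g TG -> mg apoB48)
    r_cm, r_v1, r_v2 = r.entry_ratios
    for route_id, k_stage, tg_to, b48_to, ratio in (
        (49, k_fast, 20, 13, r_cm),
        (51, k_slow, 20, 13, r_cm),
        (52, k_fast, 23, 16, r_v1),
        (53, k_fast, 25, 18, r_v2),
    ):
        A[ix[route_id], ix[route_id]] -= k_stage
        A[ix[tg_to], ix[route_id]] += k_stage
        A[ix[b48_to], ix[route_id]] += k_stage * 1000.0 / ratio
        A[ix[ACC_B48TG_SEC], ix[route_id]] += k_stage
        A[ix[ACC_B48_SEC], ix[route_id]] += k_stage * 1000.0 / ratio

    # constant secretion inputs
    pr1, pr2 = v["pr_apob100_vldl1"], v["pr_apob100_vldl2"]
    u[ix[1]] += pr1
    u[ix[4]] += pr2
    u[ix[7]] += pr1 * v["ratio_v1_new"] / 1000.0
    u[ix[10]] += pr2 * v["ratio_v2_new"] / 1000.0
    w_cm, w_v1, w_v2 = r.apob48_shares
    basal = r.basal_apob48
    for w, b48_to, tg_to in ((w_cm, 13, 20), (w_v1, 16, 23), (w_v2, 18, 25)):
        u[ix[b48_to]] += basal * w
        u[ix[tg_to]] += basal * w * r.basal_ratio / 1000.0
    u[ix[ACC_B48_SEC]] += basal
    u[ix[ACC_B48TG_SEC]] += r.basal_apob48_tg

    e_meal = np.zeros(N_TRACEE)
    e_meal[ix[48]] = 1.0
    e_meal[ix[ACC_ABSORBED]] = 1.0
    return A, u, e_meal


def build_leucine_system(params: SubjectParameters) -> np.ndarray:
    """Rate matrix of the d3-leucine tracer subsystem (per day)."""
    ix = LEU_INDEX
    A = np.zeros((N_LEU, N_LEU))
    v = params.values

    def edge(frm, to, k):
        A[ix[frm], ix[frm]] -= k
        if to is not None:
            A[ix[to], ix[frm]] += k

    edge(27, 28, v["kleu_27_28"])
    edge(28, 27, v["kleu_28_27"])
    edge(27, 29, v["kleu_27_29"])
    edge(29, 27, v["kleu_29_27"])
    edge(27, None, v["kleu_27_0"])
    A[ix["leu_loss"], ix[27]] += v["kleu_27_0"]
    edge(27, 30, v["kleu_27_30"])
    edge(30, 31, v["delay_k_intestine"])
    edge(31, None, v["delay_k_intestine"])
    A[ix["leu_inc_b48"], ix[31]] += v["delay_k_intestine"]
    edge(27, 32, v["kleu_27_32"])
    edge(32, 33, v["delay_k_liver"])
    edge(33, None, v["delay_k_liver"])
    A[ix["leu_inc_b100"], ix[33]] += v["delay_k_liver"]

    # labelled protein enters secretion-entry compartments with fixed shares
    w_cm, w_v1, w_v2 = params.routing.apob48_shares
    a48 = v["alpha_apob48"] * v["delay_k_intestine"]
    for w, to in ((w_cm, 13), (w_v1, 16), (w_v2, 18)):
        A[ix[to], ix[31]] += a48 * w
    pr1, pr2 = v["pr_apob100_vldl1"], v["pr_apob100_vldl2"]
    f_v1 = pr1 / (pr1 + pr2) if (pr1 + pr2) > 0 else 0.5
    a100 = v["alpha_apob100"] * v["delay_k_liver"]
    A[ix[1], ix[33]] += a100 * f_v1
    A[ix[4], ix[33]] += a100 * (1.0 - f_v1)

    # bound label follows the tracee protein kinetics
    rates = _kinetic_edge_rates(params)
    eff = tg_transfer_efficiencies(params.ratios)
    _apply_kinetic_edges(A, ix, params, APOB100_EDGES, None, rates, eff)
    _apply_kinetic_edges(A, ix, params, APOB48_EDGES, None, rates, eff)
    return A


def build_glycerol_system(params: SubjectParameters) -> np.ndarray:
    """Rate matrix of the d5-glycerol tracer subsystem (per day)."""
    ix = GLY_INDEX
    A = np.zeros((N_GLY, N_GLY))
    v = params.values

    def edge(frm, to, k):
        A[ix[frm], ix[frm]] -= k
        if to is not None:
            A[ix[to], ix[frm]] += k

    edge(38, 39, v["kgly_38_39"])
    edge(39, 38, v["kgly_39_38"])
    edge(38, None, v["kgly_38_0"])
    A[ix["gly_loss"], ix[38]] += v["kgly_38_0"]
    edge(38, 40, v["kgly_38_40"])
    edge(40, 41, v["delay_k_glycerol"])
    edge(41, None, v["delay_k_glycerol"])
    A[ix["gly_inc_tg"], ix[41]] += v["delay_k_glycerol"]

    pr1 = v["pr_apob100_vldl1"] * v["ratio_v1_new"]
    pr2 = v["pr_apob100_vldl2"] * v["ratio_v2_new"]
    f_v1 = pr1 / (pr1 + pr2) if (pr1 + pr2) > 0 else 0.5
    ag = v["alpha_tg"] * v["delay_k_glycerol"]
    A[ix[7], ix[41]] += ag * f_v1
    A[ix[10], ix[41]] += ag * (1.0 - f_v1)

    # bound label follows the (shedding) apoB100-TG kinetics
    _apply_kinetic_edges(A, ix, params, APOB100_EDGES, APOB100_TG_OFFSET)
    return A


# ---------------------------------------------------------------------------
# system state and derivatives
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SystemState:
    """Masses of all compartments at one instant.

    ``tracee``, ``leu`` and ``gly`` are the three state vectors described
    in the module docstring; ``time`` is hours since the tracer bolus.
    """

    time: float
    tracee: np.ndarray
    leu: np.ndarray
    gly: np.ndarray
    params: SubjectParameters

    def tracee_by_id(self, cid: int) -> float:
        return float(self.tracee[TRACEE_INDEX[cid]])

    def tracer_by_id(self, cid: int) -> float:
        """Tracer mass in a compartment (0 for structurally label-free pools)."""
        if cid in LEU_INDEX:
            return float(self.leu[LEU_INDEX[cid]])
        if cid in GLY_INDEX:
            return float(self.gly[GLY_INDEX[cid]])
        return 0.0

    def with_tracer_added(self, cid: int, amount: float) -> "SystemState":
        if cid in LEU_INDEX:
            leu = self.leu.copy()
            leu[LEU_INDEX[cid]] += amount
            return replace(self, leu=leu)
        if cid in GLY_INDEX:
            gly = self.gly.copy()
            gly[GLY_INDEX[cid]] += amount
            return replace(self, gly=gly)
        raise KeyError(cid)


def zero_state(params: SubjectParameters, time: float = 0.0) -> SystemState:
    return SystemState(time, np.zeros(N_TRACEE), np.zeros(N_LEU),
                       np.zeros(N_GLY), params)


def derivatives(
    state: SystemState,
    params: SubjectParameters,
    schedule: DaySchedule | None,
    t: float,
) -> SystemState:
    """Pure right-hand side: rate of change of every compartment at ``t``.

    Returned as a :class:`SystemState` whose vectors hold d(mass)/dt in
    per-day units.  Used by the ODE-solver cross-checks; the production
    simulator integrates the same matrices analytically.
    """
    A_t, u, e_meal = build_tracee_system(params)
    flux = float(meals_mod.gut_input(schedule, t)) if schedule is not None else 0.0
    d_tracee = A_t @ state.tracee + u + flux * e_meal
    d_leu = build_leucine_system(params) @ state.leu
    d_gly = build_glycerol_system(params) @ state.gly
    return SystemState(t, d_tracee, d_leu, d_gly, params)


# ---------------------------------------------------------------------------
# exact piecewise-LTI propagation
# ---------------------------------------------------------------------------

def _meal_breakpoints(schedule: DaySchedule) -> list[float]:
    pts: list[float] = []
    for m in schedule.meals:
        pts.extend((m.start, m.end))
    return pts


def _propagate(
    A: np.ndarray,
    x0: np.ndarray,
    t0: float,
    out_times: np.ndarray,
    u_const: np.ndarray | None = None,
    meal_flux=None,
    breakpoints: list[float] | None = None,
) -> np.ndarray:
    """March ``dx/dt = A x + u(t)`` exactly from ``t0`` through ``out_times``.

    ``u(t) = u_const + meal_flux(t) * e_meal`` is constant between
    breakpoints; each step uses the matrix exponential of the augmented
    system ``[[A, u], [0, 0]]`` (times in hours, rates per day).
    """
    n = A.shape[0]
    out_times = np.asarray(out_times, dtype=float)
    if out_times.size == 0:
        return np.empty((0, n))
    t_end = float(out_times[-1])
    bounds = sorted({t0, t_end, *out_times.tolist(),
                     *[b for b in (breakpoints or []) if t0 < b < t_end]})
    bounds = [b for b in bounds if t0 <= b <= t_end]

    # assemble one augmented matrix per step and exponentiate as a stack
    deltas, inputs = [], []
    for ta, tb in zip(bounds[:-1], bounds[1:]):
        deltas.append((tb - ta) / 24.0)  # days
        if u_const is None and meal_flux is None:
            inputs.append(None)
        else:
            u = np.zeros(n) if u_const is None else u_const.copy()
            if meal_flux is not None:
                u = u + meal_flux(0.5 * (ta + tb))
            inputs.append(u)

    M = np.zeros((len(deltas), n + 1, n + 1))
    for i, (d, u) in enumerate(zip(deltas, inputs)):
        M[i, :n, :n] = A * d
        if u is not None:
            M[i, :n, n] = u * d
    E = expm(M)

    out_set = {round(t, 12): None for t in out_times}
    results: dict[float, np.ndarray] = {}
    x = x0.astype(float).copy()
    if round(t0, 12) in out_set:
        results[round(t0, 12)] = x.copy()
    for i, (ta, tb) in enumerate(zip(bounds[:-1], bounds[1:])):
        x = E[i, :n, :n] @ x + E[i, :n, n]
        key = round(tb, 12)
        if key in out_set:
            results[key] = x.copy()
    if not np.all(np.isfinite(x)):
        raise SimulationError("non-finite state during propagation")
    return np.stack([results[round(t, 12)] for t in out_times])


def _tracee_meal_flux_fn(schedule: DaySchedule, e_meal: np.ndarray):
    def fn(t: float) -> np.ndarray:
        return float(meals_mod.gut_input(schedule, t)) * e_meal
    return fn


def basal_steady_state(params: SubjectParameters) -> np.ndarray:
    """Tracee vector at the meal-free steady state (accumulators zero)."""
    A, u, _ = build_tracee_system(params)
    n_kin = len(TRACEE_IDS)
    x = np.zeros(N_TRACEE)
    x[:n_kin] = np.linalg.solve(A[:n_kin, :n_kin], -u[:n_kin])
    if np.any(x[:n_kin] < -1e-9):
        raise SimulationError("negative basal steady state")
    return np.clip(x, 0.0, None)


def initial_state(
    params: SubjectParameters, previous_day: DaySchedule | None = None
) -> SystemState:
    """Basal steady state carried through the previous day's meals to t = 0."""
    previous_day = previous_day or default_previous_day()
    A, u, e_meal = build_tracee_system(params)
    x0 = basal_steady_state(params)
    if previous_day.meals:
        t_start = min(m.start for m in previous_day.meals)
    else:
        t_start = -24.0
    xs = _propagate(
        A, x0, t_start, np.array([0.0]), u_const=u,
        meal_flux=_tracee_meal_flux_fn(previous_day, e_meal),
        breakpoints=_meal_breakpoints(previous_day),
    )
    x = xs[0]
    for name in TRACEE_ACCS:  # study-day accounting starts at zero
        x[TRACEE_INDEX[name]] = 0.0
    return SystemState(0.0, x, np.zeros(N_LEU), np.zeros(N_GLY), params)


@dataclass(frozen=True)
class Trajectories:
    """Time series of all state vectors on a common output grid."""

    times: np.ndarray          # hours since bolus
    tracee: np.ndarray         # (nt, N_TRACEE)
    leu: np.ndarray            # (nt, N_LEU)
    gly: np.ndarray            # (nt, N_GLY)
    params: SubjectParameters
    protocol: str = "fed"

    def state_at(self, i: int) -> SystemState:
        return SystemState(float(self.times[i]), self.tracee[i],
                           self.leu[i], self.gly[i], self.params)

    def tracee_series(self, cids) -> np.ndarray:
        cids = [cids] if isinstance(cids, (int, str)) else cids
        return sum(self.tracee[:, TRACEE_INDEX[c]] for c in cids)

    def _tracer_col(self, cid: int) -> np.ndarray:
        if cid in LEU_INDEX:
            return self.leu[:, LEU_INDEX[cid]]
        if cid in GLY_INDEX:
            return self.gly[:, GLY_INDEX[cid]]
        return np.zeros_like(self.times)

    def tracer_series(self, cid, t: np.ndarray | None = None) -> np.ndarray:
        col = (sum(self._tracer_col(c) for c in cid)
               if isinstance(cid, (list, tuple)) else self._tracer_col(cid))
        if t is None:
            return col
        t = np.atleast_1d(np.asarray(t, dtype=float))
        return np.interp(t, self.times, col, left=0.0)

    def ttr(self, tracer_cids, tracee_cids) -> np.ndarray:
        """Tracer-to-tracee ratio of a fraction (summed over compartments)."""
        num = (sum(self._tracer_col(c) for c in tracer_cids)
               if isinstance(tracer_cids, (list, tuple))
               else self._tracer_col(tracer_cids))
        den = self.tracee_series(tracee_cids)
        num = np.asarray(num, dtype=float)
        bad = (den <= 0) & (num > 1e-12)
        if np.any(bad):
            raise InconsistentStateError(
                "tracer mass present in a pool with zero tracee mass")
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        return out


def simulate(
    params: SubjectParameters,
    schedule: DaySchedule,
    doses,
    times: np.ndarray,
    x0: SystemState | None = None,
    protocol: str = "fed",
) -> Trajectories:
    """Propagate from a 0 h state through the study day.

    ``times`` must be sorted and within the study day; ``doses`` is the
    list of tracer boluses applied at t = 0.
    """
    times = np.asarray(times, dtype=float)
    if times.size and np.any(np.diff(times) < 0):
        raise ValueError("output times must be sorted")
    state = x0 if x0 is not None else initial_state(params)
    for dose in doses:
        state = tracers_mod.apply_bolus(state, dose)

    A_t, u, e_meal = build_tracee_system(params)
    X_t = _propagate(
        A_t, state.tracee, 0.0, times, u_const=u,
        meal_flux=_tracee_meal_flux_fn(schedule, e_meal),
        breakpoints=_meal_breakpoints(schedule),
    )
    X_l = _propagate(build_leucine_system(params), state.leu, 0.0, times)
    X_g = _propagate(build_glycerol_system(params), state.gly, 0.0, times)
    return Trajectories(times, X_t, X_l, X_g, params, protocol)


def run_study(
    params: SubjectParameters,
    protocol: str,
    times: np.ndarray,
    previous_day: DaySchedule | None = None,
    doses=None,
    study_schedule: DaySchedule | None = None,
) -> Trajectories:
    """Previous day + bolus + study day in one call.

    ``study_schedule`` overrides the protocol's default meal schedule
    (the standard test meal at +2 h for ``fed``, none for ``fasted``);
    ``doses`` overrides the default weight-based bolus doses.
    """
    schedule = study_schedule or study_day_schedule(protocol)
    if doses is None:
        doses = tracers_mod.default_doses(params["body_weight"])
    x0 = initial_state(params, previous_day)
    return simulate(params, schedule, doses, np.asarray(times, float),
                    x0=x0, protocol=protocol)


def integrate_study(
    params: SubjectParameters,
    protocol: str,
    previous_day: DaySchedule | None = None,
    t_end: float = 24.0,
):
    """Exact time-integrals of the tracee pools over the study day.

    Returns ``(x0, x_end, integral)`` where ``integral[i]`` is
    ``∫ x_i dt`` over [0, t_end] in mass x days (so dividing by the
    window length in days gives the time-averaged pool).  Computed by
    augmenting the propagator with running-integral states, so the result
    carries no quadrature error.
    """
    schedule = study_day_schedule(protocol)
    A, u, e_meal = build_tracee_system(params)
    x0 = initial_state(params, previous_day).tracee
    n = A.shape[0]
    bounds = sorted({0.0, t_end,
                     *[b for b in _meal_breakpoints(schedule) if 0 < b < t_end]})
    x = x0.copy()
    s = np.zeros(n)
    for ta, tb in zip(bounds[:-1], bounds[1:]):
        d = (tb - ta) / 24.0
        uu = u + float(meals_mod.gut_input(schedule, 0.5 * (ta + tb))) * e_meal
        M = np.zeros((2 * n + 1, 2 * n + 1))
        M[:n, :n] = A * d
        M[:n, n] = uu * d
        M[n + 1:, :n] = np.eye(n) * d
        E = expm(M)
        x_new = E[:n, :n] @ x + E[:n, n]
        s = s + E[n + 1:, :n] @ x + E[n + 1:, n]
        x = x_new
    return x0, x, s


# ---------------------------------------------------------------------------
# observables
# ---------------------------------------------------------------------------

#: observable series -> (kind, tracer compartments, tracee compartments)
_FRACTION_POOLS = {
    "apob48_plasma": list(range(13, 20)),
    "apob48_cm": [13, 14, 15],
    "apob48_vldl1": [16, 17],
    "apob48_vldl2": [18, 19],
    "apob100_vldl1": [1, 2, 3],
    "apob100_vldl2": [4, 5, 6],
    "tg_cm": [20, 21, 22],
    "tg_vldl1": [7, 8, 9, 23, 24],
    "tg_vldl2": [10, 11, 12, 25, 26],
    "tg_plasma": list(range(7, 13)) + list(range(20, 27)),
}


def aggregate_observables(traj: Trajectories, params: SubjectParameters | None = None):
    """Measured pools and enrichments from raw trajectories.

    Concentrations use the plasma-volume convention (0.045 L/kg): apoB in
    mg/L, triglyceride in mmol/L.  Tracer-to-tracee ratios are summed
    tracer over summed tracee per density fraction; plasma leucine
    enrichment is tracer mass over the (constant) unlabelled plasma
    leucine pool.
    """
    params = params or traj.params
    vol = params.plasma_volume
    obs: dict[str, np.ndarray] = {}

    for name, pool in _FRACTION_POOLS.items():
        mass = traj.tracee_series(pool)
        if name.startswith("tg"):
            obs[name] = mass / TG_MG_PER_MMOL / vol   # g -> mmol/L
        else:
            obs[name] = mass / vol                    # mg -> mg/L

    obs["plasma_leucine_enr"] = (
        traj.tracer_series(27) / params["leu_pool_plasma"]
    )
    obs["ttr_apob48_plasma"] = traj.ttr(list(range(13, 20)), list(range(13, 20)))
    obs["ttr_apob48_cm"] = traj.ttr([13, 14, 15], [13, 14, 15])
    obs["ttr_apob48_vldl1"] = traj.ttr([16, 17], [16, 17])
    obs["ttr_apob48_vldl2"] = traj.ttr([18, 19], [18, 19])
    obs["ttr_apob100_vldl1"] = traj.ttr([1, 2, 3], [1, 2, 3])
    obs["ttr_apob100_vldl2"] = traj.ttr([4, 5, 6], [4, 5, 6])
    # glycerol label lives only in apoB100-TG; measured VLDL TG pools also
    # contain (unlabelled) apoB48-TG, diluting the observed enrichment
    obs["ttr_tg_glycerol_vldl1"] = traj.ttr([7, 8, 9], [7, 8, 9, 23, 24])
    obs["ttr_tg_glycerol_vldl2"] = traj.ttr([10, 11, 12], [10, 11, 12, 25, 26])
    return obs
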