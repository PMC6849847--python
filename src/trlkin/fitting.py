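"""Simultaneous fitting of pool and enrichment series, and derived kinetics.

The model is fitted to all observed series at once (masses and
tracer-to-tracee ratios are coupled in a non-steady-state system, so
neither can be fitted alone).  Residuals are weighted by a proportional
error model with a per-series floor; optimization is trust-region least
squares in log-parameter space with box bounds and seeded multistart.

The derived kinetic parameters summarize each fraction over the 24 h
study day: the fractional catabolic rate FCR(F) is the time-averaged
flux leaving fraction F (irreversible catabolism plus transfer to the
next density fraction) divided by the time-averaged pool mass of F; its
irreversible part is the fractional direct catabolism FDC and its
transfer part the fractional transfer rate FTR, so FCR = FDC + FTR by
construction.  Productions are time-integrals of entry fluxes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from . import model as model_mod
from .io import TracerStudyDataset
from .meals import study_day_schedule
from .params import (
    DEFAULT_FREE_NAMES,
    SPEC_BY_NAME,
    ConfigurationError,
    SubjectParameters,
    default_parameters,
    tg_transfer_efficiencies,
)

__all__ = [
    "ObservationWeights",
    "FitConfig",
    "FitResult",
    "KineticSummary",
    "objective",
    "residuals",
    "fit_subject",
    "derive_kinetics",
    "compare_protocols",
    "TTestResult",
]

#: parameters identifiable from a fasted study (total-plasma apoB48 only)
FASTED_FREE_NAMES: tuple[str, ...] = (
    "basal_apob48", "k_14_0", "k_16_0", "k_17_0", "k_18_0", "k_19_0",
    "alpha_apob48", "leu_pool_plasma",
)


@dataclass(frozen=True)
class ObservationWeights:
    """Proportional-error weighting of squared residuals.

    The cost contribution of one observation is
    ``w * ((model - value) / max(|value|, floor))**2`` with the floor set
    to ``floor_frac`` times the series maximum (so near-zero points do not
    dominate) and ``w`` an optional per-series multiplier; the cost is
    therefore linear in the weights.
    """

    floor_frac: float = 0.02
    series_scale: dict[str, float] = field(default_factory=dict)

    def weights_for(self, series_id: str, values: np.ndarray) -> np.ndarray:
        """Per-point multipliers for the *residuals* (sqrt of the weight)."""
        floor = self.floor_frac * np.max(np.abs(values)) if values.size else 1.0
        floor = floor if floor > 0 else 1.0
        w = 1.0 / np.maximum(np.abs(values), floor)
        return w * np.sqrt(self.series_scale.get(series_id, 1.0))


@dataclass
class FitConfig:
    """Bounds, starts and budget of a subject fit."""

    free_names: tuple[str, ...] = DEFAULT_FREE_NAMES
    n_starts: int = 3
    seed: int = 0
    # trust-region iteration budget; each iteration adds a finite-difference
    # Jacobian costing one simulation per free parameter
    max_nfev: int | None = 50
    bound_expand: float = 3.0     # fit bounds = envelope widened this factor
    init: SubjectParameters | None = None
    weights: ObservationWeights = field(default_factory=ObservationWeights)
    cm_only: bool = False          # structural variant: no direct VLDL secretion

    def bounds_for(self, name: str) -> tuple[float, float]:
        spec = SPEC_BY_NAME[name]
        return spec.lo / self.bound_expand, spec.hi * self.bound_expand


@dataclass
class FitResult:
    """Outcome of a multistart subject fit."""

    estimate: SubjectParameters
    cost: float
    series_sse: dict[str, float]
    converged: bool
    n_iterations: int
    seed: int
    start_costs: tuple[float, ...] = ()
    message: str = ""


def _base_params(dataset: TracerStudyDataset,
                 config: FitConfig) -> SubjectParameters:
    base = config.init or default_parameters()
    updates = {"body_weight": dataset.body_weight}
    if config.cm_only:
        # all meal-driven secretion enters the CM fraction; VLDL apoB48 can
        # only arise through lipolytic transfer
        updates.update(tg_share_cm=1.0, tg_share_vldl1=0.0)
    return base.with_values(**updates)


class _SeriesCache:
    """Dataset series extracted to plain arrays once per fit."""

    def __init__(self, dataset: TracerStudyDataset,
                 weights: ObservationWeights):
        if not dataset.series_ids:
            raise ConfigurationError("dataset contains no series")
        self.protocol = dataset.protocol
        self.times = dataset.times()
        self.series = []
        for sid in dataset.series_ids:
            ts, values = dataset.series(sid)
            self.series.append(
                (sid, ts, values, weights.weights_for(sid, values)))

    def model_series(self, params: SubjectParameters) -> dict[str, np.ndarray]:
        traj = model_mod.run_study(params, self.protocol, self.times)
        obs = model_mod.aggregate_observables(traj)
        return {sid: np.interp(ts, self.times, obs[sid])
                for sid, ts, _, _ in self.series}

    def residuals(self, params: SubjectParameters) -> dict[str, np.ndarray]:
        model = self.model_series(params)
        return {sid: (model[sid] - values) * w
                for sid, _, values, w in self.series}


def _model_series(params: SubjectParameters, dataset: TracerStudyDataset):
    return _SeriesCache(dataset, ObservationWeights()).model_series(params)


def residuals(
    params: SubjectParameters,
    dataset: TracerStudyDataset,
    weights: ObservationWeights | None = None,
) -> dict[str, np.ndarray]:
    """Weighted residual vector per series (model minus data)."""
    return _SeriesCache(dataset, weights or ObservationWeights()).residuals(params)


def objective(
    params: SubjectParameters,
    dataset: TracerStudyDataset,
    weights: ObservationWeights | None = None,
) -> float:
    """Weighted residual sum of squares over all series simultaneously."""
    res = residuals(params, dataset, weights)
    return float(sum(np.sum(r**2) for r in res.values()))


def fit_subject(dataset: TracerStudyDataset, config: FitConfig | None = None) -> FitResult:
    """Best-of-multistart trust-region least-squares fit of one subject.

    Start 0 is the configured initial parameter set; further starts are
    log-uniform draws within the sampling envelopes.  Optimization runs in
    log-parameter space.  Reproducible given ``config.seed``.
    """
    config = config or FitConfig()
    if dataset.protocol == "fasted" and config.free_names == DEFAULT_FREE_NAMES:
        config = FitConfig(**{**config.__dict__, "free_names": FASTED_FREE_NAMES})
    base = _base_params(dataset, config)
    cache = _SeriesCache(dataset, config.weights)
    free = list(config.free_names)
    lo = np.log([config.bounds_for(n)[0] for n in free])
    hi = np.log([config.bounds_for(n)[1] for n in free])

    def to_params(x: np.ndarray) -> SubjectParameters:
        return base.with_values(**dict(zip(free, np.exp(x))))

    def fun(x: np.ndarray) -> np.ndarray:
        res = cache.residuals(to_params(x))
        return np.concatenate(list(res.values()))

    rng = np.random.default_rng(config.seed)
    x0s = [np.log([base[n] for n in free])]
    for _ in range(max(0, config.n_starts - 1)):
        draw = [np.log(np.clip(
            np.exp(rng.uniform(np.log(SPEC_BY_NAME[n].lo),
                               np.log(SPEC_BY_NAME[n].hi))),
            config.bounds_for(n)[0], config.bounds_for(n)[1]))
            for n in free]
        x0s.append(np.asarray(draw))

    best = None
    start_costs = []
    n_iter = 0
    failures = []
    for x0 in x0s:
        x0 = np.clip(x0, lo, hi)
        try:
            sol = least_squares(fun, x0, bounds=(lo, hi), method="trf",
                                max_nfev=config.max_nfev, x_scale="jac")
        except Exception as exc:  # noqa: BLE001 - collected into the result
            failures.append(str(exc))
            start_costs.append(np.inf)
            continue
        cost = 2.0 * sol.cost  # scipy reports 0.5 * sum(r^2)
        start_costs.append(cost)
        n_iter += sol.nfev
        if best is None or cost < best[0]:
            best = (cost, sol)
    if best is None:
        return FitResult(estimate=base, cost=np.inf, series_sse={},
                         converged=False, n_iterations=n_iter,
                         seed=config.seed, start_costs=tuple(start_costs),
                         message="all starts failed: " + "; ".join(failures))
    cost, sol = best
    est = to_params(sol.x)
    res = cache.residuals(est)
    return FitResult(
        estimate=est,
        cost=cost,
        series_sse={s: float(np.sum(r**2)) for s, r in res.items()},
        converged=bool(sol.status > 0),
        n_iterations=n_iter,
        seed=config.seed,
        start_costs=tuple(start_costs),
        message=sol.message,
    )


# ---------------------------------------------------------------------------
# derived kinetic parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticSummary:
    """Per-subject derived kinetic parameters.

    ApoB productions in mg/day, TG productions in g/day, FCR/FDC/FTR in
    pools/day.  ``apob48_total_fcr`` is computed on the whole-plasma
    apoB48 pool (all apoB48 compartments combined), the quantity observed
    when only total plasma can be measured.
    """

    apob48_total_prod: float
    apob48_basal_prod: float
    apob48_pp_prod: float
    apob48_total_fcr: float
    apob48_cm_fcr: float
    apob48_vldl1_fcr: float
    apob48_vldl2_fcr: float
    tg_apob48_total_prod: float
    tg_apob48_basal_prod: float
    tg_apob48_pp_prod: float
    tg_apob48_cm_fcr: float
    tg_apob48_vldl1_fcr: float
    tg_apob48_vldl2_fcr: float
    apob100_vldl1_fcr: float
    apob100_vldl1_fdc: float
    apob100_vldl1_ftr: float
    apob100_vldl1_prod: float
    apob100_vldl2_fcr: float
    apob100_vldl2_prod: float
    apob100_vldl2_dir_prod: float
    apob100_vldl_total_prod: float
    tg_apob100_vldl1_fcr: float
    tg_apob100_vldl1_fdc: float
    tg_apob100_vldl1_ftr: float
    tg_apob100_vldl1_prod: float
    tg_apob100_vldl2_fcr: float
    tg_apob100_vldl2_prod: float
    tg_apob100_vldl2_dir_prod: float
    tg_apob100_vldl_total_prod: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}

#: fraction definitions: protein compartments, transfer edges leaving the
#: fraction, loss edges
_PROTEIN_FRACTIONS = {
    "apob48_cm": ([13, 14, 15], [(14, 16), (15, 16)], [(14, 0), (15, 0)]),
    "apob48_vldl1": ([16, 17], [(16, 18)], [(16, 0), (17, 0)]),
    "apob48_vldl2": ([18, 19], [], [(18, 0), (19, 0)]),
    "apob48_total": (list(range(13, 20)), [],
                     [(14, 0), (15, 0), (16, 0), (17, 0), (18, 0), (19, 0)]),
    "apob100_vldl1": ([1, 2, 3], [(2, 4)], [(2, 0), (3, 0)]),
    "apob100_vldl2": ([4, 5, 6], [], [(5, 0), (6, 0)]),
}


def _fraction_rates(params, pools, transfers, losses, integral,
                    tg_offset=None):
    """Time-averaged (FDC, FTR) of one fraction from exact pool integrals.

    For TG fractions (``tg_offset`` set), transfers deliver only their
    efficiency; the shed remainder — including shedding on intra-fraction
    delipidation steps — is irreversible loss and counts in FDC.
    """
    rates = params.rate_constants().values
    eff = tg_transfer_efficiencies(params.ratios) if tg_offset else {}
    idx = model_mod.TRACEE_INDEX

    def pool_int(pc):
        cid = pc + tg_offset if tg_offset else pc
        return integral[idx[cid]]

    denom = sum(pool_int(c) for c in pools)
    if denom <= 0:
        raise ZeroDivisionError("zero time-averaged pool mass; FCR undefined")
    fdc = 0.0
    ftr = 0.0
    for frm, to in losses:
        fdc += rates[(frm, to)] * pool_int(frm)
    for frm, to in transfers:
        k = rates[(frm, to)]
        e = eff.get((frm, to), 1.0)
        ftr += k * e * pool_int(frm)
        fdc += k * (1.0 - e) * pool_int(frm)
    if tg_offset:
        # shedding on delipidation steps internal to the fraction
        internal = {
            (f, t) for f in pools
            for (f2, t) in rates if f2 == f and t in pools
        }
        for frm, to in internal:
            e = eff.get((frm, to), 1.0)
            fdc += rates[(frm, to)] * (1.0 - e) * pool_int(frm)
    return fdc / denom, ftr / denom


def derive_kinetics(
    params: SubjectParameters, protocol: str = "fed"
) -> "KineticSummary":
    """Table of derived kinetic parameters for one subject.

    Pools are time-averaged exactly over the 24 h study day (including
    the postprandial transient under the fed protocol).
    """
    schedule = study_day_schedule(protocol)
    # integral over exactly one day in mass x days == time-averaged pool
    _, _, integral = model_mod.integrate_study(params, protocol)

    r = params.routing
    absorbed = schedule.total_absorbed
    pp_b48 = absorbed * 1000.0 * sum(
        s / er for s, er in zip(r.tg_shares, r.entry_ratios))
    basal = r.basal_apob48

    out: dict[str, float] = {}
    out["apob48_basal_prod"] = basal
    out["apob48_pp_prod"] = pp_b48
    out["apob48_total_prod"] = basal + pp_b48
    out["tg_apob48_basal_prod"] = r.basal_apob48_tg
    out["tg_apob48_pp_prod"] = absorbed
    out["tg_apob48_total_prod"] = r.basal_apob48_tg + absorbed

    for name, (pools, transfers, losses) in _PROTEIN_FRACTIONS.items():
        fdc, ftr = _fraction_rates(params, pools, transfers, losses, integral)
        if name == "apob48_total":
            out["apob48_total_fcr"] = fdc + ftr
        elif name.startswith("apob48"):
            out[f"{name}_fcr"] = fdc + ftr
        else:
            out[f"{name}_fcr"] = fdc + ftr
            if name == "apob100_vldl1":
                out[f"{name}_fdc"], out[f"{name}_ftr"] = fdc, ftr
        if name in ("apob48_cm", "apob48_vldl1", "apob48_vldl2",
                    "apob100_vldl1", "apob100_vldl2"):
            offset = 7 if name.startswith("apob48") else 6
            fdc_t, ftr_t = _fraction_rates(params, pools, transfers, losses,
                                           integral, tg_offset=offset)
            out[f"tg_{name}_fcr"] = fdc_t + ftr_t
            if name == "apob100_vldl1":
                out["tg_apob100_vldl1_fdc"] = fdc_t
                out["tg_apob100_vldl1_ftr"] = ftr_t

    # apoB100 productions: VLDL2 receives direct secretion plus the
    # time-averaged transfer flux from VLDL1
    idx = model_mod.TRACEE_INDEX
    rates = params.rate_constants().values
    eff = tg_transfer_efficiencies(params.ratios)
    pr1, pr2 = params["pr_apob100_vldl1"], params["pr_apob100_vldl2"]
    transfer_b = rates[(2, 4)] * integral[idx[2]]
    transfer_tg = rates[(2, 4)] * eff[(2, 4)] * integral[idx[8]]
    out["apob100_vldl1_prod"] = pr1
    out["apob100_vldl2_dir_prod"] = pr2
    out["apob100_vldl2_prod"] = pr2 + transfer_b
    out["apob100_vldl_total_prod"] = pr1 + pr2
    tg1 = pr1 * params["ratio_v1_new"] / 1000.0
    tg2 = pr2 * params["ratio_v2_new"] / 1000.0
    out["tg_apob100_vldl1_prod"] = tg1
    out["tg_apob100_vldl2_dir_prod"] = tg2
    out["tg_apob100_vldl2_prod"] = tg2 + transfer_tg
    out["tg_apob100_vldl_total_prod"] = tg1 + tg2
    return KineticSummary(**out)


@dataclass(frozen=True)
class TTestResult:
    mean_difference: float
    t_statistic: float
    p_value: float
    n: int


def compare_protocols(fed, fasted) -> TTestResult:
    """Paired two-tailed t-test on basal apoB48 production (fed vs fasted).

    Accepts lists of :class:`KineticSummary` or of basal production values,
    matched by subject.
    """
    def basal(x):
        return float(getattr(x, "apob48_basal_prod", x))

    a = np.array([basal(x) for x in fed], dtype=float)
    b = np.array([basal(x) for x in fasted], dtype=float)
    if a.size != b.size:
        raise ConfigurationError("fed and fasted subject lists differ in length")
    if a.size < 2:
        raise ConfigurationError("need at least 2 paired subjects")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0.0:
        t = 0.0
        p = 1.0
    else:
        t = float(d.mean() / (sd / np.sqrt(d.size)))
        p = float(2.0 * stats.t.sf(abs(t), df=d.size - 1))
    return TTestResult(mean_difference=float(d.mean()), t_statistic=t,
                       p_value=p, n=int(d.size))
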