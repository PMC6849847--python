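"""Dietary fat input, secretion routing and the simulated previous day.

Meals are boxcar fluxes: a meal of ``fat`` grams eaten over a consumption
window delivers ``fat * absorption_fraction`` grams of triglyceride into
the intestinal-tract lipid compartment at a constant rate across the
window.  Absorption is assumed near-complete (95%) and invariant between
subjects; what varies per subject is the *timing* of appearance in plasma,
carried by the gut-emptying and staging-pool rate constants.

The ``previous day`` (three main meals plus two snacks, 100 g fat in
total) is simulated with the subject's own kinetics to produce a
physiological 0 h state containing both basally secreted apoB48 and
long-lived meal remnants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ConfigurationError, SecretionRouting, SubjectParameters

__all__ = [
    "MealEvent",
    "DaySchedule",
    "STUDY_MEAL_FAT_G",
    "default_previous_day",
    "study_day_schedule",
    "gut_input",
    "secretion_fluxes",
    "build_initial_state",
]

#: fat content of the standard mixed test meal, g
STUDY_MEAL_FAT_G = 68.5
#: test meal served 2 h after the tracer bolus, eaten within 10 min
STUDY_MEAL_START_H = 2.0
DEFAULT_WINDOW_H = 1.0 / 6.0


@dataclass(frozen=True)
class MealEvent:
    """One meal: start time (h relative to tracer bolus), fat (g)."""

    start: float
    fat: float
    consumption_window: float = DEFAULT_WINDOW_H
    absorption_fraction: float = 0.95

    def __post_init__(self) -> None:
        if self.fat < 0:
            raise ValueError("meal fat must be >= 0")
        if not (0.0 <= self.absorption_fraction <= 1.0):
            raise ValueError("absorption fraction must be in [0, 1]")
        if self.consumption_window <= 0:
            raise ValueError("consumption window must be positive")

    @property
    def end(self) -> float:
        return self.start + self.consumption_window

    @property
    def absorbed(self) -> float:
        """Total absorbed triglyceride, g."""
        return self.fat * self.absorption_fraction

    @property
    def flux(self) -> float:
        """Absorbed-TG input flux during the window, g/day."""
        return self.absorbed / (self.consumption_window / 24.0)


@dataclass(frozen=True)
class DaySchedule:
    """An ordered list of meals with a protocol label."""

    meals: tuple[MealEvent, ...]
    label: str = "study-day-fed"

    def __post_init__(self) -> None:
        labels = {"previous-day", "study-day-fed", "study-day-fasted"}
        if self.label not in labels:
            raise ValueError(f"label must be one of {sorted(labels)}")
        if self.label == "study-day-fasted" and self.meals:
            raise ValueError("a fasted study day contains no meals")
        starts = [m.start for m in self.meals]
        if starts != sorted(starts):
            raise ValueError("meals must be in chronological order")

    @property
    def total_fat(self) -> float:
        return sum(m.fat for m in self.meals)

    @property
    def total_absorbed(self) -> float:
        return sum(m.absorbed for m in self.meals)


def default_previous_day() -> DaySchedule:
    """Three main meals and two snacks totalling 100 g fat.

    Clock times 08:00, 12:00, 16:00 (snack), 19:00, 21:00 (snack) expressed
    relative to the next morning's 08:00 tracer bolus; fat split
    30/30/10/25/5 g.
    """
    times_fat = [(-24.0, 30.0), (-20.0, 30.0), (-16.0, 10.0),
                 (-13.0, 25.0), (-11.0, 5.0)]
    return DaySchedule(
        meals=tuple(MealEvent(start=t, fat=f) for t, f in times_fat),
        label="previous-day",
    )


def study_day_schedule(protocol: str) -> DaySchedule:
    """The fed (test meal at +2 h) or fasted study-day schedule."""
    if protocol == "fed":
        return DaySchedule(
            meals=(MealEvent(start=STUDY_MEAL_START_H, fat=STUDY_MEAL_FAT_G),),
            label="study-day-fed",
        )
    if protocol == "fasted":
        return DaySchedule(meals=(), label="study-day-fasted")
    raise ConfigurationError(f"unknown protocol {protocol!r}")


def gut_input(schedule: DaySchedule, t: float | np.ndarray) -> np.ndarray:
    """Dietary TG flux into the intestinal-tract compartment, g/day.

    Zero outside meal consumption windows; the time integral over each
    meal equals ``fat * absorption_fraction``.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    for m in schedule.meals:
        out = out + np.where((t >= m.start) & (t < m.end), m.flux, 0.0)
    return out


def secretion_fluxes(
    state, routing: SecretionRouting, t: float | None = None
):
    """ApoB48 and apoB48-TG entry fluxes into each density fraction.

    ``state`` is a :class:`trlkin.model.SystemState` (anything exposing
    ``tracee`` masses by compartment id).  Returns a dict keyed by route
    (``cm``, ``vldl1``, ``vldl2``) of ``(apob48_flux_mg_day,
    tg_flux_g_day)`` tuples combining the constant, meal-independent basal
    secretion with the staged meal-driven outflow of the route pools.
    """
    shares = routing.apob48_shares
    if abs(sum(shares) - 1.0) > 1e-9:  # defensive; derived shares sum to 1
        raise ConfigurationError("apoB48 route shares must sum to 1")
    params = state.params
    k_fast = params["k_stage_fast"]
    k_slow = params["k_stage_slow"]
    tg_out = {
        "cm": k_fast * state.tracee_by_id(49) + k_slow * state.tracee_by_id(51),
        "vldl1": k_fast * state.tracee_by_id(52),
        "vldl2": k_fast * state.tracee_by_id(53),
    }
    entry = dict(zip(("cm", "vldl1", "vldl2"), routing.entry_ratios))
    out = {}
    for i, route in enumerate(("cm", "vldl1", "vldl2")):
        basal_b48 = routing.basal_apob48 * shares[i]
        basal_tg = basal_b48 * routing.basal_ratio / 1000.0
        meal_tg = tg_out[route]
        meal_b48 = meal_tg * 1000.0 / entry[route]
        out[route] = (basal_b48 + meal_b48, basal_tg + meal_tg)
    return out


def build_initial_state(
    params: SubjectParameters, previous_day: DaySchedule | None = None
):
    """Simulate the previous day and return the 0 h system state.

    The apoB100 and apoB48 subsystems are first placed at their basal
    (meal-free) steady states, then the previous-day meals are layered on
    with the subject's own rate constants; the state at the end of that
    day (the moment of tracer injection) is returned.
    """
    from . import model  # deferred: model imports this module's schedules

    return model.initial_state(params, previous_day or default_previous_day())
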