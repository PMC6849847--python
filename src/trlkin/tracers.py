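"""Stable-isotope tracer doses and the precursor subsystems.

d3-leucine (7 mg per kg body weight) and d5-glycerol (a fixed 500 mg) are
injected as a bolus at t = 0.  Plasma leucine is a three-compartment
subsystem (27 injection site, 28 tissue pools, 29 interstitial fluid);
plasma glycerol a two-compartment subsystem (38 plasma, 39 rapidly
exchanging pools).  Label reaches protein and triglyceride synthesis
through two-stage delay chains: intestine 30-31 (apoB48), liver 32-33
(apoB100) and glycerol 40-41 (hepatic TG).  Label recycling from
catabolized apoB back to the precursor pools is neglected over the 24 h
study day.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ConfigurationError

__all__ = [
    "TracerDose",
    "leucine_dose",
    "glycerol_dose",
    "default_doses",
    "apply_bolus",
    "precursor_enrichment",
]

LEUCINE_MG_PER_KG = 7.0
GLYCEROL_DOSE_MG = 500.0

#: injection-site compartment per tracer
INJECTION_COMPARTMENT = {"d3-leucine": 27, "d5-glycerol": 38}

#: delay pathways: (first stage, terminal stage, stage-rate parameter name)
DELAY_PATHWAYS = {
    "intestine": (30, 31, "delay_k_intestine"),
    "liver": (32, 33, "delay_k_liver"),
    "glycerol": (40, 41, "delay_k_glycerol"),
}


@dataclass(frozen=True)
class TracerDose:
    """A bolus tracer dose given at t = 0 h."""

    tracer: str
    amount: float  # mg

    def __post_init__(self) -> None:
        if self.tracer not in INJECTION_COMPARTMENT:
            raise ConfigurationError(f"unknown tracer {self.tracer!r}")
        if not (np.isfinite(self.amount) and self.amount > 0):
            raise ValueError(f"dose must be positive, got {self.amount}")


def leucine_dose(body_weight_kg: float) -> TracerDose:
    """The weight-based d3-leucine dosing rule: 7 mg per kg."""
    return TracerDose("d3-leucine", LEUCINE_MG_PER_KG * body_weight_kg)


def glycerol_dose() -> TracerDose:
    """The invariant 500 mg d5-glycerol dose."""
    return TracerDose("d5-glycerol", GLYCEROL_DOSE_MG)


def default_doses(body_weight_kg: float) -> tuple[TracerDose, TracerDose]:
    return (leucine_dose(body_weight_kg), glycerol_dose())


def apply_bolus(state, dose: TracerDose):
    """Return a copy of ``state`` with the dose added to its injection site.

    The d3-leucine bolus enters compartment 27, the d5-glycerol bolus
    compartment 38; everything else is unchanged.
    """
    if not (np.isfinite(dose.amount) and dose.amount > 0):
        raise ValueError("bolus dose must be positive")
    return state.with_tracer_added(INJECTION_COMPARTMENT[dose.tracer], dose.amount)


def precursor_enrichment(trajectories, pathway: str, t: float | np.ndarray):
    """Label fraction of newly synthesized material at time ``t``.

    The tracer-to-tracee ratio of the terminal delay stage of the given
    pathway (``intestine`` feeds apoB48 synthesis, ``liver`` apoB100,
    ``glycerol`` hepatic TG), with the unlabelled precursor pool treated
    as a constant.  Zero before the bolus.
    """
    if pathway not in DELAY_PATHWAYS:
        raise ConfigurationError(f"unknown pathway {pathway!r}")
    _, terminal, _ = DELAY_PATHWAYS[pathway]
    t = np.asarray(t, dtype=float)
    q = trajectories.tracer_series(terminal, t)
    pool = trajectories.params["leu_pool_plasma"]
    ttr = np.clip(q / pool, 0.0, 1.0)
    return np.where(t < 0.0, 0.0, ttr)
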