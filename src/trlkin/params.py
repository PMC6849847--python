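"""Adjustable quantities of the model and the parameter-linkage rules.

All rate constants are fractional turnover rates in pools per day.  ApoB
masses are carried in mg and triglyceride (TG) masses in g, so the
TG/apoB composition ratios (mg TG per mg apoB, dimensionless) enter the
equations with a factor of 1/1000.

Parameter classes
-----------------
``kinetic``
    Per-subject fractional rate constants of the delipidation cascades.
    Each one governs a protein edge *and* its triglyceride mirror edge
    (the linkage constraint, e.g. k(0,5) = k(0,11)).
``production`` / ``ratio`` / ``secretion`` / ``timing`` / ``scale``
    Per-subject quantities: apoB100 secretion rates, TG/apoB composition
    ratios, basal apoB48 secretion, meal-appearance timing constants and
    tracer enrichment scales.
``infrastructure``
    Cohort-level constants of the tracer subsystems and meal routing that
    are held fixed across subjects (plasma leucine/glycerol exchange
    constants, delay-stage rates, route shares, absorption fraction,
    plasma-volume convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure import (
    APOB100_EDGES,
    APOB48_EDGES,
    Edge,
    ModelStructure,
    build_structure,
    edge_param_name,
)

__all__ = [
    "ParamSpec",
    "PARAM_SPECS",
    "SubjectParameters",
    "RateConstantSet",
    "CompositionRatios",
    "SecretionRouting",
    "apply_linkages",
    "default_parameters",
    "ConfigurationError",
]


class ConfigurationError(ValueError):
    """Raised when a parameter set or configuration is structurally invalid."""


@dataclass(frozen=True)
class ParamSpec:
    """Schema entry for one scalar parameter."""

    name: str
    default: float
    lo: float          # sampling envelope, low
    hi: float          # sampling envelope, high
    unit: str
    cls: str           # kinetic | production | ratio | secretion | timing | scale | infrastructure
    tier_scaled: bool = False   # True for removal/transfer rates that fall with rising plasma TG


def _k(name, default, lo, hi, tier=True):
    return ParamSpec(name, default, lo, hi, "pools/day", "kinetic", tier)


PARAM_SPECS: tuple[ParamSpec, ...] = (
    # --- apoB100 / apoB100-TG cascade (linked mirror edges) ---
    _k("k_1_2", 20.0, 4.0, 80.0),
    _k("k_1_3", 4.0, 0.8, 16.0),
    _k("k_2_4", 6.0, 1.0, 24.0),
    _k("k_2_0", 12.0, 1.5, 60.0),
    _k("k_3_0", 2.0, 0.4, 8.0),
    _k("k_4_5", 3.0, 0.8, 12.0),
    _k("k_4_6", 1.2, 0.3, 5.0),
    _k("k_5_0", 3.5, 0.8, 14.0),
    _k("k_6_0", 1.0, 0.25, 4.0),
    # --- apoB48 / apoB48-TG cascade ---
    _k("k_13_14", 150.0, 40.0, 500.0),
    _k("k_13_15", 60.0, 15.0, 250.0),
    _k("k_14_16", 8.0, 1.5, 40.0),
    _k("k_14_0", 40.0, 8.0, 160.0),
    _k("k_15_16", 2.0, 0.4, 10.0),
    _k("k_15_0", 10.0, 2.0, 40.0),
    _k("k_16_17", 1.5, 0.4, 6.0),
    _k("k_16_18", 1.5, 0.4, 6.0),
    _k("k_16_0", 1.2, 0.3, 5.0),
    _k("k_17_0", 0.8, 0.2, 3.0),
    _k("k_18_19", 1.2, 0.3, 6.0),
    _k("k_18_0", 2.5, 0.5, 12.0),
    _k("k_19_0", 0.7, 0.15, 3.0),
    # --- secretion rates (envelopes follow the development-cohort ranges) ---
    ParamSpec("pr_apob100_vldl1", 900.0, 559.0, 1080.0, "mg/day", "production"),
    ParamSpec("pr_apob100_vldl2", 270.0, 180.0, 360.0, "mg/day", "production"),
    ParamSpec("basal_apob48", 50.0, 27.3, 101.0, "mg/day", "secretion"),
    # --- TG/apoB composition ratios (mg TG per mg apoB) ---
    ParamSpec("ratio_v1_new", 29.0, 22.0, 36.0, "mg/mg", "ratio"),
    ParamSpec("ratio_v1_rem", 12.0, 5.0, 20.0, "mg/mg", "ratio"),
    ParamSpec("ratio_v2_new", 20.0, 10.0, 28.0, "mg/mg", "ratio"),
    ParamSpec("ratio_v2_rem", 8.0, 3.0, 14.0, "mg/mg", "ratio"),
    ParamSpec("ratio_cm_new", 300.0, 100.0, 800.0, "mg/mg", "ratio"),
    ParamSpec("ratio_cm_rem", 100.0, 40.0, 160.0, "mg/mg", "ratio"),
    ParamSpec("ratio_vldl1_b48", 25.0, 12.0, 40.0, "mg/mg", "ratio"),
    ParamSpec("ratio_vldl2_b48", 12.0, 6.0, 20.0, "mg/mg", "ratio"),
    # basal (fasting-state) apoB48 particles are TG-poor, VLDL-sized
    ParamSpec("ratio_basal_48", 21.0, 10.0, 50.0, "mg/mg", "ratio"),
    # --- meal appearance timing (free to vary between individuals) ---
    ParamSpec("k_gut", 30.0, 14.0, 70.0, "pools/day", "timing"),
    ParamSpec("k_stage_fast", 36.0, 14.0, 80.0, "pools/day", "timing"),
    ParamSpec("k_stage_slow", 7.0, 2.5, 20.0, "pools/day", "timing"),
    # --- tracer enrichment scales (per subject) ---
    ParamSpec("leu_pool_plasma", 3000.0, 1000.0, 10000.0, "mg", "scale"),
    ParamSpec("alpha_apob48", 0.01, 0.001, 0.1, "mg/mg", "scale"),
    ParamSpec("alpha_apob100", 0.05, 0.005, 0.5, "mg/mg", "scale"),
    ParamSpec("alpha_tg", 0.005, 0.0005, 0.05, "g/mg", "scale"),
    # --- cohort-level infrastructure constants ---
    ParamSpec("tg_share_cm", 0.97, 0.95, 0.99, "-", "infrastructure"),
    ParamSpec("tg_share_vldl1", 0.02, 0.005, 0.04, "-", "infrastructure"),
    ParamSpec("cm_fast_frac", 0.7, 0.5, 0.9, "-", "infrastructure"),
    ParamSpec("absorption_fraction", 0.95, 0.95, 0.95, "-", "infrastructure"),
    ParamSpec("plasma_volume_per_kg", 0.045, 0.045, 0.045, "L/kg", "infrastructure"),
    ParamSpec("kleu_27_28", 90.0, 45.0, 180.0, "pools/day", "infrastructure"),
    ParamSpec("kleu_28_27", 30.0, 15.0, 60.0, "pools/day", "infrastructure"),
    ParamSpec("kleu_27_29", 60.0, 30.0, 120.0, "pools/day", "infrastructure"),
    ParamSpec("kleu_29_27", 6.0, 3.0, 12.0, "pools/day", "infrastructure"),
    ParamSpec("kleu_27_0", 15.0, 7.5, 30.0, "pools/day", "infrastructure"),
    ParamSpec("kleu_27_30", 3.0, 1.5, 6.0, "pools/day", "infrastructure"),
    ParamSpec("kleu_27_32", 6.0, 3.0, 12.0, "pools/day", "infrastructure"),
    ParamSpec("delay_k_intestine", 72.0, 24.0, 288.0, "pools/day", "infrastructure"),
    ParamSpec("delay_k_liver", 72.0, 24.0, 288.0, "pools/day", "infrastructure"),
    ParamSpec("kgly_38_39", 300.0, 150.0, 600.0, "pools/day", "infrastructure"),
    ParamSpec("kgly_39_38", 150.0, 75.0, 300.0, "pools/day", "infrastructure"),
    ParamSpec("kgly_38_0", 400.0, 200.0, 800.0, "pools/day", "infrastructure"),
    ParamSpec("kgly_38_40", 50.0, 25.0, 100.0, "pools/day", "infrastructure"),
    ParamSpec("delay_k_glycerol", 96.0, 24.0, 288.0, "pools/day", "infrastructure"),
    # --- subject metadata ---
    ParamSpec("body_weight", 92.5, 85.0, 100.0, "kg", "infrastructure"),
)

SPEC_BY_NAME: dict[str, ParamSpec] = {s.name: s for s in PARAM_SPECS}
PARAM_NAMES: tuple[str, ...] = tuple(s.name for s in PARAM_SPECS)

#: parameters fitted per subject by default (everything subject-level)
DEFAULT_FREE_NAMES: tuple[str, ...] = tuple(
    s.name for s in PARAM_SPECS if s.cls != "infrastructure"
)


@dataclass(frozen=True)
class RateConstantSet:
    """Fractional rate constants per edge with linkage equalities applied."""

    values: dict[Edge, float]
    linkage_groups: dict[str, frozenset[Edge]]

    def __post_init__(self) -> None:
        arr = np.asarray(list(self.values.values()), dtype=float)
        if arr.size and (not np.all(np.isfinite(arr)) or np.any(arr < 0)):
            raise ValueError("rate constants must be finite and non-negative")

    def k(self, frm: int, to: int) -> float:
        return self.values[(frm, to)]

    def linked_ok(self) -> bool:
        return all(
            len({self.values[e] for e in grp}) == 1
            for grp in self.linkage_groups.values()
        )


@dataclass(frozen=True)
class CompositionRatios:
    """TG/apoB composition ratios (mg TG per mg apoB) per particle class."""

    r_v1_new: float
    r_v1_rem: float
    r_v2_new: float
    r_v2_rem: float
    r_cm_new: float
    r_cm_rem: float
    r_v1_48: float
    r_v2_48: float

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"ratio {name} must be positive, got {v}")
        if self.r_cm_new < self.r_cm_rem:
            raise ValueError("newly secreted chylomicrons must carry at least "
                             "as much TG per apoB48 as their remnants")


#: protein compartment -> name of the composition-ratio attribute tied to it
_RATIO_BY_COMPARTMENT = {
    1: "r_v1_new", 2: "r_v1_rem", 3: "r_v1_rem",
    4: "r_v2_new", 5: "r_v2_rem", 6: "r_v2_rem",
    13: "r_cm_new", 14: "r_cm_rem", 15: "r_cm_rem",
    16: "r_v1_48", 17: "r_v1_48", 18: "r_v2_48", 19: "r_v2_48",
}


def compartment_ratio(ratios: "CompositionRatios", cid: int) -> float:
    """TG/apoB composition ratio (mg/mg) tied to a protein compartment."""
    return getattr(ratios, _RATIO_BY_COMPARTMENT[cid])


def tg_transfer_efficiencies(ratios: "CompositionRatios") -> dict[Edge, float]:
    """Fraction of TG mass delivered along each mirrored transfer edge.

    Delipidation shrinks particles: when a transfer moves particles into a
    compartment with a lower TG/apoB ratio, only ratio(dest)/ratio(src) of
    the triglyceride follows the protein; the remainder is shed by
    lipolysis and leaves the system.  Efficiency is capped at 1 (a particle
    cannot gain core TG by transfer).  When all ratios are equal every
    efficiency is 1 and the TG subsystem mirrors the protein subsystem
    exactly.
    """
    eff: dict[Edge, float] = {}
    for frm, to in APOB100_EDGES + APOB48_EDGES:
        if to == 0:
            continue
        r_src = compartment_ratio(ratios, frm)
        r_dst = compartment_ratio(ratios, to)
        eff[(frm, to)] = min(1.0, r_dst / r_src)
    return eff


@dataclass(frozen=True)
class SecretionRouting:
    """Basal and meal-driven apoB48/TG secretion routing.

    TG shares give the split of absorbed dietary fat over the chylomicron,
    VLDL1-direct and VLDL2-direct routes.  ApoB48 shares are derived: each
    route's protein flux equals its TG flux divided by the TG/apoB48
    composition ratio of the route's entry compartment, so routes carrying
    small, TG-poor particles carry a disproportionate share of the protein.
    """

    basal_apob48: float            # mg/day
    tg_shares: tuple[float, float, float]   # CM, VLDL1, VLDL2; sum to 1
    entry_ratios: tuple[float, float, float]  # mg TG per mg apoB48 per route
    basal_ratio: float = 21.0      # mg TG per mg apoB48 of basal particles
    cm_fast_frac: float = 0.7

    def __post_init__(self) -> None:
        if abs(sum(self.tg_shares) - 1.0) > 1e-9:
            raise ConfigurationError("route TG shares must sum to 1")
        if any(s < 0 for s in self.tg_shares):
            raise ConfigurationError("route TG shares must be non-negative")

    @property
    def apob48_shares(self) -> tuple[float, float, float]:
        w = np.array(self.tg_shares) / np.array(self.entry_ratios)
        w = w / w.sum()
        return tuple(float(x) for x in w)

    @property
    def basal_apob48_tg(self) -> float:
        """Derived basal apoB48-TG secretion, g/day."""
        return float(self.basal_apob48 * self.basal_ratio / 1000.0)


@dataclass(frozen=True)
class SubjectParameters:
    """Complete per-subject parameter vector as a name -> value mapping."""

    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(PARAM_NAMES) - set(self.values)
        if missing:
            raise ConfigurationError(f"missing parameters: {sorted(missing)}")
        unknown = set(self.values) - set(PARAM_NAMES)
        if unknown:
            raise ConfigurationError(f"unknown parameters: {sorted(unknown)}")
        for name, v in self.values.items():
            if not np.isfinite(v) or v < 0:
                raise ConfigurationError(f"{name} must be finite and >= 0, got {v}")

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def with_values(self, **updates: float) -> "SubjectParameters":
        vals = dict(self.values)
        vals.update(updates)
        return SubjectParameters(vals)

    # -- derived structured views -------------------------------------------
    @property
    def ratios(self) -> CompositionRatios:
        v = self.values
        return CompositionRatios(
            r_v1_new=v["ratio_v1_new"], r_v1_rem=v["ratio_v1_rem"],
            r_v2_new=v["ratio_v2_new"], r_v2_rem=v["ratio_v2_rem"],
            r_cm_new=v["ratio_cm_new"], r_cm_rem=v["ratio_cm_rem"],
            r_v1_48=v["ratio_vldl1_b48"], r_v2_48=v["ratio_vldl2_b48"],
        )

    @property
    def routing(self) -> SecretionRouting:
        v = self.values
        s_cm = v["tg_share_cm"]
        s_v1 = v["tg_share_vldl1"]
        return SecretionRouting(
            basal_apob48=v["basal_apob48"],
            tg_shares=(s_cm, s_v1, 1.0 - s_cm - s_v1),
            entry_ratios=(v["ratio_cm_new"], v["ratio_vldl1_b48"],
                          v["ratio_vldl2_b48"]),
            basal_ratio=v["ratio_basal_48"],
            cm_fast_frac=v["cm_fast_frac"],
        )

    @property
    def plasma_volume(self) -> float:
        """Plasma volume in litres (0.045 L per kg body weight)."""
        return self.values["plasma_volume_per_kg"] * self.values["body_weight"]

    def rate_constants(self, structure: ModelStructure | None = None) -> RateConstantSet:
        """Expand the free kinetic parameters to the full linked edge set."""
        structure = structure or _canonical_structure()
        free = {edge_param_name(e): self.values[edge_param_name(e)]
                for e in APOB100_EDGES + APOB48_EDGES}
        return apply_linkages(free, structure)


_STRUCTURE_CACHE: list[ModelStructure] = []


def _canonical_structure() -> ModelStructure:
    if not _STRUCTURE_CACHE:
        _STRUCTURE_CACHE.append(build_structure())
    return _STRUCTURE_CACHE[0]


def apply_linkages(
    free_parameters: dict[str, float], structure: ModelStructure
) -> RateConstantSet:
    """Expand one value per linkage group into the full linked rate set.

    ``free_parameters`` maps the canonical group name (the protein-edge name,
    e.g. ``"k_2_0"``) to the shared fractional rate constant.  Idempotent in
    the sense that re-deriving the free values from the result and applying
    again reproduces the same set.
    """
    if not free_parameters and structure.linkage_groups:
        raise ConfigurationError("no free parameters supplied for a structure "
                                 "with linkage groups")
    values: dict[Edge, float] = {}
    for name, group in structure.linkage_groups.items():
        if name not in free_parameters:
            raise ConfigurationError(f"missing value for linkage group {name}")
        v = float(free_parameters[name])
        if v < 0 or not np.isfinite(v):
            raise ValueError(f"rate constant {name} must be >= 0, got {v}")
        for e in group:
            values[e] = v
    return RateConstantSet(values=values, linkage_groups=dict(structure.linkage_groups))


def default_parameters(**overrides: float) -> SubjectParameters:
    """A typical normolipidemic subject; keyword overrides applied on top."""
    vals = {s.name: s.default for s in PARAM_SPECS}
    vals.update(overrides)
    return SubjectParameters(vals)
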