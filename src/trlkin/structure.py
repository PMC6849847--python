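"""Compartment graph of the integrated apoB48/apoB100 lipoprotein model.

The model tracks four metabolic subsystems over a study day:

* hepatic apoB100 particles moving through delipidation chains in the
  VLDL1 (compartments 1-3) and VLDL2 (4-6) density intervals, with the
  associated triglyceride in a mirrored chain (7-12);
* intestinal apoB48 particles in chylomicrons (13-15), VLDL1 (16-17) and
  VLDL2 (18-19), again with mirrored triglyceride compartments (20-26);
* the plasma d3-leucine (27-29) and d5-glycerol (38-39) tracer subsystems
  and the synthesis delays that feed labelled protein and triglyceride
  into the secretion pathways (intestine 30-31, liver 32-33, glycerol
  40-41);
* dietary fat handling: lipid in the intestinal tract (48) and the
  secretion staging pools routing absorbed triglyceride into chylomicrons
  (49, 51) or directly into VLDL1 (52) and VLDL2 (53).

Compartment numbering follows the published schematic of the model; ids
that only appear in its (unavailable) supplementary figure are omitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

__all__ = [
    "CompartmentSpec",
    "ModelStructure",
    "build_structure",
    "write_structure",
    "read_structure",
    "APOB100_IDS",
    "APOB100_TG_IDS",
    "APOB48_IDS",
    "APOB48_TG_IDS",
    "CM_APOB48_IDS",
    "VLDL1_APOB48_IDS",
    "VLDL2_APOB48_IDS",
]

#: mirror offsets between protein and triglyceride subgraphs
APOB100_TG_OFFSET = 6
APOB48_TG_OFFSET = 7

APOB100_IDS = (1, 2, 3, 4, 5, 6)
APOB100_TG_IDS = tuple(i + APOB100_TG_OFFSET for i in APOB100_IDS)
APOB48_IDS = (13, 14, 15, 16, 17, 18, 19)
APOB48_TG_IDS = tuple(i + APOB48_TG_OFFSET for i in APOB48_IDS)

CM_APOB48_IDS = (13, 14, 15)
VLDL1_APOB48_IDS = (16, 17)
VLDL2_APOB48_IDS = (18, 19)
CM_TG_IDS = (20, 21, 22)
VLDL1_APOB48_TG_IDS = (23, 24)
VLDL2_APOB48_TG_IDS = (25, 26)
VLDL1_APOB100_IDS = (1, 2, 3)
VLDL2_APOB100_IDS = (4, 5, 6)
VLDL1_APOB100_TG_IDS = (7, 8, 9)
VLDL2_APOB100_TG_IDS = (10, 11, 12)

LEUCINE_IDS = (27, 28, 29)
GLYCEROL_IDS = (38, 39)
INTESTINE_DELAY_IDS = (30, 31)
LIVER_DELAY_IDS = (32, 33)
GLYCEROL_DELAY_IDS = (40, 41)
GUT_LIPID_ID = 48
CM_ROUTE_IDS = (49, 51)
VLDL1_ROUTE_ID = 52
VLDL2_ROUTE_ID = 53
ROUTE_IDS = (49, 51, 52, 53)

SPECIES = {
    "apoB100",
    "apoB100-TG",
    "apoB48",
    "apoB48-TG",
    "leucine",
    "glycerol",
    "dietary-lipid",
    "delay-stage",
}
FRACTIONS = {"plasma", "CM", "VLDL1", "VLDL2", "extravascular", "gut", "none"}
ROLES = {
    "secretion-entry",
    "delipidation-fast",
    "delipidation-slow",
    "slow-remnant",
    "exchange",
    "delay",
    "source",
}


@dataclass(frozen=True)
class CompartmentSpec:
    """A single compartment: id, chemical species, density fraction, role."""

    id: int
    species: str
    fraction: str
    role: str

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        if self.fraction not in FRACTIONS:
            raise ValueError(f"unknown fraction {self.fraction!r}")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")


Edge = tuple[int, int]  # (from_id, to_id); to_id == 0 is irreversible loss


@dataclass(frozen=True)
class ModelStructure:
    """The full compartment graph: compartments, transfers and losses.

    ``linkage_groups`` maps a canonical parameter name to the set of edges
    whose fractional rate constants are constrained equal (the protein /
    triglyceride mirror pairs).
    """

    compartments: tuple[CompartmentSpec, ...]
    transfers: frozenset[Edge]
    losses: frozenset[Edge]
    linkage_groups: dict[str, frozenset[Edge]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [c.id for c in self.compartments]
        if len(ids) != len(set(ids)):
            raise ValueError("compartment ids must be unique")
        known = set(ids)
        for frm, to in self.transfers:
            if frm not in known or to not in known:
                raise ValueError(f"transfer ({frm},{to}) references unknown id")
        for frm, to in self.losses:
            if frm not in known or to != 0:
                raise ValueError(f"loss ({frm},{to}) must end in 0")
        for name, group in self.linkage_groups.items():
            if not group <= self.edges:
                raise ValueError(f"linkage group {name} references unknown edge")

    @property
    def edges(self) -> frozenset[Edge]:
        return self.transfers | self.losses

    @property
    def ids(self) -> frozenset[int]:
        return frozenset(c.id for c in self.compartments)

    def compartment(self, cid: int) -> CompartmentSpec:
        for c in self.compartments:
            if c.id == cid:
                return c
        raise KeyError(cid)

    def outgoing(self, cid: int) -> set[Edge]:
        return {e for e in self.edges if e[0] == cid}


def _mirror(edges: Iterable[Edge], offset: int) -> set[Edge]:
    """Map a protein subgraph edge set onto its triglyceride mirror."""
    return {(f + offset, (t + offset) if t else 0) for f, t in edges}


# Canonical kinetic edges of the protein subgraphs.  Within VLDL1 the entry
# compartment (1) feeds a fast (2) and a slow (3) delipidation arm; the fast
# arm transfers to VLDL2 (2->4) or leaves directly (2->0); the slow arm is a
# remnant pool cleared directly.  VLDL2 repeats the motif without further
# transfer.  The apoB48 cascade adds the chylomicron stage: newly secreted
# particles (13) are rapidly delipidated to faster (14) and slower (15)
# species which transfer into VLDL1 (16) or are cleared; VLDL1 apoB48 either
# converts to a slow remnant species (17), transfers to VLDL2 (18) or is
# cleared, and VLDL2 mirrors that (18 -> 19 slow remnant).
APOB100_EDGES: tuple[Edge, ...] = (
    (1, 2), (1, 3), (2, 4), (2, 0), (3, 0),
    (4, 5), (4, 6), (5, 0), (6, 0),
)
APOB48_EDGES: tuple[Edge, ...] = (
    (13, 14), (13, 15), (14, 16), (14, 0), (15, 16), (15, 0),
    (16, 17), (16, 18), (16, 0), (17, 0),
    (18, 19), (18, 0), (19, 0),
)
LEUCINE_EDGES: tuple[Edge, ...] = (
    (27, 28), (28, 27), (27, 29), (29, 27), (27, 0),
    (27, 30), (30, 31), (31, 0),
    (27, 32), (32, 33), (33, 0),
)
GLYCEROL_EDGES: tuple[Edge, ...] = (
    (38, 39), (39, 38), (38, 0), (38, 40), (40, 41), (41, 0),
)
# Dietary lipid routing: gut lipid (48) empties into two chylomicron staging
# pools (49 fast, 51 slow) and the direct VLDL1/VLDL2 staging pools (52, 53);
# the pools release into the triglyceride entry compartments of each route.
GUT_EDGES: tuple[Edge, ...] = (
    (48, 49), (48, 51), (48, 52), (48, 53),
    (49, 20), (51, 20), (52, 23), (53, 25),
)

#: canonical free-parameter name for each protein kinetic edge
def edge_param_name(edge: Edge) -> str:
    return f"k_{edge[0]}_{edge[1]}"


def _compartments() -> tuple[CompartmentSpec, ...]:
    c: list[CompartmentSpec] = []
    roles6 = {
        0: "secretion-entry", 1: "delipidation-fast", 2: "delipidation-slow",
        3: "secretion-entry", 4: "delipidation-fast", 5: "slow-remnant",
    }
    for i, cid in enumerate(APOB100_IDS):
        frac = "VLDL1" if cid <= 3 else "VLDL2"
        c.append(CompartmentSpec(cid, "apoB100", frac, roles6[i]))
    for i, cid in enumerate(APOB100_TG_IDS):
        frac = "VLDL1" if cid <= 9 else "VLDL2"
        c.append(CompartmentSpec(cid, "apoB100-TG", frac, roles6[i]))
    roles48 = {
        13: "secretion-entry", 14: "delipidation-fast", 15: "delipidation-slow",
        16: "secretion-entry", 17: "slow-remnant",
        18: "secretion-entry", 19: "slow-remnant",
    }
    frac48 = {13: "CM", 14: "CM", 15: "CM", 16: "VLDL1", 17: "VLDL1",
              18: "VLDL2", 19: "VLDL2"}
    for cid in APOB48_IDS:
        c.append(CompartmentSpec(cid, "apoB48", frac48[cid], roles48[cid]))
    for cid in APOB48_TG_IDS:
        p = cid - APOB48_TG_OFFSET
        c.append(CompartmentSpec(cid, "apoB48-TG", frac48[p], roles48[p]))
    c.append(CompartmentSpec(27, "leucine", "plasma", "source"))
    c.append(CompartmentSpec(28, "leucine", "extravascular", "exchange"))
    c.append(CompartmentSpec(29, "leucine", "extravascular", "exchange"))
    c.append(CompartmentSpec(30, "delay-stage", "gut", "delay"))
    c.append(CompartmentSpec(31, "delay-stage", "gut", "delay"))
    c.append(CompartmentSpec(32, "delay-stage", "extravascular", "delay"))
    c.append(CompartmentSpec(33, "delay-stage", "extravascular", "delay"))
    c.append(CompartmentSpec(38, "glycerol", "plasma", "source"))
    c.append(CompartmentSpec(39, "glycerol", "extravascular", "exchange"))
    c.append(CompartmentSpec(40, "delay-stage", "extravascular", "delay"))
    c.append(CompartmentSpec(41, "delay-stage", "extravascular", "delay"))
    c.append(CompartmentSpec(48, "dietary-lipid", "gut", "source"))
    for cid in ROUTE_IDS:
        c.append(CompartmentSpec(cid, "dietary-lipid", "gut", "delay"))
    return tuple(c)


def build_structure() -> ModelStructure:
    """Return the canonical model structure (deterministic, fixed edge list)."""
    protein = set(APOB100_EDGES) | set(APOB48_EDGES)
    tg = _mirror(APOB100_EDGES, APOB100_TG_OFFSET) | _mirror(
        APOB48_EDGES, APOB48_TG_OFFSET
    )
    other = set(LEUCINE_EDGES) | set(GLYCEROL_EDGES) | set(GUT_EDGES)
    all_edges = protein | tg | other
    transfers = frozenset(e for e in all_edges if e[1] != 0)
    losses = frozenset(e for e in all_edges if e[1] == 0)

    groups: dict[str, frozenset[Edge]] = {}
    for e in APOB100_EDGES:
        m = (e[0] + APOB100_TG_OFFSET, (e[1] + APOB100_TG_OFFSET) if e[1] else 0)
        groups[edge_param_name(e)] = frozenset({e, m})
    for e in APOB48_EDGES:
        m = (e[0] + APOB48_TG_OFFSET, (e[1] + APOB48_TG_OFFSET) if e[1] else 0)
        groups[edge_param_name(e)] = frozenset({e, m})

    return ModelStructure(
        compartments=_compartments(),
        transfers=transfers,
        losses=losses,
        linkage_groups=groups,
    )


def write_structure(structure: ModelStructure, path: str | Path) -> None:
    """Export the graph as a plain-text edge table.

    One row per edge: ``from_id  to_id  linkage_group  kind``, tab separated,
    with ``-`` for edges outside any linkage group.
    """
    edge_group = {}
    for name, group in structure.linkage_groups.items():
        for e in group:
            edge_group[e] = name
    lines = ["from_id\tto_id\tlinkage_group\tkind"]
    for frm, to in sorted(structure.edges):
        kind = "loss" if to == 0 else "transfer"
        lines.append(f"{frm}\t{to}\t{edge_group.get((frm, to), '-')}\t{kind}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_structure(path: str | Path) -> ModelStructure:
    """Re-import an edge table written by :func:`write_structure`.

    Compartment metadata is taken from the canonical structure; the edge set
    and linkage groups come from the file and are validated against it.
    """
    canonical = build_structure()
    transfers: set[Edge] = set()
    losses: set[Edge] = set()
    groups: dict[str, set[Edge]] = {}
    lines = Path(path).read_text().strip().splitlines()
    if lines[0].split("\t") != ["from_id", "to_id", "linkage_group", "kind"]:
        raise ValueError("bad structure table header")
    for line in lines[1:]:
        frm_s, to_s, grp, kind = line.split("\t")
        edge = (int(frm_s), int(to_s))
        if kind == "loss":
            losses.add(edge)
        elif kind == "transfer":
            transfers.add(edge)
        else:
            raise ValueError(f"unknown edge kind {kind!r}")
        if grp != "-":
            groups.setdefault(grp, set()).add(edge)
    return ModelStructure(
        compartments=canonical.compartments,
        transfers=frozenset(transfers),
        losses=frozenset(losses),
        linkage_groups={k: frozenset(v) for k, v in groups.items()},
    )
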