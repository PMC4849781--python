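"""Compartmentalized metabolic network representation.

A :class:`Network` bundles compartments, metabolites and reactions together
with the cell number used to scale per-cell fluxes (mmol·cell⁻¹·min⁻¹) into
concentration derivatives (mM·min⁻¹).  Carbon atom-transition maps attached
to reactions drive ¹³C label propagation; they are kept separate from the
stoichiometry so that "invisible" reactions (label exchange with zero net
stoichiometric change) are expressible.

Carbon positions are 1-based, following biochemical nomenclature (C1 is the
carbonyl end of a sugar).  Atom-map slots identify individual molecule
instances of a species in a reaction as ``met#k`` (k = 1..stoichiometric
coefficient).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Compartment",
    "Metabolite",
    "AtomTransitionMap",
    "Reaction",
    "Network",
    "NetworkError",
    "stoichiometric_matrix",
    "validate_atom_maps",
]


class NetworkError(ValueError):
    """Raised when a network definition is inconsistent."""


@dataclass(frozen=True)
class Compartment:
    id: str
    name: str = ""
    volume: float = 1.0  # litres

    def __post_init__(self):
        if not self.volume > 0:
            raise NetworkError(f"compartment {self.id!r}: volume must be > 0")


@dataclass(frozen=True)
class Metabolite:
    id: str
    compartment: str
    name: str = ""
    n_carbons: int = 0
    labelable: bool = False
    constant: bool = False
    initial_concentration: float = 0.0  # mM

    def __post_init__(self):
        if self.n_carbons < 0:
            raise NetworkError(f"metabolite {self.id!r}: negative carbon count")
        if self.labelable and self.n_carbons < 1:
            raise NetworkError(
                f"metabolite {self.id!r}: labelable species need >= 1 carbon"
            )
        if self.initial_concentration < 0:
            raise NetworkError(
                f"metabolite {self.id!r}: negative initial concentration"
            )


@dataclass(frozen=True)
class Slot:
    """One molecule instance of a species on one side of a reaction."""

    met: str
    occurrence: int = 1  # 1-based

    def __str__(self) -> str:  # "met#1"
        return f"{self.met}#{self.occurrence}"

    @classmethod
    def parse(cls, text: str) -> "Slot":
        if "#" in text:
            met, occ = text.split("#", 1)
            return cls(met, int(occ))
        return cls(text, 1)


@dataclass
class AtomTransitionMap:
    """Mapping (substrate slot, carbon) -> (product slot, carbon).

    Carbons of non-labelable species are left unmapped; carbons that leave
    the labelable universe (e.g. the CO₂ released by decarboxylation when
    CO₂ is declared non-labelable) are simply absent from the map.
    """

    entries: dict[tuple[Slot, int], tuple[Slot, int]] = field(default_factory=dict)

    def add(self, sub: Slot | str, sc: int, prod: Slot | str, pc: int) -> None:
        if isinstance(sub, str):
            sub = Slot.parse(sub)
        if isinstance(prod, str):
            prod = Slot.parse(prod)
        self.entries[(sub, sc)] = (prod, pc)

    def inverted(self) -> "AtomTransitionMap":
        inv = AtomTransitionMap()
        for (s, sc), (p, pc) in self.entries.items():
            inv.entries[(p, pc)] = (s, sc)
        return inv

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class Reaction:
    id: str
    substrates: list[tuple[str, int]]
    products: list[tuple[str, int]]
    name: str = ""
    reversible: bool = False
    invisible: bool = False
    atom_map: AtomTransitionMap | None = None
    kinetic_law: str | None = None  # key into the kinetics registry

    def __post_init__(self):
        for side in (self.substrates, self.products):
            for met, coef in side:
                if not (isinstance(coef, (int, np.integer)) and coef > 0):
                    raise NetworkError(
                        f"reaction {self.id!r}: stoichiometric coefficient of "
                        f"{met!r} must be a positive integer, got {coef!r}"
                    )

    def slots(self, side: str) -> list[Slot]:
        pairs = self.substrates if side == "substrates" else self.products
        out = []
        for met, coef in pairs:
            out.extend(Slot(met, k + 1) for k in range(coef))
        return out


@dataclass
class Network:
    compartments: list[Compartment]
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    ncell: float = 1.0
    symmetric_metabolites: set[str] = field(default_factory=set)
    name: str = "network"

    def __post_init__(self):
        self.validate()

    # -- lookups -----------------------------------------------------------
    @property
    def compartment_index(self) -> dict[str, Compartment]:
        return {c.id: c for c in self.compartments}

    @property
    def metabolite_index(self) -> dict[str, Metabolite]:
        return {m.id: m for m in self.metabolites}

    @property
    def reaction_index(self) -> dict[str, Reaction]:
        return {r.id: r for r in self.reactions}

    def metabolite(self, mid: str) -> Metabolite:
        return self.metabolite_index[mid]

    def volume_of(self, mid: str) -> float:
        return self.compartment_index[self.metabolite(mid).compartment].volume

    @property
    def dynamic_metabolites(self) -> list[Metabolite]:
        return [m for m in self.metabolites if not m.constant]

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        if not self.ncell > 0:
            raise NetworkError("ncell must be > 0")
        for coll, label in (
            (self.compartments, "compartment"),
            (self.metabolites, "metabolite"),
            (self.reactions, "reaction"),
        ):
            ids = [x.id for x in coll]
            dupes = {i for i in ids if ids.count(i) > 1}
            if dupes:
                raise NetworkError(f"duplicate {label} ids: {sorted(dupes)}")
        comp_ids = {c.id for c in self.compartments}
        met_ids = {m.id for m in self.metabolites}
        for m in self.metabolites:
            if m.compartment not in comp_ids:
                raise NetworkError(
                    f"metabolite {m.id!r} references unknown compartment "
                    f"{m.compartment!r}"
                )
        for r in self.reactions:
            for met, _ in r.substrates + r.products:
                if met not in met_ids:
                    raise NetworkError(
                        f"reaction {r.id!r} references unknown metabolite {met!r}"
                    )
        for mid in self.symmetric_metabolites:
            if mid not in met_ids:
                raise NetworkError(f"symmetric metabolite {mid!r} not declared")
        if not any(not m.constant for m in self.metabolites):
            raise NetworkError("network needs at least one non-constant metabolite")
        # invisible reactions must have zero net stoichiometry
        for r in self.reactions:
            if r.invisible:
                net: dict[str, int] = {}
                for met, coef in r.substrates:
                    net[met] = net.get(met, 0) - coef
                for met, coef in r.products:
                    net[met] = net.get(met, 0) + coef
                if any(v != 0 for v in net.values()):
                    raise NetworkError(
                        f"invisible reaction {r.id!r} has non-zero net stoichiometry"
                    )


def stoichiometric_matrix(net: Network) -> np.ndarray:
    """Net stoichiometric matrix N (metabolites × reactions).

    Rows of constant (boundary) metabolites are zeroed and invisible
    reactions contribute an all-zero column, so ``N @ j`` gives the net
    molar production rate of every dependent species.
    """
    met_pos = {m.id: i for i, m in enumerate(net.metabolites)}
    N = np.zeros((len(net.metabolites), len(net.reactions)))
    for j, r in enumerate(net.reactions):
        if r.invisible:
            continue
        for met, coef in r.substrates:
            N[met_pos[met], j] -= coef
        for met, coef in r.products:
            N[met_pos[met], j] += coef
    for m in net.metabolites:
        if m.constant:
            N[met_pos[m.id], :] = 0.0
    return N


def validate_atom_maps(net: Network) -> list[str]:
    """Check every atom map for carbon balance and bijectivity.

    Returns a list of human-readable violations; empty iff all maps are
    consistent.  Only carbons of labelable species participate: a labelable
    substrate must have every carbon mapped exactly once onto a labelable
    product carbon, and every labelable product carbon must be covered by
    exactly one substrate carbon *unless* the reaction has no labelable
    substrates at all (pure unlabelled inflow).
    """
    issues: list[str] = []
    mets = net.metabolite_index
    for r in net.reactions:
        if r.atom_map is None:
            continue
        sub_slots = [s for s in r.slots("substrates") if mets[s.met].labelable]
        prod_slots = [s for s in r.slots("products") if mets[s.met].labelable]
        sink_slots = {s for s in r.slots("products") if not mets[s.met].labelable}
        wanted_sub = {
            (s, c) for s in sub_slots for c in range(1, mets[s.met].n_carbons + 1)
        }
        wanted_prod = {
            (s, c) for s in prod_slots for c in range(1, mets[s.met].n_carbons + 1)
        }
        seen_prod: dict[tuple[Slot, int], tuple[Slot, int]] = {}
        for (s, sc), (p, pc) in r.atom_map.entries.items():
            if (s, sc) not in wanted_sub:
                issues.append(
                    f"{r.id}: maps carbon {s}.{sc} which is not a labelable "
                    "substrate carbon"
                )
                continue
            if p in sink_slots:
                # carbon leaves the labelable universe (e.g. CO₂ declared
                # non-labelable); bijectivity is checked over labelable
                # species only
                continue
            if (p, pc) not in wanted_prod:
                issues.append(
                    f"{r.id}: carbon {s}.{sc} routed to {p}.{pc} which is not "
                    "a labelable product carbon"
                )
                continue
            if (p, pc) in seen_prod:
                issues.append(f"{r.id}: product carbon {p}.{pc} mapped twice")
            seen_prod[(p, pc)] = (s, sc)
        mapped_sub = {k for k in r.atom_map.entries if k in wanted_sub}
        for missing in sorted(wanted_sub - mapped_sub, key=str):
            issues.append(
                f"{r.id}: unmapped substrate carbon {missing[0]}.{missing[1]}"
            )
        if wanted_sub:  # unlabelled-inflow reactions may leave products m0
            for missing in sorted(wanted_prod - set(seen_prod), key=str):
                issues.append(
                    f"{r.id}: unmapped product carbon {missing[0]}.{missing[1]}"
                )
    return issues


def labelable_closure(net: Network, sources: Iterable[str]) -> set[str]:
    """Metabolite ids reachable by carbon flow from ``sources``.

    Used to skip isotopomer bookkeeping for species that can never receive
    labelled carbon from the tracer substrates.
    """
    reach = set(sources)
    edges: list[tuple[str, str]] = []
    for r in net.reactions:
        if r.atom_map is None:
            continue
        for (s, _), (p, _) in r.atom_map.entries.items():
            edges.append((s.met, p.met))
            if r.reversible or r.invisible:
                edges.append((p.met, s.met))
    changed = True
    while changed:
        changed = False
        for a, b in edges:
            if a in reach and b not in reach:
                reach.add(b)
                changed = True
    return {m for m in reach if net.metabolite_index[m].labelable}
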