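"""Small test-fixture networks with analytic or brute-force-checkable
behaviour.

All toys use unit cell number and unit compartment volume, so mass-action
constants are plain first-order rates in min⁻¹ and per-cell fluxes equal
concentration rates.
"""

from __future__ import annotations

from ..kinetics import (KineticModel, MassAction, ParameterGroups, ParameterSet,
                        ReversibleMassAction)
from ..network import (AtomTransitionMap, Compartment, Metabolite, Network,
                       Reaction)

__all__ = ["make_toy", "TOY_NAMES"]

TOY_NAMES = ("chain3", "loop_exchange", "symmetric_krebs_stub",
             "degenerate_pair")


def _identity_map(met_a: str, met_b: str, n: int) -> AtomTransitionMap:
    amap = AtomTransitionMap()
    for c in range(1, n + 1):
        amap.add(f"{met_a}#1", c, f"{met_b}#1", c)
    return amap


def _chain3() -> KineticModel:
    """A → B → C → (sink); 3 carbons, identity maps.

    A is a constant feed pool, so the label wash-in of B against its
    balanced drain follows the first-order closed form
    1 − exp(−k·A·t/B₀) when B starts at its steady state.
    """
    comp = [Compartment("c", "cell", 1.0)]
    mets = [
        Metabolite("A", "c", n_carbons=3, labelable=True, constant=True,
                   initial_concentration=1.0),
        # B and C start at their metabolic steady states (k1·A/k2, k1·A/k3)
        # so totals stay constant and label wash-in is exactly first order
        Metabolite("B", "c", n_carbons=3, labelable=True,
                   initial_concentration=0.625),
        Metabolite("C", "c", n_carbons=3, labelable=True,
                   initial_concentration=0.05 / 0.06),
        Metabolite("OUT", "c", constant=True),
    ]
    sink = AtomTransitionMap()
    for c in range(1, 4):
        sink.add("C#1", c, "OUT#1", c)
    rxns = [
        Reaction("r1", [("A", 1)], [("B", 1)],
                 atom_map=_identity_map("A", "B", 3)),
        Reaction("r2", [("B", 1)], [("C", 1)],
                 atom_map=_identity_map("B", "C", 3)),
        Reaction("r3", [("C", 1)], [("OUT", 1)], atom_map=sink),
    ]
    net = Network(comp, mets, rxns, ncell=1.0, name="chain3")
    true_k = {"r1.k": 0.05, "r2.k": 0.08, "r3.k": 0.06}
    laws = {
        "r1": MassAction("r1", [("A", 1)]),
        "r2": MassAction("r2", [("B", 1)]),
        "r3": MassAction("r3", [("C", 1)]),
    }
    groups = ParameterGroups(
        [
            ("k1", [("r1.k", true_k["r1.k"])]),
            ("k2", [("r2.k", true_k["r2.k"])]),
            ("k3", [("r3.k", true_k["r3.k"])]),
        ]
    )
    return KineticModel(net, laws, ParameterSet(true_k), groups)


def _loop_exchange() -> KineticModel:
    """Two pools joined only by an invisible exchange reaction.

    Totals of A and B are constant while the carbon skeletons swap, so
    label mixes between the pools with zero net flux.
    """
    comp = [Compartment("c", "cell", 1.0)]
    mets = [
        Metabolite("A", "c", n_carbons=2, labelable=True,
                   initial_concentration=1.0),
        Metabolite("B", "c", n_carbons=2, labelable=True,
                   initial_concentration=2.0),
    ]
    amap = AtomTransitionMap()
    for c in (1, 2):
        amap.add("A#1", c, "B#1", c)
        amap.add("B#1", c, "A#1", c)
    rxns = [
        Reaction("exch", [("A", 1), ("B", 1)], [("A", 1), ("B", 1)],
                 invisible=True, atom_map=amap),
    ]
    net = Network(comp, mets, rxns, ncell=1.0, name="loop_exchange")
    laws = {"exch": MassAction("exch", [("A", 1), ("B", 1)])}
    params = ParameterSet({"exch.k": 0.2})
    groups = ParameterGroups([("exch", [("exch.k", 0.2)])])
    return KineticModel(net, laws, params, groups)


def _symmetric_krebs_stub() -> KineticModel:
    """SRC → fumarate (symmetric) → malate → (sink), 4 carbons.

    Fumarate's rotational symmetry scrambles C1↔C4 and C2↔C3, so a
    C1-labelled feed yields malate labelled 50/50 at C1 and C4.
    """
    comp = [Compartment("c", "cell", 1.0)]
    mets = [
        Metabolite("SRC", "c", n_carbons=4, labelable=True, constant=True,
                   initial_concentration=1.0),
        Metabolite("fum", "c", n_carbons=4, labelable=True,
                   initial_concentration=0.5),
        Metabolite("mal", "c", n_carbons=4, labelable=True,
                   initial_concentration=0.5),
        Metabolite("OUT", "c", constant=True),
    ]
    sink = AtomTransitionMap()
    for c in range(1, 5):
        sink.add("mal#1", c, "OUT#1", c)
    rxns = [
        Reaction("feed", [("SRC", 1)], [("fum", 1)],
                 atom_map=_identity_map("SRC", "fum", 4)),
        Reaction("fh", [("fum", 1)], [("mal", 1)],
                 atom_map=_identity_map("fum", "mal", 4)),
        Reaction("out", [("mal", 1)], [("OUT", 1)], atom_map=sink),
    ]
    net = Network(comp, mets, rxns, ncell=1.0,
                  symmetric_metabolites={"fum"}, name="symmetric_krebs_stub")
    laws = {
        "feed": MassAction("feed", [("SRC", 1)]),
        "fh": MassAction("fh", [("fum", 1)]),
        "out": MassAction("out", [("mal", 1)]),
    }
    params = ParameterSet({"feed.k": 0.1, "fh.k": 0.5, "out.k": 0.2})
    groups = ParameterGroups([("feed", [("feed.k", 0.1)]),
                              ("fh", [("fh.k", 0.5)]),
                              ("out", [("out.k", 0.2)])])
    return KineticModel(net, laws, params, groups)


def _degenerate_pair() -> KineticModel:
    """Structural non-identifiability fixture.

    A (constant) ↔ B with linear exchange capacity k₁, then B → C with
    rate k₂·[B] where k₂ ≫ k₁, so B is a fast quasi-steady trace pool and
    the accumulation of C depends on the capacities only through the
    harmonic combination k₁k₂/(k₁+k₂) ≈ k₁.  Measuring C alone therefore
    bounds the downstream capacity k₂ from below but not from above: its
    profile is flat upward.
    """
    comp = [Compartment("c", "cell", 1.0)]
    mets = [
        Metabolite("A", "c", constant=True, initial_concentration=0.5),
        # B starts at its quasi-steady level k1·A/(k1+k2)
        Metabolite("B", "c", initial_concentration=0.005),
        Metabolite("C", "c", initial_concentration=0.0),
    ]
    rxns = [
        Reaction("r1", [("A", 1)], [("B", 1)], reversible=True),
        Reaction("r2", [("B", 1)], [("C", 1)]),
    ]
    net = Network(comp, mets, rxns, ncell=1.0, name="degenerate_pair")
    laws = {
        "r1": ReversibleMassAction("r1", ["A"], ["B"]),
        "r2": MassAction("r2", [("B", 1)]),
    }
    params = ParameterSet({"r1.k": 0.1, "r1.keq": 1.0, "r2.k": 10.0})
    groups = ParameterGroups([("k1", [("r1.k", 0.1)]),
                              ("k2", [("r2.k", 10.0)])])
    return KineticModel(net, laws, params, groups)


_BUILDERS = {
    "chain3": _chain3,
    "loop_exchange": _loop_exchange,
    "symmetric_krebs_stub": _symmetric_krebs_stub,
    "degenerate_pair": _degenerate_pair,
}


def make_toy(name: str) -> KineticModel:
    """Build a named toy network with its true parameter set."""
    try:
        return _BUILDERS[name]()
    except KeyError:
        raise ValueError(
            f"unknown toy {name!r}; available: {sorted(_BUILDERS)}"
        ) from None
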