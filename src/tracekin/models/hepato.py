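"""Reduced hepatocyte glucose/fructose demonstration model.

A ~35-reaction network over three compartments (extracellular medium,
cytosol, mitochondria) covering glucose transport and phosphorylation into
two channelled hexose-phosphate pools (*a*, glycolysis-oriented; *b*,
glycogen-oriented), the three net aldolase reactions, the fructose pathway
(low-affinity transport, fructokinase, triokinase), lower glycolysis to
lactate export, the glycogen branch, and a closed energy subsystem
(ATP/ADP/AMP with adenylate kinase, an ATPase load, inorganic-phosphate
transport and a lumped saturable mitochondrial ATP regeneration standing in
for the respiratory chain + adenine translocator block).

The parameterization is a hand-tuned reduction, not the published full
model: capacities are chosen so that with 20 mM glucose + 3 mM fructose the
cell accumulates glycogen at roughly steady energy charge, while with
20 mM fructose the unregulated fructokinase flux accumulates fructose
1-phosphate, sequesters phosphate, throttles oxidative ATP regeneration and
depletes cytosolic ATP and Pi — suppressing glycogen synthesis and the
propagation of glucose carbon to lactate.  Only directional agreement with
the measured phenotype is claimed.

Units: concentrations mM; capacities mmol·cell⁻¹·min⁻¹ (the ``_percell``
helper converts an intended cytosolic mM·min⁻¹ rate); volumes litres.

Uridine nucleotides are folded into the adenine pool (UDP-glucose
formation consumes ATP and glycogen synthase releases ADP), which keeps the
adenine and phosphate moieties closed without a separate uracil subsystem.
Excluded branches (pentose phosphate pathway, Krebs cycle, fatty acid and
glutamate metabolism) mean glutamate observables are not available.
"""

from __future__ import annotations

from typing import Mapping

from ..experiments import Condition, Observable
from ..kinetics import (Glucokinase, Hill, KineticModel, KineticsError,
                        MassAction, MichaelisMenten, ParameterGroups,
                        ParameterSet, RateLaw, ReversibleMassAction,
                        ReversibleMichaelisMenten)
from ..network import (AtomTransitionMap, Compartment, Metabolite, Network,
                       Reaction)

__all__ = ["make_demo_model", "condition_library", "demo_observables",
           "NCELL", "VOL_EXT", "VOL_CYT", "VOL_MITO"]

NCELL = 1.0e7  # cells per incubation
VOL_EXT = 2.0e-3  # litres of medium
VOL_CYT = 4.0e-5  # litres of total cytosol
VOL_MITO = 1.0e-5  # litres of total mitochondrial matrix


def _percell(mM_per_min: float) -> float:
    """Capacity (mmol·cell⁻¹·min⁻¹) giving this cytosolic rate in mM·min⁻¹."""
    return mM_per_min * VOL_CYT / NCELL


def _identity(a: str, b: str, n: int) -> AtomTransitionMap:
    m = AtomTransitionMap()
    for c in range(1, n + 1):
        m.add(f"{a}#1", c, f"{b}#1", c)
    return m


def _metabolites() -> list[Metabolite]:
    E, C, M = "ext", "cyt", "mito"

    def met(mid, comp, nC=0, init=0.0, constant=False, name=""):
        return Metabolite(mid, comp, name=name, n_carbons=nC,
                          labelable=nC > 0, constant=constant,
                          initial_concentration=init)

    return [
        met("eGlc", E, 6, 20.0, name="medium glucose"),
        met("eFru", E, 6, 3.0, name="medium fructose"),
        met("eLac", E, 3, 0.5, name="medium lactate"),
        met("ePi", E, 0, 1.2, constant=True, name="medium phosphate"),
        met("cGlc", C, 6, 1.0, name="cytosolic glucose"),
        met("G6Pa", C, 6, 0.10, name="glucose 6-phosphate, pool a"),
        met("G6Pb", C, 6, 0.10, name="glucose 6-phosphate, pool b"),
        met("F6Pa", C, 6, 0.04, name="fructose 6-phosphate, pool a"),
        met("F6Pb", C, 6, 0.04, name="fructose 6-phosphate, pool b"),
        met("FBPa", C, 6, 0.02, name="fructose 1,6-bisphosphate, pool a"),
        met("FBPb", C, 6, 0.02, name="fructose 1,6-bisphosphate, pool b"),
        met("cFru", C, 6, 0.01, name="cytosolic fructose"),
        met("Fru1P", C, 6, 0.02, name="fructose 1-phosphate"),
        met("Gra", C, 3, 0.01, name="glyceraldehyde"),
        met("DHAP", C, 3, 0.04, name="dihydroxyacetone phosphate"),
        met("GAP", C, 3, 0.02, name="glyceraldehyde 3-phosphate"),
        met("BPG", C, 3, 0.005, name="1,3-bisphosphoglycerate"),
        met("PG3", C, 3, 0.20, name="3-phosphoglycerate"),
        met("PG2", C, 3, 0.03, name="2-phosphoglycerate"),
        met("PEP", C, 3, 0.10, name="phosphoenolpyruvate"),
        met("Pyr", C, 3, 0.10, name="pyruvate"),
        met("cLac", C, 3, 0.5, name="cytosolic lactate"),
        met("G1P", C, 6, 0.03, name="glucose 1-phosphate"),
        met("UDPG", C, 6, 0.30, name="UDP-glucose (glucosyl donor)"),
        met("Glyc", C, 6, 1.0, name="glycogen (glucosyl units)"),
        met("cATP", C, 0, 3.0, name="cytosolic ATP"),
        met("cADP", C, 0, 1.0, name="cytosolic ADP"),
        met("cAMP", C, 0, 0.3, name="cytosolic AMP"),
        met("cPi", C, 0, 5.0, name="cytosolic phosphate"),
        met("PPi", C, 0, 0.01, name="pyrophosphate"),
        met("mPi", M, 0, 10.0, name="mitochondrial phosphate"),
    ]


def _reactions_and_laws() -> tuple[list[Reaction], dict[str, RateLaw],
                                   ParameterSet]:
    rxns: list[Reaction] = []
    laws: dict[str, RateLaw] = {}
    params: dict[str, float] = {}

    def add(rid, subs, prods, law, p, reversible=False, amap=None, name=""):
        rxns.append(Reaction(rid, subs, prods, name=name,
                             reversible=reversible, atom_map=amap))
        laws[rid] = law
        for k, v in p.items():
            params[f"{rid}.{k}"] = v

    # --- glucose entry and the two hexose-phosphate pools -----------------
    add("glctr", [("eGlc", 1)], [("cGlc", 1)],
        ReversibleMichaelisMenten("glctr", ["eGlc"], ["cGlc"]),
        {"Vmax": _percell(4.0), "Km_eGlc": 17.0, "Km_cGlc": 17.0, "keq": 1.0},
        reversible=True, amap=_identity("eGlc", "cGlc", 6),
        name="glucose transport (GLUT2)")
    for pool, vgk, vg6p in (("a", 0.70, 0.10), ("b", 0.50, 0.06)):
        add(f"gk{pool}", [("cGlc", 1), ("cATP", 1)],
            [(f"G6P{pool}", 1), ("cADP", 1)],
            Glucokinase(f"gk{pool}", "cGlc", "cATP", f"F6P{pool}", "Fru1P"),
            {"Vmax": _percell(vgk), "Km": 8.0, "Katp": 0.4,
             "Ki_f6p": 0.06, "Ka_f1p": 0.5},
            amap=_identity("cGlc", f"G6P{pool}", 6),
            name=f"glucokinase, pool {pool}")
        add(f"g6pase{pool}", [(f"G6P{pool}", 1)], [("cGlc", 1), ("cPi", 1)],
            MichaelisMenten(f"g6pase{pool}", [f"G6P{pool}"]),
            {"Vmax": _percell(vg6p), f"Km_G6P{pool}": 2.0},
            amap=_identity(f"G6P{pool}", "cGlc", 6),
            name=f"glucose 6-phosphatase, pool {pool}")
        add(f"gpi{pool}", [(f"G6P{pool}", 1)], [(f"F6P{pool}", 1)],
            ReversibleMichaelisMenten(f"gpi{pool}", [f"G6P{pool}"],
                                      [f"F6P{pool}"]),
            {"Vmax": _percell(3.0), f"Km_G6P{pool}": 0.8,
             f"Km_F6P{pool}": 0.3, "keq": 0.36},
            reversible=True, amap=_identity(f"G6P{pool}", f"F6P{pool}", 6),
            name=f"glucose phosphate isomerase, pool {pool} (near equilibrium)")
    for pool, vpfk, vfbase in (("a", 0.40, 0.08), ("b", 0.05, 0.09)):
        add(f"pfkl{pool}", [(f"F6P{pool}", 1), ("cATP", 1)],
            [(f"FBP{pool}", 1), ("cADP", 1)],
            MichaelisMenten(f"pfkl{pool}", [f"F6P{pool}", "cATP"]),
            {"Vmax": _percell(vpfk), f"Km_F6P{pool}": 0.1, "Km_cATP": 0.15},
            amap=_identity(f"F6P{pool}", f"FBP{pool}", 6),
            name=f"phosphofructokinase, pool {pool}")
        add(f"fbase{pool}", [(f"FBP{pool}", 1)], [(f"F6P{pool}", 1), ("cPi", 1)],
            MichaelisMenten(f"fbase{pool}", [f"FBP{pool}"]),
            {"Vmax": _percell(vfbase), f"Km_FBP{pool}": 0.01},
            amap=_identity(f"FBP{pool}", f"F6P{pool}", 6),
            name=f"fructose 1,6-bisphosphatase, pool {pool}")

    # --- aldolase (three net reactions sharing capacity) ------------------
    m = AtomTransitionMap()
    for c in (1, 2, 3):
        m.add("FBPa#1", c, "DHAP#1", c)
    for c in (4, 5, 6):
        m.add("FBPa#1", c, "GAP#1", c - 3)
    add("aldo1", [("FBPa", 1)], [("DHAP", 1), ("GAP", 1)],
        ReversibleMichaelisMenten("aldo1", ["FBPa"], ["DHAP", "GAP"],
                                  inhibitors=["Fru1P"]),
        {"Vmax": _percell(0.8), "Km_FBPa": 0.05, "Km_DHAP": 0.4,
         "Km_GAP": 0.3, "Ki_Fru1P": 2.0, "keq": 0.1},
        reversible=True, amap=m, name="aldolase: FBP cleavage")
    m = AtomTransitionMap()
    for c in (1, 2, 3):
        m.add("Fru1P#1", c, "DHAP#1", c)
    for c in (4, 5, 6):
        m.add("Fru1P#1", c, "Gra#1", c - 3)
    add("aldo2", [("Fru1P", 1)], [("DHAP", 1), ("Gra", 1)],
        ReversibleMichaelisMenten("aldo2", ["Fru1P"], ["DHAP", "Gra"],
                                  inhibitors=["FBPa"]),
        {"Vmax": _percell(0.55), "Km_Fru1P": 1.0, "Km_DHAP": 1.2,
         "Km_Gra": 1.0, "Ki_FBPa": 0.1, "keq": 0.1},
        reversible=True, amap=m, name="aldolase: Fru1P cleavage")
    m = AtomTransitionMap()
    for c in (1, 2, 3):
        m.add("FBPa#1", c, "Fru1P#1", c)
    for c in (4, 5, 6):
        m.add("FBPa#1", c, "GAP#1", c - 3)
    for c in (1, 2, 3):
        m.add("Gra#1", c, "Fru1P#1", c + 3)
    add("aldo3", [("FBPa", 1), ("Gra", 1)], [("Fru1P", 1), ("GAP", 1)],
        ReversibleMichaelisMenten("aldo3", ["FBPa", "Gra"], ["Fru1P", "GAP"]),
        {"Vmax": _percell(0.15), "Km_FBPa": 0.05, "Km_Gra": 1.0,
         "Km_Fru1P": 1.0, "Km_GAP": 0.3, "keq": 1.0},
        reversible=True, amap=m, name="aldolase: transfer reaction")

    m = AtomTransitionMap()
    m.add("DHAP#1", 1, "GAP#1", 3)
    m.add("DHAP#1", 2, "GAP#1", 2)
    m.add("DHAP#1", 3, "GAP#1", 1)
    add("tim", [("DHAP", 1)], [("GAP", 1)],
        ReversibleMichaelisMenten("tim", ["DHAP"], ["GAP"]),
        {"Vmax": _percell(4.0), "Km_DHAP": 0.5, "Km_GAP": 0.5,
         "keq": 0.045},
        reversible=True, amap=m,
        name="triose phosphate isomerase (near equilibrium)")

    # --- fructose pathway -------------------------------------------------
    add("frutr", [("eFru", 1)], [("cFru", 1)],
        ReversibleMichaelisMenten("frutr", ["eFru"], ["cFru"]),
        {"Vmax": _percell(2.6), "Km_eFru": 67.0, "Km_cFru": 67.0, "keq": 1.0},
        reversible=True, amap=_identity("eFru", "cFru", 6),
        name="fructose transport (low affinity)")
    add("fruhk", [("cFru", 1), ("cATP", 1)], [("Fru1P", 1), ("cADP", 1)],
        MichaelisMenten("fruhk", ["cFru", "cATP"]),
        {"Vmax": _percell(1.6), "Km_cFru": 0.5, "Km_cATP": 0.4},
        amap=_identity("cFru", "Fru1P", 6), name="fructokinase")
    add("trik", [("Gra", 1), ("cATP", 1)], [("GAP", 1), ("cADP", 1)],
        MichaelisMenten("trik", ["Gra", "cATP"]),
        {"Vmax": _percell(0.45), "Km_Gra": 0.05, "Km_cATP": 0.4},
        amap=_identity("Gra", "GAP", 3), name="triokinase")

    # --- lower glycolysis and lactate export ------------------------------
    add("gapdh", [("GAP", 1), ("cPi", 1)], [("BPG", 1)],
        ReversibleMichaelisMenten("gapdh", ["GAP", "cPi"], ["BPG"]),
        {"Vmax": _percell(6.0), "Km_GAP": 0.1, "Km_cPi": 1.5, "Km_BPG": 0.1,
         "keq": 0.05},
        reversible=True, amap=_identity("GAP", "BPG", 3),
        name="glyceraldehyde 3-phosphate dehydrogenase (NAD folded in)")
    add("pgk", [("BPG", 1), ("cADP", 1)], [("PG3", 1), ("cATP", 1)],
        ReversibleMichaelisMenten("pgk", ["BPG", "cADP"], ["PG3", "cATP"]),
        {"Vmax": _percell(3.0), "Km_BPG": 0.02, "Km_cADP": 0.35,
         "Km_PG3": 1.2, "Km_cATP": 0.5, "keq": 1500.0},
        reversible=True, amap=_identity("BPG", "PG3", 3),
        name="phosphoglycerate kinase")
    add("pgm", [("PG3", 1)], [("PG2", 1)],
        ReversibleMichaelisMenten("pgm", ["PG3"], ["PG2"]),
        {"Vmax": _percell(2.0), "Km_PG3": 0.5, "Km_PG2": 0.1, "keq": 0.15},
        reversible=True, amap=_identity("PG3", "PG2", 3),
        name="phosphoglycerate mutase")
    add("eno", [("PG2", 1)], [("PEP", 1)],
        ReversibleMichaelisMenten("eno", ["PG2"], ["PEP"]),
        {"Vmax": _percell(3.0), "Km_PG2": 0.1, "Km_PEP": 0.2, "keq": 4.0},
        reversible=True, amap=_identity("PG2", "PEP", 3),
        name="enolase (near equilibrium)")
    add("pk", [("PEP", 1), ("cADP", 1)], [("Pyr", 1), ("cATP", 1)],
        Hill("pk", "PEP", cosubstrates=["cADP"]),
        {"Vmax": _percell(2.0), "K": 0.8, "h": 1.5, "Km_cADP": 0.3},
        amap=_identity("PEP", "Pyr", 3), name="pyruvate kinase (L isoform)")
    add("ldh", [("Pyr", 1)], [("cLac", 1)],
        ReversibleMichaelisMenten("ldh", ["Pyr"], ["cLac"]),
        {"Vmax": _percell(4.0), "Km_Pyr": 0.3, "Km_cLac": 4.0, "keq": 10.0},
        reversible=True, amap=_identity("Pyr", "cLac", 3),
        name="lactate dehydrogenase (NADH folded in)")
    add("lactr", [("cLac", 1)], [("eLac", 1)],
        ReversibleMichaelisMenten("lactr", ["cLac"], ["eLac"]),
        {"Vmax": _percell(2.0), "Km_cLac": 3.0, "Km_eLac": 3.0, "keq": 1.0},
        reversible=True, amap=_identity("cLac", "eLac", 3),
        name="lactate transport (MCT)")

    # --- glycogen branch --------------------------------------------------
    add("pglm", [("G6Pb", 1)], [("G1P", 1)],
        ReversibleMichaelisMenten("pglm", ["G6Pb"], ["G1P"]),
        {"Vmax": _percell(2.0), "Km_G6Pb": 0.1, "Km_G1P": 0.05, "keq": 0.06},
        reversible=True, amap=_identity("G6Pb", "G1P", 6),
        name="phosphoglucomutase (near equilibrium)")
    add("ugt", [("G1P", 1), ("cATP", 1)], [("UDPG", 1), ("PPi", 1)],
        MichaelisMenten("ugt", ["G1P", "cATP"]),
        {"Vmax": _percell(0.55), "Km_G1P": 0.05, "Km_cATP": 0.5},
        amap=_identity("G1P", "UDPG", 6),
        name="UDP-glucose pyrophosphorylase (UTP folded into ATP)")
    add("gs", [("UDPG", 1)], [("Glyc", 1), ("cADP", 1)],
        MichaelisMenten("gs", ["UDPG"]),
        {"Vmax": _percell(0.55), "Km_UDPG": 0.3},
        amap=_identity("UDPG", "Glyc", 6), name="glycogen synthase")
    add("gp", [("Glyc", 1), ("cPi", 1)], [("G1P", 1)],
        MichaelisMenten("gp", ["Glyc", "cPi"]),
        {"Vmax": _percell(0.06), "Km_Glyc": 2.0, "Km_cPi": 1.0},
        amap=_identity("Glyc", "G1P", 6), name="glycogen phosphorylase")

    # --- energy subsystem -------------------------------------------------
    add("atpase", [("cATP", 1)], [("cADP", 1), ("cPi", 1)],
        MichaelisMenten("atpase", ["cATP"]),
        {"Vmax": _percell(0.7), "Km_cATP": 0.3}, name="cytosolic ATP load")
    add("adk", [("cATP", 1), ("cAMP", 1)], [("cADP", 2)],
        MassAction("adk", [("cATP", 1), ("cAMP", 1)], [("cADP", 2)],
                   reversible=True),
        {"k": _percell(1.0), "keq": 0.44},
        reversible=True, name="adenylate kinase")
    add("ppase", [("PPi", 1)], [("cPi", 2)],
        MichaelisMenten("ppase", ["PPi"]),
        {"Vmax": _percell(1.5), "Km_PPi": 0.01},
        name="inorganic pyrophosphatase")
    # sodium-coupled phosphate import: effective keq > 1 models the
    # inward pump that holds cytosolic Pi ~5 mM against ~1 mM medium Pi
    add("pimtr", [("ePi", 1)], [("cPi", 1)],
        ReversibleMichaelisMenten("pimtr", ["ePi"], ["cPi"]),
        {"Vmax": _percell(0.7), "Km_ePi": 0.5, "Km_cPi": 8.0, "keq": 4.17},
        reversible=True, name="medium phosphate transport (Na-coupled)")
    add("pitr", [("cPi", 1)], [("mPi", 1)],
        ReversibleMassAction("pitr", ["cPi"], ["mPi"]),
        {"k": _percell(1.5), "keq": 2.0},
        reversible=True, name="mitochondrial phosphate carrier")
    add("oxphos", [("cADP", 1), ("mPi", 1)], [("cATP", 1)],
        MichaelisMenten("oxphos", ["cADP", "mPi"]),
        {"Vmax": _percell(2.8), "Km_cADP": 0.3, "Km_mPi": 2.0},
        name="lumped mitochondrial ATP regeneration")

    return rxns, laws, ParameterSet(params)


def _parameter_groups(params: ParameterSet) -> ParameterGroups:
    """Fitted activity groups: unbranched chains collapse to one factor.

    Near-equilibrium steps (glucose phosphate isomerase, triose phosphate
    isomerase, enolase, phosphoglucomutase) and the housekeeping
    phosphate/adenylate reactions keep fixed literature-scale capacities
    and are not fitted.
    """

    def g(name, *members):
        return (name, [(p, params[p]) for p in members])

    return ParameterGroups([
        g("glctr", "glctr.Vmax"),
        g("gk_a", "gka.Vmax"),
        g("gk_b", "gkb.Vmax"),
        g("g6pase_a", "g6pasea.Vmax"),
        g("g6pase_b", "g6paseb.Vmax"),
        g("pfk_a", "pfkla.Vmax"),
        g("pfk_b", "pfklb.Vmax"),
        g("fbase_a", "fbasea.Vmax"),
        g("fbase_b", "fbaseb.Vmax"),
        g("aldo", "aldo1.Vmax", "aldo2.Vmax", "aldo3.Vmax"),
        g("fru_uptake", "frutr.Vmax"),
        g("fruhk", "fruhk.Vmax"),
        g("trik", "trik.Vmax"),
        g("lower_glycolysis", "gapdh.Vmax", "pgk.Vmax", "pgm.Vmax"),
        g("pk", "pk.Vmax"),
        g("lactate_out", "ldh.Vmax", "lactr.Vmax"),
        g("glycogen_syn", "ugt.Vmax", "gs.Vmax"),
        g("gp", "gp.Vmax"),
        g("atpase", "atpase.Vmax"),
        g("oxphos", "oxphos.Vmax"),
    ])


def make_demo_model(overrides: Mapping[str, float] | None = None) -> KineticModel:
    """Build the validated demo model with optional parameter overrides."""
    rxns, laws, params = _reactions_and_laws()
    if overrides:
        unknown = [k for k in overrides if k not in params]
        if unknown:
            raise KineticsError(f"override of unknown parameters {unknown}")
        params = params.updated(overrides)
    net = Network(
        compartments=[
            Compartment("ext", "extracellular medium", VOL_EXT),
            Compartment("cyt", "cytosol", VOL_CYT),
            Compartment("mito", "mitochondrial matrix", VOL_MITO),
        ],
        metabolites=_metabolites(),
        reactions=rxns,
        ncell=NCELL,
        name="hepatocyte_demo",
    )
    return KineticModel(net, laws, params, _parameter_groups(params))


# tracer masks: [1,2-¹³C₂] hexose = C1+C2 set; [U-¹³C₆] = all six carbons
MASK_12 = 0b000011
MASK_U6 = 0b111111


def condition_library() -> dict[str, Condition]:
    """The three incubation conditions.

    A1: 20 mM glucose (50% [1,2-¹³C₂]) + 3 mM fructose;
    A2: 20 mM glucose + 3 mM fructose (50% [U-¹³C₆]);
    B:  20 mM glucose (50% [1,2-¹³C₂]) + 20 mM fructose.
    A1 and A2 differ only in the labelling pattern of the substrates.
    """
    return {
        "A1": Condition(
            id="A1",
            initial={"eGlc": 20.0, "eFru": 3.0},
            tracers={"eGlc": [(MASK_12, 0.5), (0, 0.5)]},
            t_end=120.0,
        ),
        "A2": Condition(
            id="A2",
            initial={"eGlc": 20.0, "eFru": 3.0},
            tracers={"eFru": [(MASK_U6, 0.5), (0, 0.5)]},
            t_end=120.0,
        ),
        "B": Condition(
            id="B",
            initial={"eGlc": 20.0, "eFru": 20.0},
            tracers={"eGlc": [(MASK_12, 0.5), (0, 0.5)]},
            t_end=120.0,
        ),
    }


def demo_observables() -> list[Observable]:
    """The measured quantities the study design provides at the endpoint:
    medium glucose/lactate concentrations, glycogen content, and MIDs of
    medium glucose C1-C6, glycogen C1-C4 and C3-C6, medium lactate C1-C3
    and sorbitol C1-C6 (pooled medium glucose + fructose).  Glutamate
    fragments are not available in the reduced network."""
    obs: list[Observable] = [
        Observable("eGlc", "conc"),
        Observable("eLac", "conc"),
        Observable("Glyc", "conc"),
    ]
    for k in range(7):
        obs.append(Observable("eGlc", "mid", (1, 6), k))
    for k in range(5):
        obs.append(Observable("Glyc", "mid", (1, 4), k))
    for k in range(5):
        obs.append(Observable("Glyc", "mid", (3, 6), k))
    for k in range(4):
        obs.append(Observable("eLac", "mid", (1, 3), k))
    for k in range(7):
        obs.append(Observable("eGlc", "mid", (1, 6), k, pooled_with="eFru"))
    return obs
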