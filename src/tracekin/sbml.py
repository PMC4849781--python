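"""Minimal SBML Level-2/3 import for model structure.

SBML is XML; this reader extracts compartments, species and reactions
(with stoichiometry and reversibility) directly from the document, and
lowers kinetic-law MathML to the generic parsed-expression rate law.
Carbon counts and atom-transition maps are not expressible in plain SBML;
they are supplied through sidecar tables (a metabolite-annotation TSV and
the native atom-map TSV) keyed by species/reaction id.

Only the subset needed for model structure is supported: no rules, events,
function definitions or unit conversion.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import pandas as pd
from lxml import etree

from .kinetics import ExpressionLaw, KineticModel, ParameterSet, RateLaw
from .network import (AtomTransitionMap, Compartment, Metabolite, Network,
                      NetworkError, Reaction)

__all__ = ["load_sbml", "load_species_annotations"]


def _local(tag) -> str:
    return etree.QName(tag).localname if isinstance(tag, str) else ""


def _findall(el, name):
    return [c for c in el.iter() if etree.QName(c).localname == name]


def _children(el, name):
    return [c for c in el if isinstance(c.tag, str)
            and etree.QName(c).localname == name]


def _mathml_to_expr(el) -> str:
    """Lower a MathML content tree to an arithmetic expression string."""
    name = etree.QName(el).localname
    if name == "math":
        kids = [c for c in el if isinstance(c.tag, str)]
        if len(kids) != 1:
            raise NetworkError("malformed MathML: expected one child of <math>")
        return _mathml_to_expr(kids[0])
    if name == "ci":
        return el.text.strip()
    if name == "cn":
        sub = _children(el, "sep")
        if sub:  # rational / e-notation form
            parts = [t.strip() for t in el.itertext() if t.strip()]
            cn_type = el.get("type", "real")
            if cn_type == "e-notation":
                return f"({parts[0]}e{parts[1]})"
            return f"({parts[0]}/{parts[1]})"
        return f"({el.text.strip()})"
    if name == "apply":
        kids = [c for c in el if isinstance(c.tag, str)]
        op = etree.QName(kids[0]).localname
        args = [_mathml_to_expr(c) for c in kids[1:]]
        if op == "plus":
            return "(" + " + ".join(args) + ")" if args else "0"
        if op == "minus":
            return f"(-{args[0]})" if len(args) == 1 else f"({args[0]} - {args[1]})"
        if op == "times":
            return "(" + " * ".join(args) + ")"
        if op == "divide":
            return f"({args[0]} / {args[1]})"
        if op == "power":
            return f"({args[0]} ** {args[1]})"
        if op == "root":
            return f"({args[-1]} ** 0.5)" if len(args) == 1 else (
                f"({args[-1]} ** (1/{args[0]}))"
            )
        if op == "exp":
            return f"exp({args[0]})"
        if op == "ln":
            return f"log({args[0]})"
        raise NetworkError(f"unsupported MathML operator {op!r}")
    raise NetworkError(f"unsupported MathML element {name!r}")


def load_species_annotations(path) -> dict[str, dict]:
    """Sidecar table: species_id, n_carbons, labelable (0/1)."""
    df = pd.read_csv(path, sep="\t")
    out = {}
    for _, row in df.iterrows():
        out[str(row["species_id"])] = {
            "n_carbons": int(row["n_carbons"]),
            "labelable": bool(int(row["labelable"])),
        }
    return out


def load_sbml(
    path,
    *,
    species_annotations: Mapping[str, dict] | None = None,
    atom_maps: Mapping[str, AtomTransitionMap] | None = None,
) -> KineticModel:
    """Read an SBML document into a KineticModel.

    Species with ``boundaryCondition`` or ``constant`` true become constant
    metabolites; kinetic laws (when present) become parsed-expression laws
    over species ids with local + global parameters substituted; missing
    kinetic laws leave the reaction without a rate (structure-only import).
    """
    try:
        tree = etree.parse(str(path))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise NetworkError(f"cannot parse SBML document {path}: {exc}") from None
    root = tree.getroot()
    if _local(root.tag) != "sbml":
        raise NetworkError(f"{path}: not an SBML document (root {root.tag!r})")
    models = _findall(root, "model")
    if not models:
        raise NetworkError(f"{path}: no <model> element")
    model_el = models[0]
    annotations = dict(species_annotations or {})
    atom_maps = dict(atom_maps or {})

    comps = []
    for c in _findall(model_el, "compartment"):
        size = c.get("size") or c.get("volume") or "1.0"
        comps.append(Compartment(c.get("id"), c.get("name") or "",
                                 float(size)))
    mets = []
    for s in _findall(model_el, "species"):
        sid = s.get("id")
        if sid is None:
            raise NetworkError("species without id")
        ann = annotations.get(sid, {})
        constant = (s.get("boundaryCondition") == "true"
                    or s.get("constant") == "true")
        init = s.get("initialConcentration")
        if init is None:
            init = s.get("initialAmount") or "0"
        mets.append(
            Metabolite(
                id=sid,
                compartment=s.get("compartment"),
                name=s.get("name") or "",
                n_carbons=int(ann.get("n_carbons", 0)),
                labelable=bool(ann.get("labelable", False)),
                constant=constant,
                initial_concentration=float(init),
            )
        )

    global_params = {}
    lists = _children(model_el, "listOfParameters")
    for lp in lists:
        for p in _children(lp, "parameter"):
            if p.get("value") is not None:
                global_params[p.get("id")] = float(p.get("value"))
    ncell = global_params.pop("ncell", 1.0)

    reactions = []
    laws: dict[str, RateLaw] = {}
    params = ParameterSet()
    for r in _findall(model_el, "reaction"):
        rid = r.get("id")
        if rid is None:
            raise NetworkError("reaction without id")

        def side(list_name):
            out = []
            for lst in _children(r, list_name):
                for sr in _children(lst, "speciesReference"):
                    sp = sr.get("species")
                    stoich = float(sr.get("stoichiometry") or "1")
                    if abs(stoich - round(stoich)) > 1e-9 or stoich <= 0:
                        raise NetworkError(
                            f"reaction {rid!r}: non-integer stoichiometry "
                            f"{stoich} for species {sp!r}"
                        )
                    out.append((sp, int(round(stoich))))
            return out

        subs = side("listOfReactants")
        prods = side("listOfProducts")
        reversible = (r.get("reversible") or "true") == "true"
        reactions.append(
            Reaction(rid, subs, prods, name=r.get("name") or "",
                     reversible=reversible, atom_map=atom_maps.get(rid),
                     kinetic_law=rid)
        )
        kl = _children(r, "kineticLaw")
        if kl:
            local = {}
            for lst_name in ("listOfLocalParameters", "listOfParameters"):
                for lst in _children(kl[0], lst_name):
                    for p in lst:
                        if not isinstance(p.tag, str):
                            continue
                        local[p.get("id")] = float(p.get("value") or "0")
            math = _children(kl[0], "math")
            if math:
                expr = _mathml_to_expr(math[0])
                merged = {**global_params, **local}
                pnames = sorted(merged)
                law = ExpressionLaw(rid, expr, None, pnames)
                laws[rid] = law
                for k, v in merged.items():
                    params[f"{rid}.{k}"] = v

    net = Network(
        compartments=comps,
        metabolites=mets,
        reactions=reactions,
        ncell=float(ncell),
        name=model_el.get("id") or model_el.get("name") or "sbml_model",
    )
    return KineticModel(net, laws, params, None)
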