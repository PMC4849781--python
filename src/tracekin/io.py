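"""Native structured-config I/O.

A model is shipped as one YAML document (compartments, metabolites,
reactions with rate-law templates, parameters, groups, conditions) plus a
TSV atom-map table (reaction id, substrate slot, substrate carbon, product
slot, product carbon).  The writer emits sorted keys and plain float
formatting so a written file is bit-identical on rewrite.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import kinetics as K
from .experiments import Condition
from .kinetics import KineticModel, ParameterGroups, ParameterSet, RateLaw
from .network import (AtomTransitionMap, Compartment, Metabolite, Network,
                      NetworkError, Reaction, Slot)

__all__ = [
    "load_model", "save_model", "load_network",
    "load_atom_maps", "save_atom_maps",
    "load_conditions", "save_conditions",
]

LAW_TEMPLATES: dict[str, type[RateLaw]] = {
    "mass_action": K.MassAction,
    "michaelis_menten": K.MichaelisMenten,
    "reversible_michaelis_menten": K.ReversibleMichaelisMenten,
    "reversible_mass_action": K.ReversibleMassAction,
    "hill": K.Hill,
    "glucokinase": K.Glucokinase,
    "expression": K.ExpressionLaw,
}
_TEMPLATE_NAMES = {v: k for k, v in LAW_TEMPLATES.items()}


# ---------------------------------------------------------------------------
# Atom maps
# ---------------------------------------------------------------------------

ATOM_MAP_COLUMNS = ["reaction_id", "substrate", "sub_carbon", "product",
                    "prod_carbon"]


def load_atom_maps(path) -> dict[str, AtomTransitionMap]:
    df = pd.read_csv(path, sep="\t", dtype={"substrate": str, "product": str})
    missing = [c for c in ATOM_MAP_COLUMNS if c not in df.columns]
    if missing:
        raise NetworkError(f"atom-map table missing columns {missing}")
    maps: dict[str, AtomTransitionMap] = {}
    for _, row in df.iterrows():
        rid = str(row["reaction_id"])
        maps.setdefault(rid, AtomTransitionMap()).add(
            Slot.parse(str(row["substrate"])), int(row["sub_carbon"]),
            Slot.parse(str(row["product"])), int(row["prod_carbon"]),
        )
    return maps


def save_atom_maps(maps: Mapping[str, AtomTransitionMap], path) -> None:
    rows = []
    for rid in sorted(maps):
        for (s, sc), (p, pc) in sorted(
            maps[rid].entries.items(), key=lambda kv: (str(kv[0][0]), kv[0][1])
        ):
            rows.append((rid, str(s), sc, str(p), pc))
    pd.DataFrame(rows, columns=ATOM_MAP_COLUMNS).to_csv(path, sep="\t",
                                                        index=False)


# ---------------------------------------------------------------------------
# Model YAML
# ---------------------------------------------------------------------------


def _law_to_dict(law: RateLaw) -> dict:
    template = _TEMPLATE_NAMES[type(law)]
    if isinstance(law, K.ExpressionLaw):
        args = {
            "forward_expression": law.forward_expression,
            "reverse_expression": law.reverse_expression,
            "parameters": law.param_names(),
        }
    else:

        def _untuple(x):
            if isinstance(x, (list, tuple)):
                return [_untuple(v) for v in x]
            return x

        args = {
            k: _untuple(v)
            for k, v in dataclasses.asdict(law).items()
            if k != "reaction_id"
        }
    return {"template": template, "args": args}


def _law_from_dict(rid: str, spec: dict) -> RateLaw:
    template = spec["template"]
    if template not in LAW_TEMPLATES:
        raise NetworkError(f"reaction {rid!r}: unknown law template {template!r}")
    cls = LAW_TEMPLATES[template]
    args = dict(spec.get("args", {}))
    if cls is K.ExpressionLaw:
        return K.ExpressionLaw(rid, args["forward_expression"],
                               args.get("reverse_expression"),
                               args.get("parameters", ()))
    if cls is K.MassAction:
        args["substrates"] = [tuple(x) for x in args.get("substrates", [])]
        args["products"] = [tuple(x) for x in args.get("products", [])]
    return cls(reaction_id=rid, **args)


def model_to_dict(model: KineticModel) -> dict:
    net = model.network
    doc = {
        "name": net.name,
        "ncell": float(net.ncell),
        "compartments": [
            {"id": c.id, "name": c.name, "volume": float(c.volume)}
            for c in net.compartments
        ],
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "carbons": int(m.n_carbons),
                "labelable": bool(m.labelable),
                "constant": bool(m.constant),
                "initial": float(m.initial_concentration),
            }
            for m in net.metabolites
        ],
        "symmetric": sorted(net.symmetric_metabolites),
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "substrates": [[m, int(c)] for m, c in r.substrates],
                "products": [[m, int(c)] for m, c in r.products],
                "reversible": bool(r.reversible),
                "invisible": bool(r.invisible),
                "law": _law_to_dict(model.rate_laws[r.kinetic_law or r.id]),
            }
            for r in net.reactions
        ],
        "parameters": {k: float(v) for k, v in sorted(model.params.items())},
        "groups": [
            {"name": g, "members": [[p, float(w)] for p, w in members]}
            for g, members in (model.groups.groups if model.groups else [])
        ],
    }
    return doc


def model_from_dict(doc: dict,
                    atom_maps: Mapping[str, AtomTransitionMap] | None = None
                    ) -> KineticModel:
    atom_maps = atom_maps or {}
    try:
        comps = [
            Compartment(c["id"], c.get("name", ""), float(c["volume"]))
            for c in doc.get("compartments", [])
        ]
        mets = [
            Metabolite(
                id=m["id"],
                compartment=m["compartment"],
                name=m.get("name", ""),
                n_carbons=int(m.get("carbons", 0)),
                labelable=bool(m.get("labelable", False)),
                constant=bool(m.get("constant", False)),
                initial_concentration=float(m.get("initial", 0.0)),
            )
            for m in doc.get("metabolites", [])
        ]
        reactions = []
        laws: dict[str, RateLaw] = {}
        for r in doc.get("reactions", []):
            rid = r["id"]
            subs = [(str(m), int(c)) for m, c in r.get("substrates", [])]
            prods = [(str(m), int(c)) for m, c in r.get("products", [])]
            reactions.append(
                Reaction(
                    id=rid,
                    name=r.get("name", ""),
                    substrates=subs,
                    products=prods,
                    reversible=bool(r.get("reversible", False)),
                    invisible=bool(r.get("invisible", False)),
                    atom_map=atom_maps.get(rid),
                    kinetic_law=rid,
                )
            )
            if "law" in r:
                laws[rid] = _law_from_dict(rid, r["law"])
    except KeyError as exc:
        raise NetworkError(f"malformed model document: missing key {exc}") from None
    net = Network(
        compartments=comps,
        metabolites=mets,
        reactions=reactions,
        ncell=float(doc.get("ncell", 1.0)),
        symmetric_metabolites=set(doc.get("symmetric", [])),
        name=doc.get("name", "network"),
    )
    params = ParameterSet(
        {str(k): float(v) for k, v in doc.get("parameters", {}).items()}
    )
    groups = None
    if doc.get("groups"):
        groups = ParameterGroups(
            [
                (g["name"], [(str(p), float(w)) for p, w in g["members"]])
                for g in doc["groups"]
            ]
        )
    return KineticModel(net, laws, params, groups)


def save_model(model: KineticModel, path, atom_map_path=None) -> None:
    path = Path(path)
    doc = model_to_dict(model)
    path.write_text(
        yaml.safe_dump(doc, sort_keys=True, default_flow_style=False,
                       allow_unicode=True)
    )
    if atom_map_path is not None:
        maps = {
            r.id: r.atom_map
            for r in model.network.reactions
            if r.atom_map is not None
        }
        save_atom_maps(maps, atom_map_path)


def load_model(path, atom_map_path=None) -> KineticModel:
    doc = yaml.safe_load(Path(path).read_text())
    maps = load_atom_maps(atom_map_path) if atom_map_path else {}
    return model_from_dict(doc, maps)


def load_network(path, atom_map_path=None) -> Network:
    """Load just the network structure from a native config document."""
    return load_model(path, atom_map_path).network


# ---------------------------------------------------------------------------
# Conditions
# ---------------------------------------------------------------------------


def conditions_to_dict(conditions: list[Condition]) -> dict:
    return {
        "conditions": [
            {
                "id": c.id,
                "t_end": float(c.t_end),
                "initial": {k: float(v) for k, v in sorted(c.initial.items())},
                "tracers": {
                    met: [[int(m), float(f)] for m, f in spec]
                    for met, spec in sorted(c.tracers.items())
                },
                **({"ncell": float(c.ncell)} if c.ncell is not None else {}),
                **({"volumes": c.volumes} if c.volumes else {}),
            }
            for c in conditions
        ]
    }


def conditions_from_dict(doc: dict) -> list[Condition]:
    out = []
    for c in doc.get("conditions", []):
        out.append(
            Condition(
                id=c["id"],
                initial={str(k): float(v) for k, v in c.get("initial", {}).items()},
                tracers={
                    str(met): [(int(m), float(f)) for m, f in spec]
                    for met, spec in c.get("tracers", {}).items()
                },
                ncell=c.get("ncell"),
                volumes=c.get("volumes"),
                t_end=float(c.get("t_end", 120.0)),
            )
        )
    return out


def save_conditions(conditions: list[Condition], path) -> None:
    Path(path).write_text(
        yaml.safe_dump(conditions_to_dict(conditions), sort_keys=True,
                       default_flow_style=False)
    )


def load_conditions(path) -> list[Condition]:
    return conditions_from_dict(yaml.safe_load(Path(path).read_text()))
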