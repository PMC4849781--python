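"""Rate laws, parameter sets and grouped enzyme activities.

Every reaction evaluates a *forward* and a *reverse* rate separately (the
reverse rate of an irreversible reaction is identically zero).  Reverse
capacities are never free parameters: for reversible template laws they are
derived from the forward capacity and the equilibrium constant through the
Haldane relationship, so thermodynamic consistency (zero net flux at
equilibrium) holds for any parameter values.

Rates are in mmol·cell⁻¹·min⁻¹; affinity constants in mM; equilibrium and
Hill constants dimensionless (Keq in concentration units implied by the
reaction stoichiometry).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .network import Network, NetworkError

__all__ = [
    "KineticsError",
    "ParameterSet",
    "ParameterGroups",
    "RateLaw",
    "MassAction",
    "MichaelisMenten",
    "ReversibleMichaelisMenten",
    "ReversibleMassAction",
    "Hill",
    "Glucokinase",
    "ExpressionLaw",
    "haldane_reverse_capacity",
    "FluxEvaluator",
    "evaluate_fluxes",
    "KineticModel",
]


class KineticsError(ValueError):
    pass


class ParameterSet(dict):
    """Named kinetic parameter vector ``p`` (mapping name → value).

    Parameter names are namespaced by reaction, e.g. ``"gka.Vmax"``.
    """

    def updated(self, other: Mapping[str, float]) -> "ParameterSet":
        new = ParameterSet(self)
        new.update(other)
        return new

    def require(self, names: Sequence[str], owner: str = "") -> None:
        missing = [n for n in names if n not in self]
        if missing:
            raise KineticsError(f"{owner}: missing parameters {missing}")


@dataclass
class ParameterGroups:
    """Grouped enzyme activities fitted as one scaling factor each.

    Sequential reactions in an unbranched chain carry one flux, so their
    individual capacities are not separable; each group exposes a single
    free factor E_z and member capacities are set to
    ``factor × relative_weight``.
    """

    groups: list[tuple[str, list[tuple[str, float]]]]

    def __post_init__(self):
        seen: set[str] = set()
        for gname, members in self.groups:
            for pname, w in members:
                if pname in seen:
                    raise KineticsError(
                        f"parameter {pname!r} appears in more than one group"
                    )
                seen.add(pname)

    @property
    def names(self) -> list[str]:
        return [g for g, _ in self.groups]

    @property
    def n_factors(self) -> int:
        return len(self.groups)

    def apply(self, params: ParameterSet, factors: Sequence[float]) -> ParameterSet:
        """Return a new ParameterSet with group members set to factor×weight."""
        factors = np.asarray(factors, dtype=float)
        if factors.shape != (len(self.groups),):
            raise KineticsError(
                f"expected {len(self.groups)} factors, got {factors.shape}"
            )
        out = ParameterSet(params)
        for (gname, members), f in zip(self.groups, factors):
            for pname, w in members:
                out[pname] = f * w
        return out

    def extract_factors(self, params: ParameterSet) -> np.ndarray:
        """Factors implied by ``params`` (member value / weight, first member)."""
        out = []
        for gname, members in self.groups:
            pname, w = members[0]
            out.append(params[pname] / w)
        return np.array(out)


def haldane_reverse_capacity(
    vmax_f: float, keq: float, km_s: float, km_p: float
) -> float:
    """Reverse capacity of a uni-uni reversible Michaelis–Menten law.

    From the Haldane identity ``Keq = Vmax_f·Km_P / (Vmax_r·Km_S)``:
    ``Vmax_r = Vmax_f·Km_P / (Keq·Km_S)``.  Multi-substrate templates
    document their generalized version next to the law definition.
    """
    if keq <= 0:
        raise KineticsError(f"Keq must be > 0, got {keq}")
    if km_s <= 0 or km_p <= 0:
        raise KineticsError("affinity constants must be > 0")
    return vmax_f * km_p / (keq * km_s)


# ---------------------------------------------------------------------------
# Rate-law templates
# ---------------------------------------------------------------------------

RateFn = Callable[[np.ndarray], tuple[float, float]]


class RateLaw:
    """Base class: a compiled callable mapping concentrations → (vf, vr)."""

    reaction_id: str

    def param_names(self) -> list[str]:
        raise NotImplementedError

    def referenced_metabolites(self) -> list[str]:
        """Metabolite ids this law reads (participants + modifiers)."""
        raise NotImplementedError

    def qualified(self, name: str) -> str:
        return f"{self.reaction_id}.{name}"

    def _p(self, params: Mapping[str, float], name: str) -> float:
        key = self.qualified(name)
        try:
            return params[key]
        except KeyError:
            raise KineticsError(
                f"rate law for {self.reaction_id!r} references unknown "
                f"parameter {key!r}"
            ) from None

    def compile(self, met_pos: Mapping[str, int], params: Mapping[str, float]) -> RateFn:
        raise NotImplementedError


@dataclass
class MassAction(RateLaw):
    """(Ir)reversible mass action: vf = k·Π[Sᵢ]^nᵢ, vr = (k/Keq)·Π[Pᵢ]^nᵢ."""

    reaction_id: str
    substrates: list[tuple[str, int]]
    products: list[tuple[str, int]] = field(default_factory=list)
    reversible: bool = False

    def param_names(self):
        return ["k"] + (["keq"] if self.reversible else [])

    def referenced_metabolites(self):
        return [m for m, _ in self.substrates] + [m for m, _ in self.products]
    def compile(self, met_pos, params):
        k = self._p(params, "k")
        sub = [(met_pos[m], n) for m, n in self.substrates]
        if self.reversible:
            keq = self._p(params, "keq")
            if keq <= 0:
                raise KineticsError(f"{self.reaction_id}: Keq must be > 0")
            kr = k / keq
            prod = [(met_pos[m], n) for m, n in self.products]

            def rate(c: np.ndarray) -> tuple[float, float]:
                vf = k
                for i, n in sub:
                    vf *= c[i] ** n
                vr = kr
                for i, n in prod:
                    vr *= c[i] ** n
                return vf, vr

        else:

            def rate(c: np.ndarray) -> tuple[float, float]:
                vf = k
                for i, n in sub:
                    vf *= c[i] ** n
                return vf, 0.0

        return rate


@dataclass
class MichaelisMenten(RateLaw):
    """Irreversible Michaelis–Menten with 1–2 substrates and optional
    competitive inhibitors: vf = Vmax·Π Sᵢ/(Kmᵢ+Sᵢ) / (1 + Σ I/Ki)."""

    reaction_id: str
    substrates: list[str]
    inhibitors: list[str] = field(default_factory=list)

    def param_names(self):
        names = ["Vmax"] + [f"Km_{s}" for s in self.substrates]
        names += [f"Ki_{i}" for i in self.inhibitors]
        return names

    def referenced_metabolites(self):
        return list(self.substrates) + list(self.inhibitors)
    def compile(self, met_pos, params):
        vmax = self._p(params, "Vmax")
        terms = [(met_pos[s], self._p(params, f"Km_{s}")) for s in self.substrates]
        inhib = [(met_pos[i], self._p(params, f"Ki_{i}")) for i in self.inhibitors]

        def rate(c: np.ndarray) -> tuple[float, float]:
            vf = vmax
            for i, km in terms:
                vf *= c[i] / (km + c[i]) if c[i] > 0 else 0.0
            if inhib:
                den = 1.0
                for i, ki in inhib:
                    den += c[i] / ki
                vf /= den
            return vf, 0.0

        return rate


@dataclass
class ReversibleMichaelisMenten(RateLaw):
    """Reversible Michaelis–Menten, 1–2 substrates / 1–2 products.

    vf = Vmax_f · Π(Sᵢ/Kmᵢ) / D,  vr = Vmax_r · Π(Pᵢ/Kmᵢ) / D with
    D = Π(1+Sᵢ/Kmᵢ) + Π(1+Pᵢ/Kmᵢ) − 1 and the reverse capacity fixed by
    the generalized Haldane identity
    Vmax_r = Vmax_f · Π Km_P / (Keq · Π Km_S), so the net rate vanishes
    exactly when Π[P]/Π[S] = Keq.
    """

    reaction_id: str
    substrates: list[str]
    products: list[str]
    inhibitors: list[str] = field(default_factory=list)

    def param_names(self):
        names = ["Vmax", "keq"]
        names += [f"Km_{s}" for s in self.substrates]
        names += [f"Km_{p}" for p in self.products]
        names += [f"Ki_{i}" for i in self.inhibitors]
        return names

    def referenced_metabolites(self):
        return list(self.substrates) + list(self.products) + list(self.inhibitors)
    def compile(self, met_pos, params):
        vmax_f = self._p(params, "Vmax")
        keq = self._p(params, "keq")
        kms = [(met_pos[s], self._p(params, f"Km_{s}")) for s in self.substrates]
        kmp = [(met_pos[p], self._p(params, f"Km_{p}")) for p in self.products]
        inhib = [(met_pos[i], self._p(params, f"Ki_{i}")) for i in self.inhibitors]
        if keq <= 0:
            raise KineticsError(f"{self.reaction_id}: Keq must be > 0")
        prod_km_p = float(np.prod([km for _, km in kmp]))
        prod_km_s = float(np.prod([km for _, km in kms]))
        vmax_r = vmax_f * prod_km_p / (keq * prod_km_s)

        def rate(c: np.ndarray) -> tuple[float, float]:
            num_f, den_s = vmax_f, 1.0
            for i, km in kms:
                x = c[i] / km
                num_f *= x
                den_s *= 1.0 + x
            num_r, den_p = vmax_r, 1.0
            for i, km in kmp:
                x = c[i] / km
                num_r *= x
                den_p *= 1.0 + x
            den = den_s + den_p - 1.0
            for i, ki in inhib:
                den += c[i] / ki
            return num_f / den, num_r / den

        return rate


@dataclass
class ReversibleMassAction(RateLaw):
    """Linear reversible law vf = k·Π[S], vr = (k/Keq)·Π[P]; convenient for
    transporters and near-equilibrium steps."""

    reaction_id: str
    substrates: list[str]
    products: list[str]

    def param_names(self):
        return ["k", "keq"]

    def referenced_metabolites(self):
        return list(self.substrates) + list(self.products)
    def compile(self, met_pos, params):
        k = self._p(params, "k")
        keq = self._p(params, "keq")
        if keq <= 0:
            raise KineticsError(f"{self.reaction_id}: Keq must be > 0")
        kr = k / keq
        sub = [met_pos[s] for s in self.substrates]
        prod = [met_pos[p] for p in self.products]

        def rate(c: np.ndarray) -> tuple[float, float]:
            vf = k
            for i in sub:
                vf *= c[i]
            vr = kr
            for i in prod:
                vr *= c[i]
            return vf, vr

        return rate


@dataclass
class Hill(RateLaw):
    """Irreversible Hill law vf = Vmax·S^h/(K^h+S^h)."""

    reaction_id: str
    substrate: str
    cosubstrates: list[str] = field(default_factory=list)

    def param_names(self):
        return ["Vmax", "K", "h"] + [f"Km_{s}" for s in self.cosubstrates]

    def referenced_metabolites(self):
        return [self.substrate] + list(self.cosubstrates)
    def compile(self, met_pos, params):
        vmax = self._p(params, "Vmax")
        K = self._p(params, "K")
        h = self._p(params, "h")
        i_s = met_pos[self.substrate]
        co = [(met_pos[s], self._p(params, f"Km_{s}")) for s in self.cosubstrates]

        def rate(c: np.ndarray) -> tuple[float, float]:
            s = c[i_s]
            vf = vmax * s**h / (K**h + s**h) if s > 0 else 0.0
            for i, km in co:
                vf *= c[i] / (km + c[i]) if c[i] > 0 else 0.0
            return vf, 0.0

        return rate


@dataclass
class Glucokinase(RateLaw):
    """Hepatic glucokinase with competitive inhibition by fructose
    6-phosphate that is relieved by fructose 1-phosphate.

    vf = Vmax · Glc/(Km+Glc) · ATP/(Katp+ATP)
              / (1 + (F6P/Ki_f6p)/(1 + F1P/Ka_f1p))

    The relief term models the regulatory-protein mechanism by which Fru1P
    releases glucokinase from its Fru6P-dependent inhibition.
    """

    reaction_id: str
    glucose: str
    atp: str
    f6p: str
    f1p: str

    def param_names(self):
        return ["Vmax", "Km", "Katp", "Ki_f6p", "Ka_f1p"]

    def referenced_metabolites(self):
        return [self.glucose, self.atp, self.f6p, self.f1p]
    def compile(self, met_pos, params):
        vmax = self._p(params, "Vmax")
        km = self._p(params, "Km")
        katp = self._p(params, "Katp")
        ki = self._p(params, "Ki_f6p")
        ka = self._p(params, "Ka_f1p")
        ig, ia, i6, i1 = (met_pos[m] for m in (self.glucose, self.atp, self.f6p, self.f1p))

        def rate(c: np.ndarray) -> tuple[float, float]:
            inhib = 1.0 + (c[i6] / ki) / (1.0 + c[i1] / ka)
            vf = vmax * (c[ig] / (km + c[ig])) * (c[ia] / (katp + c[ia])) / inhib
            return vf, 0.0

        return rate


class ExpressionLaw(RateLaw):
    """Generic parsed-expression law (used by the SBML importer).

    Expressions are arithmetic over metabolite ids and parameter names;
    parsed once with sympy and lambdified to a numpy-callable.
    """

    def __init__(
        self,
        reaction_id: str,
        forward_expression: str,
        reverse_expression: str | None = None,
        parameters: Sequence[str] = (),
    ):
        self.reaction_id = reaction_id
        self.forward_expression = forward_expression
        self.reverse_expression = reverse_expression
        self._params = list(parameters)

    def param_names(self):
        return list(self._params)

    def referenced_metabolites(self):
        import sympy

        mets = set()
        for expr in (self.forward_expression, self.reverse_expression):
            if not expr:
                continue
            try:
                tree = sympy.sympify(expr)
            except (sympy.SympifyError, SyntaxError):
                continue
            mets |= {str(x) for x in tree.free_symbols}
        return sorted(mets - set(self._params))

    def _build(self, expr: str, met_pos, params):
        import sympy

        syms = sorted(
            set(met_pos) | {self.qualified(p) for p in self._params}
            | set(self._params)
        )
        local = {s: sympy.Symbol(s) for s in syms}
        try:
            tree = sympy.sympify(expr, locals=local)
        except (sympy.SympifyError, SyntaxError) as exc:
            raise KineticsError(
                f"{self.reaction_id}: cannot parse expression {expr!r}: {exc}"
            )
        free = {str(s) for s in tree.free_symbols}
        unknown = free - set(met_pos) - set(self._params)
        if unknown:
            raise KineticsError(
                f"{self.reaction_id}: expression references unknown symbols "
                f"{sorted(unknown)}"
            )
        subs = {
            sympy.Symbol(p): self._p(params, p) for p in self._params
        }
        tree = tree.subs(subs)
        mets = sorted(free & set(met_pos))
        fn = sympy.lambdify([sympy.Symbol(m) for m in mets], tree, "numpy")
        idx = [met_pos[m] for m in mets]

        def ev(c: np.ndarray) -> float:
            with np.errstate(divide="raise", invalid="raise"):
                try:
                    return float(fn(*(c[i] for i in idx)))
                except (FloatingPointError, ZeroDivisionError):
                    raise KineticsError(
                        f"division by zero evaluating rate law of "
                        f"{self.reaction_id!r}"
                    ) from None

        return ev

    def compile(self, met_pos, params):
        fwd = self._build(self.forward_expression, met_pos, params)
        rev = (
            self._build(self.reverse_expression, met_pos, params)
            if self.reverse_expression
            else None
        )

        def rate(c: np.ndarray) -> tuple[float, float]:
            return fwd(c), (rev(c) if rev is not None else 0.0)

        return rate


# ---------------------------------------------------------------------------
# Evaluation over a whole network
# ---------------------------------------------------------------------------


@dataclass
class KineticModel:
    """A network together with its rate laws, parameters and groups."""

    network: Network
    rate_laws: dict[str, RateLaw]
    params: ParameterSet
    groups: ParameterGroups | None = None

    def with_factors(self, factors: Sequence[float]) -> "KineticModel":
        if self.groups is None:
            raise KineticsError("model has no parameter groups")
        return KineticModel(
            self.network, self.rate_laws, self.groups.apply(self.params, factors),
            self.groups,
        )


class FluxEvaluator:
    """Compiled per-reaction (forward, reverse) rate evaluation.

    Concentrations are clamped to zero before evaluation so that trial
    integrator excursions below zero cannot produce negative rates.
    """

    def __init__(self, net: Network, rate_laws: Mapping[str, RateLaw],
                 params: Mapping[str, float]):
        self.net = net
        self.met_pos = {m.id: i for i, m in enumerate(net.metabolites)}
        self._fns: list[RateFn] = []
        for r in net.reactions:
            law = rate_laws.get(r.kinetic_law or r.id)
            if law is None:
                raise KineticsError(f"reaction {r.id!r} has no rate law")
            self._fns.append(law.compile(self.met_pos, params))
        self._reversible = np.array(
            [r.reversible or r.invisible for r in net.reactions]
        )

    def __call__(self, conc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        c = np.maximum(conc, 0.0)
        nr = len(self._fns)
        vf = np.empty(nr)
        vr = np.empty(nr)
        for j, fn in enumerate(self._fns):
            f, r = fn(c)
            vf[j], vr[j] = f, r
        if not np.all(np.isfinite(vf)) or not np.all(np.isfinite(vr)):
            bad = [
                self.net.reactions[j].id
                for j in range(nr)
                if not (np.isfinite(vf[j]) and np.isfinite(vr[j]))
            ]
            raise KineticsError(f"non-finite rate in reactions {bad}")
        vr[~self._reversible] = 0.0
        return vf, vr


def evaluate_fluxes(
    net: Network,
    concentrations: Mapping[str, float] | np.ndarray,
    rate_laws: Mapping[str, RateLaw],
    params: ParameterSet,
) -> dict[str, tuple[float, float]]:
    """Per-reaction (forward, reverse) rates in mmol·cell⁻¹·min⁻¹."""
    ev = FluxEvaluator(net, rate_laws, params)
    if isinstance(concentrations, Mapping):
        c = np.array([concentrations.get(m.id, m.initial_concentration)
                      for m in net.metabolites])
    else:
        c = np.asarray(concentrations, dtype=float)
    vf, vr = ev(c)
    return {r.id: (vf[j], vr[j]) for j, r in enumerate(net.reactions)}
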