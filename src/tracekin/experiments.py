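"""Experimental condition and measurement-table containers.

A :class:`Condition` describes one incubation: initial concentrations,
tracer composition of the medium substrates (e.g. 50% [1,2-¹³C₂]-glucose),
cell number and the simulated horizon.  A :class:`Dataset` holds the
measurements (values with standard deviations) that the fitting objective
compares against model predictions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .network import Network, NetworkError

__all__ = ["TracerSpec", "Condition", "Observable", "Measurement", "Dataset",
           "SIGMA_FLOOR"]

SIGMA_FLOOR = 0.01  # minimum standard deviation used in the objective

# per-substrate tracer composition: [(isotopomer mask, fraction), ...]
TracerSpec = list[tuple[int, float]]


@dataclass(frozen=True)
class Observable:
    """What is measured: a concentration or a fragment MID component.

    ``kind`` is "conc" for a total concentration (mM) or "mid" for one
    isotopologue fraction of a fragment.  ``fragment`` is a 1-based
    inclusive carbon range; None means the whole molecule.
    """

    metabolite: str
    kind: str = "conc"  # "conc" | "mid"
    fragment: tuple[int, int] | None = None
    isotopologue: int | None = None  # m_k index for kind == "mid"
    pooled_with: str | None = None  # second hexose for sorbitol-style MIDs

    def __post_init__(self):
        if self.kind not in ("conc", "mid"):
            raise ValueError(f"unknown observable kind {self.kind!r}")
        if self.kind == "mid" and self.isotopologue is None:
            raise ValueError("mid observables need an isotopologue index")

    @property
    def id(self) -> str:
        frag = (
            f"C{self.fragment[0]}-C{self.fragment[1]}" if self.fragment else "C*"
        )
        pool = f"+{self.pooled_with}" if self.pooled_with else ""
        if self.kind == "conc":
            return f"{self.metabolite}{pool}:conc"
        return f"{self.metabolite}{pool}:{frag}:m{self.isotopologue}"


@dataclass
class Condition:
    """One experimental incubation."""

    id: str
    initial: dict[str, float] = field(default_factory=dict)  # mM overrides
    tracers: dict[str, list[tuple[int, float]]] = field(default_factory=dict)
    ncell: float | None = None
    volumes: dict[str, float] | None = None  # compartment overrides, litres
    t_end: float = 120.0  # minutes

    def __post_init__(self):
        for met, spec in self.tracers.items():
            total = sum(f for _, f in spec)
            if not np.isclose(total, 1.0, atol=1e-9):
                raise ValueError(
                    f"condition {self.id!r}: tracer fractions for {met!r} sum "
                    f"to {total}, expected 1"
                )
            if any(f < 0 for _, f in spec):
                raise ValueError(f"condition {self.id!r}: negative tracer fraction")
        if self.ncell is not None and not self.ncell > 0:
            raise ValueError(f"condition {self.id!r}: ncell must be > 0")

    def apply(self, net: Network) -> Network:
        """Return a copy of ``net`` with this condition's initial state."""
        unknown = [m for m in self.initial if m not in net.metabolite_index]
        unknown += [m for m in self.tracers if m not in net.metabolite_index]
        if unknown:
            raise NetworkError(
                f"condition {self.id!r} references unknown metabolites {unknown}"
            )
        mets = [
            dataclasses.replace(
                m, initial_concentration=self.initial.get(m.id, m.initial_concentration)
            )
            for m in net.metabolites
        ]
        comps = net.compartments
        if self.volumes:
            comps = [
                dataclasses.replace(c, volume=self.volumes.get(c.id, c.volume))
                for c in comps
            ]
        return Network(
            compartments=comps,
            metabolites=mets,
            reactions=net.reactions,
            ncell=self.ncell if self.ncell is not None else net.ncell,
            symmetric_metabolites=set(net.symmetric_metabolites),
            name=net.name,
        )

    def initial_fractions(self, met_id: str, n_carbons: int) -> np.ndarray:
        """Initial isotopomer fractions (length 2^n) for a metabolite."""
        frac = np.zeros(2**n_carbons)
        spec = self.tracers.get(met_id)
        if spec is None:
            frac[0] = 1.0
            return frac
        for mask, f in spec:
            if not 0 <= mask < 2**n_carbons:
                raise ValueError(
                    f"condition {self.id!r}: tracer mask {mask} out of range "
                    f"for {met_id!r} ({n_carbons} carbons)"
                )
            frac[mask] += f
        return frac


@dataclass(frozen=True)
class Measurement:
    condition_id: str
    observable: Observable
    time: float  # minutes
    value: float
    sd: float

    @property
    def sigma(self) -> float:
        return max(self.sd, SIGMA_FLOOR)


@dataclass
class Dataset:
    measurements: list[Measurement] = field(default_factory=list)

    def __post_init__(self):
        for m in self.measurements:
            if m.observable.kind == "mid" and not (0.0 <= m.value <= 1.0):
                raise ValueError(
                    f"MID measurement {m.observable.id} in {m.condition_id} "
                    f"outside [0, 1]: {m.value}"
                )

    def __len__(self) -> int:
        return len(self.measurements)

    def __iter__(self):
        return iter(self.measurements)

    def condition_ids(self) -> list[str]:
        seen: list[str] = []
        for m in self.measurements:
            if m.condition_id not in seen:
                seen.append(m.condition_id)
        return seen

    # -- schema I/O --------------------------------------------------------
    SCHEMA = [
        "condition_id", "observable_id", "metabolite", "fragment",
        "isotopologue_index", "time_min", "value", "sd",
    ]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.measurements:
            o = m.observable
            frag = f"{o.fragment[0]}-{o.fragment[1]}" if o.fragment else ""
            met = o.metabolite + (f"+{o.pooled_with}" if o.pooled_with else "")
            rows.append(
                {
                    "condition_id": m.condition_id,
                    "observable_id": o.id,
                    "metabolite": met,
                    "fragment": frag,
                    "isotopologue_index": (
                        "conc" if o.kind == "conc" else f"m{o.isotopologue}"
                    ),
                    "time_min": m.time,
                    "value": m.value,
                    "sd": m.sd,
                }
            )
        return pd.DataFrame(rows, columns=self.SCHEMA)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Dataset":
        errors = []
        ms = []
        for i, row in df.iterrows():
            try:
                met = str(row["metabolite"])
                pooled = None
                if "+" in met:
                    met, pooled = met.split("+", 1)
                frag = row.get("fragment", "")
                fragment = None
                if isinstance(frag, str) and frag.strip():
                    a, b = frag.split("-")
                    fragment = (int(a), int(b))
                idx = str(row["isotopologue_index"])
                if idx == "conc":
                    obs = Observable(met, "conc", fragment, None, pooled)
                else:
                    obs = Observable(met, "mid", fragment, int(idx.lstrip("m")), pooled)
                ms.append(
                    Measurement(
                        condition_id=str(row["condition_id"]),
                        observable=obs,
                        time=float(row["time_min"]),
                        value=float(row["value"]),
                        sd=float(row["sd"]),
                    )
                )
            except (ValueError, KeyError) as exc:
                errors.append(f"row {i}: {exc}")
        if errors:
            raise ValueError("measurement table errors:\n" + "\n".join(errors))
        return cls(ms)

    @classmethod
    def from_tsv(cls, path) -> "Dataset":
        return cls.from_frame(pd.read_csv(path, sep="\t"))
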