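"""Assembly and integration of the concentration ODE system.

For metabolite *i* located in a compartment of volume ``vol_i`` (litres),

    dc_i/dt = Σ_r N_{i,r} · j_r(c, p) · ncell / vol_i      [mM·min⁻¹]

with fluxes ``j`` in mmol·cell⁻¹·min⁻¹.  Constant (boundary) metabolites are
excluded from the integrated state vector; their fixed concentrations are
substituted when rates are evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .kinetics import FluxEvaluator, KineticsError, ParameterSet, RateLaw
from .network import Network, stoichiometric_matrix

__all__ = ["Trajectory", "IntegrationError", "build_concentration_odes", "integrate"]

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10  # mM


class IntegrationError(RuntimeError):
    """Integrator failure; carries the last time the solver reached."""

    def __init__(self, message: str, last_time: float | None = None):
        super().__init__(message)
        self.last_time = last_time


@dataclass
class Trajectory:
    """Time courses of concentrations (mM) and net fluxes.

    ``concentrations`` has one column per *dynamic* metabolite; constant
    species are available through :meth:`concentration` at their fixed value.
    """

    times: np.ndarray  # minutes
    concentrations: pd.DataFrame  # index = times, columns = metabolite ids
    fluxes: pd.DataFrame  # index = times, columns = reaction ids (net)
    network: Network | None = None

    def concentration(self, met: str) -> np.ndarray:
        if met in self.concentrations.columns:
            return self.concentrations[met].to_numpy()
        if self.network is not None:
            m = self.network.metabolite_index.get(met)
            if m is not None and m.constant:
                return np.full(len(self.times), m.initial_concentration)
        raise KeyError(met)

    def endpoint(self, met: str) -> float:
        return float(self.concentration(met)[-1])

    def to_tidy_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        conc = (
            self.concentrations.reset_index(names="time_min")
            .melt(id_vars="time_min", var_name="metabolite", value_name="conc_mM")
        )
        flux = (
            self.fluxes.reset_index(names="time_min")
            .melt(id_vars="time_min", var_name="reaction", value_name="net_flux")
        )
        return conc, flux


def build_concentration_odes(
    net: Network,
    rate_laws: Mapping[str, RateLaw],
    params: ParameterSet,
) -> tuple[Callable[[float, np.ndarray], np.ndarray], list[str], np.ndarray]:
    """Compile the total-concentration derivative function.

    Returns ``(rhs, state_ids, y0)`` where ``rhs(t, y)`` gives dy/dt in
    mM·min⁻¹ over the dynamic metabolites listed in ``state_ids``.
    """
    for r in net.reactions:
        if (r.kinetic_law or r.id) not in rate_laws:
            raise KineticsError(f"reaction {r.id!r} has no rate law")
    evaluator = FluxEvaluator(net, rate_laws, params)
    N = stoichiometric_matrix(net)
    dyn = [m for m in net.metabolites if not m.constant]
    state_ids = [m.id for m in dyn]
    dyn_rows = np.array([i for i, m in enumerate(net.metabolites) if not m.constant])
    scale = np.array([net.ncell / net.volume_of(m.id) for m in dyn])
    Nd = N[dyn_rows, :] * scale[:, None]
    full0 = np.array([m.initial_concentration for m in net.metabolites])
    y0 = full0[dyn_rows].copy()

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        c = full0.copy()
        c[dyn_rows] = y
        vf, vr = evaluator(c)
        dydt = Nd @ (vf - vr)
        if not np.all(np.isfinite(dydt)):
            bad = [state_ids[i] for i in np.where(~np.isfinite(dydt))[0]]
            raise IntegrationError(f"NaN derivative for metabolites {bad}")
        return dydt

    rhs.evaluator = evaluator  # type: ignore[attr-defined]
    rhs.state_ids = state_ids  # type: ignore[attr-defined]
    return rhs, state_ids, y0


def integrate(
    rhs: Callable[[float, np.ndarray], np.ndarray],
    y0: Sequence[float],
    t_span: tuple[float, float],
    *,
    state_ids: Sequence[str] | None = None,
    network: Network | None = None,
    t_eval: Sequence[float] | None = None,
    method: str = "BDF",
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    jac_sparsity=None,
) -> Trajectory:
    """Integrate a concentration ODE system with a stiff-capable method."""
    y0 = np.asarray(y0, dtype=float)
    if np.any(y0 < 0):
        raise ValueError("initial concentrations must be non-negative")
    if t_eval is None:
        t_eval = np.linspace(t_span[0], t_span[1], 61)
    kwargs = {}
    if jac_sparsity is not None and method in ("BDF", "Radau"):
        kwargs["jac_sparsity"] = jac_sparsity
    sol = solve_ivp(
        rhs, t_span, y0, method=method, rtol=rtol, atol=atol,
        t_eval=np.asarray(t_eval, float), **kwargs,
    )
    if not sol.success:
        raise IntegrationError(
            f"integration failed: {sol.message}",
            last_time=float(sol.t[-1]) if len(sol.t) else None,
        )
    ids = list(state_ids) if state_ids is not None else getattr(rhs, "state_ids", None)
    if ids is None:
        ids = [f"y{i}" for i in range(y0.size)]
    conc = pd.DataFrame(sol.y.T, index=pd.Index(sol.t, name="time_min"), columns=ids)
    # net fluxes along the path, recomputed from the evaluator when available
    evaluator = getattr(rhs, "evaluator", None)
    if evaluator is not None and network is not None:
        full0 = np.array([m.initial_concentration for m in network.metabolites])
        dyn_rows = np.array(
            [i for i, m in enumerate(network.metabolites) if not m.constant]
        )
        rows = []
        for k in range(len(sol.t)):
            c = full0.copy()
            c[dyn_rows] = sol.y[:, k]
            vf, vr = evaluator(c)
            rows.append(vf - vr)
        flux = pd.DataFrame(
            rows, index=conc.index, columns=[r.id for r in network.reactions]
        )
    else:
        flux = pd.DataFrame(index=conc.index)
    return Trajectory(sol.t, conc, flux, network)
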