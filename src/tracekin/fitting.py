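"""Multi-condition objective function and simulated-annealing estimation.

All conditions share one parameter set (enzyme activities normalized by
cell number are assumed equal across incubations); the free parameters are
the group scaling factors E₁..E_m.  The objective is

    X² = Σ_i ((Y_i − Z_i(E)) / σ_i)²

over every measurement, with σ_i floored at 0.01 to avoid bias from
near-zero reported standard deviations.  Parameter sets that drive any
metabolite above 50 mM anywhere along a simulated trajectory are rejected
(objective = +inf), as are parameter sets whose simulation fails.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .dynamics import IntegrationError
from .experiments import Condition, Dataset, SIGMA_FLOOR
from .kinetics import KineticModel, KineticsError, ParameterSet
from .labeling import LabeledTrajectory, simulate_labeling
from .measurement import observables_at

__all__ = ["FitProblem", "FitResult", "AnnealSchedule", "objective", "fit_anneal",
           "CONCENTRATION_CEILING"]

log = logging.getLogger(__name__)

CONCENTRATION_CEILING = 50.0  # mM; trajectories exceeding this are discarded


@dataclass
class FitProblem:
    """Bundle of model, conditions and data the objective operates on."""

    model: KineticModel
    conditions: list[Condition]
    dataset: Dataset
    rtol: float = 1e-6
    atol: float = 1e-8
    n_eval_points: int = 25

    def __post_init__(self):
        cond_ids = {c.id for c in self.conditions}
        missing = [
            m.condition_id for m in self.dataset if m.condition_id not in cond_ids
        ]
        if missing:
            raise ValueError(
                f"measurements reference unknown conditions {sorted(set(missing))}"
            )
        if self.model.groups is None:
            raise KineticsError("fit problem needs parameter groups")

    @property
    def factor_names(self) -> list[str]:
        return self.model.groups.names

    def initial_factors(self) -> np.ndarray:
        return self.model.groups.extract_factors(self.model.params)

    def _system(self, condition: Condition):
        from .labeling import build_joint_odes

        cache = getattr(self, "_systems", None)
        if cache is None:
            cache = {}
            object.__setattr__(self, "_systems", cache)
        if condition.id not in cache:
            cache[condition.id] = build_joint_odes(self.model, condition)
            cache[condition.id].jac_sparsity()
        return cache[condition.id]

    def simulate(self, factors: Sequence[float],
                 condition: Condition) -> LabeledTrajectory:
        m = self.model.with_factors(factors)
        sys_ = self._system(condition)
        sys_.set_params(m)
        times = np.unique(
            np.concatenate(
                [
                    np.linspace(0.0, condition.t_end, self.n_eval_points),
                    [
                        meas.time
                        for meas in self.dataset
                        if meas.condition_id == condition.id
                    ],
                ]
            )
        )
        return simulate_labeling(
            m, condition, (0.0, condition.t_end), t_eval=times,
            rtol=self.rtol, atol=self.atol, system=sys_,
        )

    def predictions(self, factors: Sequence[float]) -> dict[str, dict[str, float]]:
        """Predicted Z_i per condition (only conditions with measurements)."""
        out: dict[str, dict[str, float]] = {}
        for cond in self.conditions:
            meas = [m for m in self.dataset if m.condition_id == cond.id]
            if not meas:
                continue
            traj = self.simulate(factors, cond)
            preds: dict[str, float] = {}
            for t in sorted({m.time for m in meas}):
                obs = [m.observable for m in meas if m.time == t]
                vals = observables_at(traj, obs, t)
                preds.update({f"{oid}@{t:g}": v for oid, v in vals.items()})
            out[cond.id] = preds
        return out


def objective(factors: Sequence[float], problem: FitProblem) -> float:
    """X² of Eq (2)-style residuals; +inf sentinel on rejection."""
    factors = np.asarray(factors, dtype=float)
    if np.any(factors < 0):
        return np.inf
    chi2 = 0.0
    for cond in problem.conditions:
        meas = [m for m in problem.dataset if m.condition_id == cond.id]
        if not meas:
            continue
        try:
            traj = problem.simulate(factors, cond)
        except (IntegrationError, KineticsError, FloatingPointError) as exc:
            log.debug("condition %s rejected: %s", cond.id, exc)
            return np.inf
        if np.nanmax(traj.concentrations.to_numpy(), initial=0.0) > CONCENTRATION_CEILING:
            log.debug(
                "condition %s rejected: concentration above %g mM",
                cond.id, CONCENTRATION_CEILING,
            )
            return np.inf
        for t in sorted({m.time for m in meas}):
            batch = [m for m in meas if m.time == t]
            preds = observables_at(traj, [m.observable for m in batch], t)
            for m in batch:
                z = preds[m.observable.id]
                sigma = max(m.sd, SIGMA_FLOOR)
                chi2 += ((m.value - z) / sigma) ** 2
    return float(chi2)


@dataclass
class AnnealSchedule:
    """Kirkpatrick-style geometric cooling schedule.

    ``t0 = None`` starts at the initial objective value (so the first
    temperature accepts order-unity relative deteriorations).
    """

    t0: float | None = None
    cooling: float = 0.95
    moves_per_temperature: int = 50
    t_min_ratio: float = 1e-3
    max_evaluations: int = 20_000
    move_scale: float = 0.3  # sd of the log10 perturbation

    def __post_init__(self):
        if not 0 < self.cooling < 1:
            raise ValueError("cooling factor must be in (0, 1)")
        if self.move_scale <= 0:
            raise ValueError("move scale must be > 0")


@dataclass
class FitResult:
    """Best factors found, their objective and bookkeeping for reruns."""

    factors: np.ndarray
    factor_names: list[str]
    chi2: float
    n_evaluations: int
    seed: int
    accepted_moves: int = 0
    schedule: AnnealSchedule | None = None
    predictions: dict[str, dict[str, float]] = field(default_factory=dict)

    def summary_dict(self) -> dict:
        return {
            "factors": {n: float(v) for n, v in zip(self.factor_names, self.factors)},
            "chi2": float(self.chi2),
            "n_evaluations": int(self.n_evaluations),
            "accepted_moves": int(self.accepted_moves),
            "seed": int(self.seed),
            "schedule": (
                {
                    "t0": self.schedule.t0,
                    "cooling": self.schedule.cooling,
                    "moves_per_temperature": self.schedule.moves_per_temperature,
                    "t_min_ratio": self.schedule.t_min_ratio,
                    "max_evaluations": self.schedule.max_evaluations,
                    "move_scale": self.schedule.move_scale,
                }
                if self.schedule
                else None
            ),
        }


def fit_anneal(
    problem: FitProblem,
    schedule: AnnealSchedule | None = None,
    *,
    bounds: tuple[float, float] | Sequence[tuple[float, float]] | None = None,
    seed: int = 0,
    x0: Sequence[float] | None = None,
    fixed: Mapping[int, float] | None = None,
    store_predictions: bool = True,
) -> FitResult:
    """Simulated annealing over the group factors.

    Proposals perturb one randomly chosen factor multiplicatively
    (log-normal step in log₁₀ space); Metropolis acceptance on X² with a
    geometric temperature ladder.  The best-ever point is returned.
    ``fixed`` pins factor indices to values (used by profile likelihood).
    Deterministic for a given seed.
    """
    schedule = schedule or AnnealSchedule()
    rng = np.random.default_rng(seed)
    n = problem.model.groups.n_factors
    x = np.array(x0 if x0 is not None else problem.initial_factors(), dtype=float)
    if x.shape != (n,):
        raise ValueError(f"expected {n} factors")
    fixed = dict(fixed or {})
    for i, v in fixed.items():
        x[i] = v
    free_idx = [i for i in range(n) if i not in fixed]
    if not free_idx:
        raise ValueError("no free factors to fit")

    if bounds is None:
        lo = x * 1e-3
        hi = x * 1e3
    elif isinstance(bounds[0], (int, float)):
        lo = np.full(n, float(bounds[0]))
        hi = np.full(n, float(bounds[1]))
    else:
        lo = np.array([b[0] for b in bounds], float)
        hi = np.array([b[1] for b in bounds], float)
    if np.any(lo <= 0):
        raise ValueError("bounds must be positive (search is in log space)")

    n_eval = 0
    f_cur = objective(x, problem)
    n_eval += 1
    best_x, best_f = x.copy(), f_cur
    accepted = 0
    budget = schedule.max_evaluations

    if budget > 0 and not np.isfinite(f_cur):
        # probe random starts until a finite objective is found
        for _ in range(50):
            if n_eval >= budget:
                break
            trial = np.array(
                [
                    10 ** rng.uniform(np.log10(lo[i]), np.log10(hi[i]))
                    if i in free_idx else x[i]
                    for i in range(n)
                ]
            )
            f_trial = objective(trial, problem)
            n_eval += 1
            if np.isfinite(f_trial):
                x, f_cur = trial, f_trial
                best_x, best_f = trial.copy(), f_trial
                break
        else:
            raise RuntimeError(
                "no finite-objective starting point found; widen the bounds "
                "or relax the model"
            )

    T = schedule.t0 if schedule.t0 is not None else max(f_cur, 1.0)
    T0_ref = T
    T_min = schedule.t_min_ratio * T
    log.info("annealing start: X²=%.4g, T0=%.4g", f_cur, T)

    while T > T_min and n_eval < budget:
        # proposal width shrinks with the temperature so late-stage moves
        # refine rather than re-explore
        scale_t = schedule.move_scale * max((T / max(T0_ref, 1e-300)) ** 0.5,
                                            0.02)
        for _ in range(schedule.moves_per_temperature):
            if n_eval >= budget:
                break
            prop = x.copy()
            if len(free_idx) > 1 and rng.random() < 0.2:
                # joint move: rescale all free factors together, which
                # traverses the correlated valley left by chain groupings
                step = 10 ** rng.normal(0.0, scale_t)
                for i in free_idx:
                    prop[i] = min(max(x[i] * step, lo[i]), hi[i])
            else:
                i = free_idx[rng.integers(len(free_idx))]
                prop[i] = x[i] * 10 ** rng.normal(0.0, scale_t)
                prop[i] = min(max(prop[i], lo[i]), hi[i])
            f_prop = objective(prop, problem)
            n_eval += 1
            d = f_prop - f_cur
            if d <= 0 or (np.isfinite(f_prop) and rng.random() < np.exp(-d / T)):
                x, f_cur = prop, f_prop
                accepted += 1
                log.debug("accepted move: factor %d -> %.4g, X²=%.4g", i, x[i], f_cur)
                if f_cur < best_f:
                    best_x, best_f = x.copy(), f_cur
                    log.info("new best X²=%.4g after %d evaluations", best_f, n_eval)
        T *= schedule.cooling

    preds = {}
    if store_predictions and np.isfinite(best_f):
        preds = problem.predictions(best_x)
    return FitResult(
        factors=best_x,
        factor_names=problem.factor_names,
        chi2=best_f,
        n_evaluations=n_eval,
        seed=seed,
        accepted_moves=accepted,
        schedule=schedule,
        predictions=preds,
    )
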