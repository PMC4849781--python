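"""Model/Results facade for multi-condition tracer-kinetics fitting.

:class:`DynamicLabelingModel` bundles a kinetic network with the
experimental conditions and the measurement table; ``fit()`` runs the
simulated-annealing estimator and returns a
:class:`DynamicLabelingResults` carrying the estimated group factors, the
best-fit objective, per-condition predictions, and methods for
profile-likelihood intervals, prediction envelopes and a text summary.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .experiments import Condition, Dataset, Observable
from .fitting import (AnnealSchedule, FitProblem, FitResult, fit_anneal,
                      objective)
from .identifiability import (EnvelopeBand, ProfileResult, chi2_threshold,
                              envelopes, profile_parameter)
from .kinetics import KineticModel
from .labeling import LabeledTrajectory, simulate_labeling

__all__ = ["DynamicLabelingModel", "DynamicLabelingResults"]


class DynamicLabelingModel:
    """A kinetic network + conditions + measurements, ready to fit."""

    def __init__(
        self,
        kinetic_model: KineticModel,
        conditions: Sequence[Condition],
        dataset: Dataset,
        *,
        rtol: float = 1e-6,
        atol: float = 1e-8,
    ):
        self.problem = FitProblem(
            model=kinetic_model,
            conditions=list(conditions),
            dataset=dataset,
            rtol=rtol,
            atol=atol,
        )

    @classmethod
    def from_files(cls, model_path, atom_map_path, conditions_path,
                   measurements_path, **kw) -> "DynamicLabelingModel":
        from .io import load_conditions, load_model

        km = load_model(model_path, atom_map_path)
        conditions = load_conditions(conditions_path)
        dataset = Dataset.from_tsv(measurements_path)
        return cls(km, conditions, dataset, **kw)

    @property
    def factor_names(self) -> list[str]:
        return self.problem.factor_names

    def objective(self, factors: Sequence[float]) -> float:
        return objective(factors, self.problem)

    def simulate(self, condition: Condition | str,
                 factors: Sequence[float] | None = None) -> LabeledTrajectory:
        cond = self._resolve(condition)
        x = (np.asarray(factors, float) if factors is not None
             else self.problem.initial_factors())
        return self.problem.simulate(x, cond)

    def _resolve(self, condition: Condition | str) -> Condition:
        if isinstance(condition, Condition):
            return condition
        for c in self.problem.conditions:
            if c.id == condition:
                return c
        raise KeyError(f"unknown condition {condition!r}")

    def fit(
        self,
        schedule: AnnealSchedule | None = None,
        *,
        seed: int = 0,
        bounds=None,
        x0: Sequence[float] | None = None,
    ) -> "DynamicLabelingResults":
        res = fit_anneal(self.problem, schedule, seed=seed, bounds=bounds,
                         x0=x0)
        return DynamicLabelingResults(self, res)


class DynamicLabelingResults:
    """Estimates, diagnostics and post-fit analyses."""

    def __init__(self, model: DynamicLabelingModel, fit_result: FitResult):
        self.model = model
        self.fit_result = fit_result
        self._profiles: dict[str, ProfileResult] = {}

    # -- estimates ---------------------------------------------------------
    @property
    def factors(self) -> pd.Series:
        return pd.Series(self.fit_result.factors,
                         index=self.fit_result.factor_names, name="factor")

    @property
    def chi2(self) -> float:
        return self.fit_result.chi2

    @property
    def n_obs(self) -> int:
        return len(self.model.problem.dataset)

    def predict(self, condition: Condition | str) -> LabeledTrajectory:
        return self.model.simulate(condition, self.fit_result.factors)

    def predicted_vs_observed(self) -> pd.DataFrame:
        """One row per measurement: observed Y, predicted Z, residual."""
        preds = self.model.problem.predictions(self.fit_result.factors)
        rows = []
        for m in self.model.problem.dataset:
            key = f"{m.observable.id}@{m.time:g}"
            z = preds.get(m.condition_id, {}).get(key, np.nan)
            rows.append(
                {
                    "condition": m.condition_id,
                    "observable": m.observable.id,
                    "time_min": m.time,
                    "observed": m.value,
                    "predicted": z,
                    "sd": m.sd,
                    "scaled_residual": (m.value - z) / m.sigma,
                }
            )
        return pd.DataFrame(rows)

    # -- identifiability ---------------------------------------------------
    def profile(self, parameter: str | int, alpha: float = 0.05,
                **kw) -> ProfileResult:
        prof = profile_parameter(self.model.problem, self.fit_result,
                                 parameter, alpha, **kw)
        self._profiles[prof.parameter] = prof
        return prof

    def profile_all(self, alpha: float = 0.05, **kw) -> list[ProfileResult]:
        return [self.profile(name, alpha, **kw)
                for name in self.fit_result.factor_names]

    def envelopes(self, condition: Condition | str, variables,
                  profiles: Sequence[ProfileResult] | None = None,
                  t_eval=None) -> list[EnvelopeBand]:
        cond = self.model._resolve(condition)
        profs = (list(profiles) if profiles is not None
                 else list(self._profiles.values()))
        return envelopes(self.model.problem, self.fit_result, profs, cond,
                         variables, t_eval)

    def profile_table(self) -> pd.DataFrame:
        rows = []
        for p in self._profiles.values():
            rows.append(
                {
                    "parameter": p.parameter,
                    "best": p.best_value,
                    "lower": p.lower if p.lower is not None else np.nan,
                    "upper": p.upper if p.upper is not None else np.nan,
                    "lower_bounded": p.lower_bounded,
                    "upper_bounded": p.upper_bounded,
                    "alpha": p.alpha,
                    "threshold": p.threshold,
                }
            )
        return pd.DataFrame(rows)

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        fr = self.fit_result
        lines = [
            "Dynamic labeling model fit (simulated annealing)",
            "=" * 48,
            f"observations: {self.n_obs}    conditions: "
            f"{len(self.model.problem.conditions)}",
            f"free factors: {len(fr.factor_names)}    "
            f"evaluations: {fr.n_evaluations}    seed: {fr.seed}",
            f"best-fit X²: {fr.chi2:.6g}",
            "",
            f"{'factor':<20}{'estimate':>12}{'lower':>12}{'upper':>12}",
            "-" * 56,
        ]
        for name, value in zip(fr.factor_names, fr.factors):
            p = self._profiles.get(name)
            lo = (f"{p.lower:.4g}" if p and p.lower is not None
                  else ("unbounded" if p else ""))
            hi = (f"{p.upper:.4g}" if p and p.upper is not None
                  else ("unbounded" if p else ""))
            lines.append(f"{name:<20}{value:>12.4g}{lo:>12}{hi:>12}")
        return "\n".join(lines)

    def to_json(self, path=None) -> str:
        doc = self.fit_result.summary_dict()
        doc["profiles"] = {
            name: {
                "best": p.best_value,
                "lower": p.lower,
                "upper": p.upper,
                "alpha": p.alpha,
                "threshold": p.threshold,
            }
            for name, p in self._profiles.items()
        }
        text = json.dumps(doc, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text
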