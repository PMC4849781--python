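"""Shared fixtures.

Demo-model trajectories are session-scoped because the joint isotopomer
system of the hepatocyte network (~860 states) takes seconds to integrate;
every test reads from the same immutable trajectory objects.
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from tracekin.experiments import Condition, Observable
from tracekin.fitting import AnnealSchedule, FitProblem
from tracekin.labeling import simulate_labeling
from tracekin.models import (condition_library, generate_synthetic_dataset,
                             make_demo_model, make_toy)


@pytest.fixture(scope="session")
def demo_model():
    return make_demo_model()


@pytest.fixture(scope="session")
def demo_conditions():
    return condition_library()


@pytest.fixture(scope="session")
def traj_A1(demo_model, demo_conditions):
    return simulate_labeling(demo_model, demo_conditions["A1"],
                             rtol=1e-6, atol=1e-8)


@pytest.fixture(scope="session")
def traj_A2(demo_model, demo_conditions):
    return simulate_labeling(demo_model, demo_conditions["A2"],
                             rtol=1e-6, atol=1e-8)


@pytest.fixture(scope="session")
def traj_B(demo_model, demo_conditions):
    return simulate_labeling(demo_model, demo_conditions["B"],
                             rtol=1e-6, atol=1e-8)


# ---------------------------------------------------------------------------
# chain3 fitting problem factory
# ---------------------------------------------------------------------------

CHAIN3_CONDITION = Condition(
    "c", tracers={"A": [(0b011, 0.5), (0, 0.5)]}, t_end=120.0
)

CHAIN3_OBSERVABLES = (
    [Observable("B", "conc"), Observable("C", "conc")]
    + [Observable("B", "mid", None, k) for k in range(4)]
    + [Observable("C", "mid", None, k) for k in range(4)]
)

# deep schedule used where the optimum must be located precisely
CHAIN3_SCHEDULE = AnnealSchedule(
    t0=20.0, cooling=0.8, moves_per_temperature=25,
    t_min_ratio=1e-8, max_evaluations=2600, move_scale=0.3,
)

# shorter schedule for replicated experiments
CHAIN3_FAST_SCHEDULE = AnnealSchedule(
    t0=20.0, cooling=0.75, moves_per_temperature=20,
    t_min_ratio=1e-7, max_evaluations=1000, move_scale=0.3,
)


def chain3_problem(noise_sd: float, seed: int,
                   times=(15.0, 45.0, 90.0)) -> FitProblem:
    model = make_toy("chain3")
    ds = generate_synthetic_dataset(
        model, [CHAIN3_CONDITION], CHAIN3_OBSERVABLES,
        noise_sd=noise_sd, seed=seed, times=times,
    )
    return FitProblem(model, [CHAIN3_CONDITION], ds)


@pytest.fixture(scope="session")
def chain3_noisefree_problem():
    return chain3_problem(0.0, seed=11)


@pytest.fixture(scope="session")
def chain3_noisy_problem():
    return chain3_problem(0.01, seed=11)
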