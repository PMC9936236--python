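"""Shared fixtures: one small phantom case with its influence matrix and an
optimized plan, reused (session-scoped, read-only) across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from moapn.dose_engine import build_influence
from moapn.dvh_metrics import DVHTable, PlanState
from moapn.init_objectives import initial_objectives
from moapn.phantom import GeometryConfig, GridSpec, generate_case
from moapn.plan_optim import OptimConfig, optimize_plan
from moapn.scoring import ScoringConfig, eva_score

SMALL_GRID = GridSpec((16, 16, 16), (5.0, 5.0, 5.0))


@pytest.fixture(scope="session")
def small_grid() -> GridSpec:
    return SMALL_GRID


@pytest.fixture(scope="session")
def small_case():
    return generate_case(1, grid=SMALL_GRID, geometry=GeometryConfig.small())


@pytest.fixture(scope="session")
def small_influence(small_case):
    return build_influence(small_case)


@pytest.fixture(scope="session")
def small_objectives(small_case):
    objectives, _ = initial_objectives(small_case)
    return objectives


@pytest.fixture(scope="session")
def small_plan(small_case, small_influence, small_objectives):
    plan = optimize_plan(small_influence, small_case, small_objectives)
    scoring = ScoringConfig.from_ring_objectives(small_objectives.ring_objectives())
    plan.eva_score = eva_score(plan, scoring)
    return plan


def stub_plan(
    d95: float = 51.0,
    eva: float = 100.0,
    ring_geud: dict[str, float] | None = None,
    ring_objectives: dict[str, float] | None = None,
) -> PlanState:
    """Minimal scored plan state for reward-logic tests."""
    dvh = DVHTable(
        bin_edges=np.arange(850) * 0.1,
        cumulative=np.zeros((850, 1)),
        structure_order=("PTV",),
    )
    return PlanState(
        weights=np.zeros(1),
        dose=np.zeros((1, 1, 1)),
        dvh=dvh,
        metrics={"ptv_d95": d95},
        eva_score=eva,
        ring_geud=ring_geud or {f"Ring{k}": 20.0 for k in range(1, 6)},
        ring_objectives=ring_objectives or {f"Ring{k}": 15.0 for k in range(1, 6)},
    )
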