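"""Hybrid gEUD / dose-volume inverse-planning objective and its minimizer.

The plan cost combines a one-sided quadratic lower objective on the PTV at
the prescription-level point, a one-sided quadratic upper objective at the
PTV maximum-dose point, and upper gEUD objectives for the six organs at
risk and the five dose-gradient rings:

    min_w  w_L^PTV <(D - D_p)^2>_lower + w_H^PTV <(D - D_max)^2>_upper
           + sum_i w_i^OAR (gEUD_i - D_EUD_i)^2_+  + sum_j w_j^ring (...)^2_+

with gEUD the generalized mean (1/V sum D^a)^(1/a): a = 40 for serial
structures and rings (near-maximum dose), a = 1 for lung (mean dose).
Point costs carry the conventional 1/2 factor and are averaged over the
structure's voxels so weights are comparable across structure volumes.
The minimization runs over non-negative beamlet weights with L-BFGS-B and
an analytic gradient; one call stands in for one optimization pass of a
treatment planning system.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import minimize

from .dose_engine import InfluenceMatrix, compute_dose
from .dvh_metrics import DVHTable, PlanState, compute_dvh, plan_metrics
from .phantom import Case, OAR_NAMES, RING_NAMES, STATE_STRUCTURES

__all__ = [
    "ObjectiveEntry",
    "ObjectiveSet",
    "OptimConfig",
    "geud",
    "cost_point",
    "cost_geud",
    "total_objective",
    "optimize_plan",
    "assemble_plan_state",
    "default_objective_set",
    "GEUD_A_SERIAL",
    "GEUD_A_PARALLEL",
    "PTV_WEIGHT",
    "OTHER_WEIGHT",
]

GEUD_A_SERIAL = 40.0
GEUD_A_PARALLEL = 1.0
PTV_WEIGHT = 300.0
OTHER_WEIGHT = 150.0

_KINDS = ("point_lower", "point_upper", "geud_upper")


@dataclass
class ObjectiveEntry:
    """One adjustable optimization objective: structure, constraint type,
    dose level (Gy), weight, and the gEUD parameter for gEUD objectives."""

    structure: str
    kind: str
    dose_gy: float
    weight: float
    a_param: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown objective kind {self.kind!r}")
        if self.weight <= 0:
            raise ValueError("objective weight must be positive")
        if self.kind == "geud_upper":
            if self.a_param is None or self.a_param == 0:
                raise ValueError("gEUD objective needs a non-zero a parameter")


@dataclass
class ObjectiveSet:
    """The full adjustable objective list of one plan.

    Exactly one lower and one upper point objective on the PTV; every other
    entry is an upper gEUD objective.  Default weights: 300 for the target,
    150 elsewhere.
    """

    entries: list[ObjectiveEntry]
    prescription_gy: float = 50.0
    ptv_max_gy: float = 67.5

    def __post_init__(self) -> None:
        for e in self.entries:
            if e.structure != "PTV" and e.kind != "geud_upper":
                raise ValueError(
                    f"{e.structure}: non-PTV objectives must be geud_upper"
                )
        lowers = [e for e in self.entries if e.kind == "point_lower"]
        uppers = [e for e in self.entries if e.kind == "point_upper"]
        if len(lowers) != 1 or lowers[0].structure != "PTV":
            raise ValueError("need exactly one PTV point_lower objective")
        if len(uppers) != 1 or uppers[0].structure != "PTV":
            raise ValueError("need exactly one PTV point_upper objective")

    def entry_for(self, structure: str, kind: str | None = None) -> ObjectiveEntry:
        for e in self.entries:
            if e.structure == structure and (kind is None or e.kind == kind):
                return e
        raise KeyError(f"no objective for {structure!r} (kind={kind})")

    def ring_objectives(self) -> dict[str, float]:
        return {
            r: self.entry_for(r, "geud_upper").dose_gy
            for r in RING_NAMES
            if any(e.structure == r for e in self.entries)
        }

    def copy(self) -> "ObjectiveSet":
        return ObjectiveSet(
            entries=[ObjectiveEntry(e.structure, e.kind, e.dose_gy, e.weight, e.a_param)
                     for e in self.entries],
            prescription_gy=self.prescription_gy,
            ptv_max_gy=self.ptv_max_gy,
        )

    # -- JSON round-trip in the tabular schema (structure / type / a / dose /
    #    weight) used for initial-objective reports
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "prescription_gy": self.prescription_gy,
            "ptv_max_gy": self.ptv_max_gy,
            "entries": [
                {
                    "structure": e.structure,
                    "objective_type": e.kind,
                    "a_param": e.a_param,
                    "dose_gy": e.dose_gy,
                    "weight": e.weight,
                }
                for e in self.entries
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ObjectiveSet":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        return cls(
            entries=[
                ObjectiveEntry(
                    structure=e["structure"],
                    kind=e["objective_type"],
                    dose_gy=e["dose_gy"],
                    weight=e["weight"],
                    a_param=e.get("a_param"),
                )
                for e in payload["entries"]
            ],
            prescription_gy=payload["prescription_gy"],
            ptv_max_gy=payload["ptv_max_gy"],
        )


# ---------------------------------------------------------------------------
# cost terms


def geud(dose_values: np.ndarray, a_param: float) -> float:
    """Generalized equivalent uniform dose: the power mean (1/V sum D^a)^(1/a).

    a = 1 returns the arithmetic mean exactly; large positive a approaches
    the maximum dose.  Negative a requires strictly positive doses.
    """
    d = np.asarray(dose_values, dtype=float)
    if d.size == 0:
        raise ValueError("gEUD of an empty dose vector is undefined")
    if a_param == 0:
        raise ValueError("gEUD parameter a must be non-zero")
    if (d < 0).any():
        raise ValueError("doses must be non-negative")
    if a_param == 1:
        return float(d.mean())
    if a_param < 0 and (d == 0).any():
        raise ValueError("zero dose with negative a makes gEUD undefined")
    dmax = float(d.max())
    if dmax == 0.0:
        return 0.0
    m = np.mean((d / dmax) ** a_param)
    return float(dmax * m ** (1.0 / a_param))


def cost_point(dose_values: np.ndarray, entry: ObjectiveEntry) -> float:
    """One-sided quadratic point cost, summed over the structure's voxels:
    (1/2) w (D - D_obj)^2 on the violating side.

    Summing (rather than averaging) makes the target terms grow with the
    number of violating voxels, so prescription coverage dominates the
    scalar gEUD terms of the rings and organs at risk — mirroring how
    clinical optimizers prioritize the target.
    """
    if entry.kind not in ("point_lower", "point_upper"):
        raise ValueError("cost_point needs a point objective")
    d = np.asarray(dose_values, dtype=float)
    if d.size == 0:
        raise ValueError("point cost of an empty structure is undefined")
    diff = d - entry.dose_gy
    if entry.kind == "point_upper":
        viol = np.maximum(diff, 0.0)
    else:
        viol = np.minimum(diff, 0.0)
    return float(0.5 * entry.weight * np.sum(viol**2))


def cost_geud(dose_values: np.ndarray, entry: ObjectiveEntry) -> float:
    """Upper gEUD cost w (gEUD - D_EUD)^2, zero when the objective is met."""
    if entry.kind != "geud_upper":
        raise ValueError("cost_geud needs a geud_upper objective")
    g = geud(dose_values, entry.a_param)
    excess = g - entry.dose_gy
    return float(entry.weight * excess**2) if excess > 0 else 0.0


def total_objective(dose: np.ndarray, case: Case, objectives: ObjectiveSet) -> float:
    """The full plan cost: PTV lower + PTV upper + all upper gEUD terms."""
    total = 0.0
    for e in objectives.entries:
        if e.structure not in case.masks:
            raise KeyError(f"objective structure {e.structure!r} not in case")
        d = np.asarray(dose, dtype=float)[case.mask(e.structure)]
        if e.kind == "geud_upper":
            total += cost_geud(d, e)
        else:
            total += cost_point(d, e)
    return total


# ---------------------------------------------------------------------------
# optimizer


@dataclass
class OptimConfig:
    """Budget and tolerances of one optimization pass."""

    maxiter: int = 300
    ftol: float = 1e-12
    gtol: float = 1e-9
    seed: int = 0


def _objective_and_grad(
    dose_body: np.ndarray,
    struct_rows: dict[str, np.ndarray],
    objectives: ObjectiveSet,
) -> tuple[float, np.ndarray]:
    """Cost and its gradient with respect to body-voxel doses."""
    total = 0.0
    grad = np.zeros_like(dose_body)
    for e in objectives.entries:
        rows = struct_rows[e.structure]
        d = dose_body[rows]
        n = d.size
        if e.kind == "geud_upper":
            g = geud(d, e.a_param)
            excess = g - e.dose_gy
            if excess > 0 and g > 0:
                total += e.weight * excess**2
                if e.a_param == 1:
                    dg = np.full(n, 1.0 / n)
                else:
                    with np.errstate(divide="ignore"):
                        dg = (d / g) ** (e.a_param - 1.0) / n
                    dg[d == 0] = 0.0
                grad[rows] += 2.0 * e.weight * excess * dg
        else:
            diff = d - e.dose_gy
            if e.kind == "point_upper":
                viol = np.maximum(diff, 0.0)
            else:
                viol = np.minimum(diff, 0.0)
            total += 0.5 * e.weight * np.sum(viol**2)
            grad[rows] += e.weight * viol
    return total, grad


def optimize_plan(
    influence: InfluenceMatrix,
    case: Case,
    objectives: ObjectiveSet,
    config: OptimConfig | None = None,
    warm_start: np.ndarray | None = None,
) -> PlanState:
    """Minimize the plan cost over non-negative beamlet weights.

    Uses L-BFGS-B with bound constraints and an analytic gradient.  The cold
    start scales uniform weights so the mean PTV dose hits the PTV lower
    objective; a warm start continues from a previous plan's weights.  The
    returned cost never exceeds the starting cost.
    """
    config = config or OptimConfig()
    A = influence.entries

    body_pos = np.full(int(np.prod(influence.grid_shape)), -1, dtype=np.int64)
    body_pos[influence.voxel_index] = np.arange(influence.n_voxels)
    struct_rows: dict[str, np.ndarray] = {}
    for e in objectives.entries:
        if e.structure not in case.masks:
            raise KeyError(f"objective structure {e.structure!r} not in case")
        rows = body_pos[np.flatnonzero(case.mask(e.structure).ravel())]
        if (rows < 0).any():
            raise ValueError(f"structure {e.structure!r} has voxels outside body")
        struct_rows[e.structure] = rows

    if warm_start is not None:
        w0 = np.asarray(warm_start, dtype=float).copy()
        if w0.shape != (influence.n_beamlets,):
            raise ValueError("warm start has wrong number of beamlets")
        w0 = np.maximum(w0, 0.0)
    else:
        ptv_rows = struct_rows["PTV"]
        unit = A @ np.ones(influence.n_beamlets)
        mean_ptv = float(unit[ptv_rows].mean())
        if mean_ptv <= 0:
            raise ValueError("PTV receives no dose from uniform beamlets")
        target = objectives.entry_for("PTV", "point_lower").dose_gy
        w0 = np.full(influence.n_beamlets, target / mean_ptv)

    trace: list[float] = []

    def fun(w: np.ndarray) -> tuple[float, np.ndarray]:
        dose_body = A @ w
        val, gd = _objective_and_grad(dose_body, struct_rows, objectives)
        if not np.isfinite(val):
            raise FloatingPointError(
                f"non-finite objective (weights range "
                f"[{w.min():.3g}, {w.max():.3g}])"
            )
        return val, A.T @ gd

    f0, _ = fun(w0)
    res = minimize(
        fun,
        w0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * influence.n_beamlets,
        callback=lambda w: trace.append(fun(w)[0]),
        options={"maxiter": config.maxiter, "ftol": config.ftol, "gtol": config.gtol},
    )
    if res.fun <= f0:
        weights, fval = np.maximum(res.x, 0.0), float(res.fun)
    else:  # monotone acceptance: never return a worse plan than the start
        weights, fval = w0, f0
    plan = assemble_plan_state(weights, influence, case, objectives)
    plan.objective_value = fval
    plan.objective_trace = [f0] + trace
    return plan


def assemble_plan_state(
    weights: np.ndarray,
    influence: InfluenceMatrix,
    case: Case,
    objectives: ObjectiveSet,
    step_index: int = 0,
) -> PlanState:
    """Compute dose, DVH (12 state structures + body), metrics and the
    per-ring gEUDs for a weight vector.

    Cases missing some canonical structures (e.g. stripped-down test
    geometries) get a DVH/metric set over the structures they do have.
    """
    dose = compute_dose(influence, weights)
    order = tuple(n for n in STATE_STRUCTURES + ("body",) if n in case.masks)
    dvh = compute_dvh(dose, case.masks, order=order)
    if all(n in case.masks for n in STATE_STRUCTURES + ("body", "D2cm")):
        metrics = plan_metrics(dose, case, dp=objectives.prescription_gy)
    else:
        from .dvh_metrics import metric_Dmax, metric_Dx

        metrics = {
            "ptv_d95": metric_Dx(dose, case.mask("PTV"), 95.0),
            "ptv_dmax": metric_Dmax(dose, case.mask("PTV")),
        }
    ring_obj = objectives.ring_objectives()
    ring_geud = {}
    for r in ring_obj:
        e = objectives.entry_for(r, "geud_upper")
        ring_geud[r] = geud(dose[case.mask(r)], e.a_param)
    return PlanState(
        weights=np.asarray(weights, dtype=float),
        dose=dose,
        dvh=dvh,
        metrics=metrics,
        step_index=step_index,
        ring_geud=ring_geud,
        ring_objectives=ring_obj,
    )


def default_objective_set(
    d_eud: dict[str, float],
    prescription_gy: float = 50.0,
) -> ObjectiveSet:
    """Build the standard-shaped objective set from per-structure D_EUD
    values (rings and OARs); PTV points at 1.04 x and 1.35 x prescription."""
    entries = [
        ObjectiveEntry("PTV", "point_lower", 1.04 * prescription_gy, PTV_WEIGHT),
        ObjectiveEntry("PTV", "point_upper", 1.35 * prescription_gy, PTV_WEIGHT),
    ]
    for name in RING_NAMES + OAR_NAMES:
        if name not in d_eud:
            continue
        a = GEUD_A_PARALLEL if name == "lung" else GEUD_A_SERIAL
        entries.append(
            ObjectiveEntry(name, "geud_upper", float(d_eud[name]), OTHER_WEIGHT, a)
        )
    return ObjectiveSet(
        entries=entries,
        prescription_gy=prescription_gy,
        ptv_max_gy=1.35 * prescription_gy,
    )
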