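"""Dose-volume histograms, plan metrics, and the planning state matrix.

The reinforcement-learning state of a plan is the cumulative DVH sampled on
850 uniform dose bins for the twelve structures of the canonical order
(PTV, Ring1-5, lung, heart, spinal cord, esophagus, bronchus, chest wall);
each ring agent sees the three columns PTV / body / its own ring.  The body
DVH is computed alongside the twelve state structures for this purpose.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .phantom import Case, STATE_STRUCTURES, RING_NAMES

__all__ = [
    "DVHTable",
    "PlanState",
    "compute_dvh",
    "metric_Dx",
    "metric_Vx",
    "metric_Dmax",
    "metric_CI",
    "metric_GI",
    "plan_metrics",
    "build_state",
    "agent_view",
    "N_BINS",
    "DOSE_AXIS_MAX_GY",
]

N_BINS = 850
#: dose axis top: 0.1 Gy bins up to 85 Gy (1.7 x the 50 Gy prescription)
DOSE_AXIS_MAX_GY = 85.0


@dataclass
class DVHTable:
    """Cumulative DVH: fraction of each structure receiving >= each bin edge."""

    bin_edges: np.ndarray  # (n_bins,) Gy
    cumulative: np.ndarray  # (n_bins, n_structures) in [0, 1]
    structure_order: tuple[str, ...]

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.structure_order.index(name)
        except ValueError:
            raise KeyError(f"structure {name!r} not in DVH table") from None
        return self.cumulative[:, j]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.cumulative, columns=list(self.structure_order))
        df.insert(0, "dose_gy", self.bin_edges)
        return df

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path, index=False)
        return path


@dataclass
class PlanState:
    """One optimized plan: beamlet weights, dose, DVH, metrics and score."""

    weights: np.ndarray
    dose: np.ndarray
    dvh: DVHTable
    metrics: dict[str, float]
    eva_score: float | None = None
    step_index: int = 0
    objective_value: float | None = None
    ring_geud: dict[str, float] = field(default_factory=dict)
    ring_objectives: dict[str, float] = field(default_factory=dict)
    objective_trace: list[float] = field(default_factory=list)


def compute_dvh(
    dose: np.ndarray,
    masks: dict[str, np.ndarray],
    n_bins: int = N_BINS,
    d_max_axis: float = DOSE_AXIS_MAX_GY,
    order: tuple[str, ...] | None = None,
) -> DVHTable:
    """Cumulative DVH on uniform bins: entry (b, s) is the fraction of
    structure s receiving at least ``bin_edges[b]`` Gy.

    Empty structures yield a zero column (with a warning) rather than an
    error, so partially degenerate cases remain inspectable.
    """
    order = tuple(order) if order is not None else tuple(masks)
    edges = np.arange(n_bins) * (d_max_axis / n_bins)
    cum = np.zeros((n_bins, len(order)))
    flat = np.asarray(dose, dtype=float).ravel()
    for j, name in enumerate(order):
        if name not in masks:
            raise KeyError(f"structure {name!r} missing from masks")
        sel = np.flatnonzero(np.asarray(masks[name]).ravel())
        if sel.size == 0:
            import warnings

            warnings.warn(f"structure {name!r} is empty; DVH column set to 0")
            continue
        d = np.sort(flat[sel])
        cum[:, j] = 1.0 - np.searchsorted(d, edges, side="left") / d.size
    return DVHTable(bin_edges=edges, cumulative=cum, structure_order=order)


# ---------------------------------------------------------------------------
# scalar metrics (computed directly from voxel doses, not from binned DVHs)


def _structure_doses(dose: np.ndarray, mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("metric requested on an empty structure")
    return np.asarray(dose, dtype=float)[mask]


def metric_Dx(dose: np.ndarray, mask: np.ndarray, x_percent: float) -> float:
    """Minimum dose received by the hottest x% of the volume (Gy).

    D95 is the dose that 95% of the structure receives at least, i.e. the
    (100 - x)th percentile of the voxel doses, linearly interpolated.
    """
    if not 0 < x_percent <= 100:
        raise ValueError("x must be in (0, 100]")
    return float(np.quantile(_structure_doses(dose, mask), 1.0 - x_percent / 100.0))


def metric_Vx(dose: np.ndarray, mask: np.ndarray, x_gy: float) -> float:
    """Percent of the structure volume receiving more than x Gy."""
    d = _structure_doses(dose, mask)
    return float(100.0 * np.mean(d > x_gy))


def metric_Dmax(dose: np.ndarray, mask: np.ndarray) -> float:
    return float(_structure_doses(dose, mask).max())


def metric_CI(dose: np.ndarray, ptv: np.ndarray, body: np.ndarray, dp: float) -> float:
    """Paddick-style conformity index (TV_RI/TV) x (TV_RI/V_RI), where TV_RI
    is the target volume covered by the prescription isodose and V_RI the
    total body volume covered."""
    dose = np.asarray(dose, dtype=float)
    ptv = np.asarray(ptv, dtype=bool)
    body = np.asarray(body, dtype=bool)
    tv = int(ptv.sum())
    if tv == 0:
        raise ValueError("empty PTV")
    iso = dose >= dp
    tv_ri = int((iso & ptv).sum())
    v_ri = int((iso & body).sum())
    if v_ri == 0:
        raise ValueError("prescription isodose volume is empty; CI undefined")
    return (tv_ri / tv) * (tv_ri / v_ri)


def metric_GI(dose: np.ndarray, body: np.ndarray, dp: float) -> float:
    """Gradient index V50% / Vp: volume covered by half the prescription dose
    over the volume covered by the prescription dose."""
    d = np.asarray(dose, dtype=float)[np.asarray(body, dtype=bool)]
    vp = int((d >= dp).sum())
    if vp == 0:
        raise ValueError("prescription isodose volume is empty; GI undefined")
    v50 = int((d >= 0.5 * dp).sum())
    return v50 / vp


def plan_metrics(dose: np.ndarray, case: Case, dp: float = 50.0) -> dict[str, float]:
    """All scalar metrics the plan-quality score needs, plus D2cm Dmax.

    CI and GI are undefined when no voxel reaches the prescription dose;
    so the adjustment loop can keep scoring such degenerate plans (they
    are about to be terminally penalized for lost coverage anyway), this
    aggregator substitutes the worst-case finite values CI = 0 and
    GI = the voxel count of the half-prescription isodose.
    """
    m = case.masks
    body_dose = np.asarray(dose, dtype=float)[m["body"]]
    try:
        ci = metric_CI(dose, m["PTV"], m["body"], dp)
        gi = metric_GI(dose, m["body"], dp)
    except ValueError:
        ci = 0.0
        gi = float(max((body_dose >= 0.5 * dp).sum(), 1))
    out: dict[str, float] = {
        "ptv_d95": metric_Dx(dose, m["PTV"], 95.0),
        "ptv_dmax": metric_Dmax(dose, m["PTV"]),
        "ptv_ci": ci,
        "ptv_gi": gi,
        "lung_v5": metric_Vx(dose, m["lung"], 5.0),
        "d2cm_dmax": metric_Dmax(dose, m["D2cm"]),
    }
    for name in ("chest_wall", "spinal_cord", "heart", "esophagus", "bronchus"):
        out[f"{name}_dmax"] = metric_Dmax(dose, m[name])
    for rk in RING_NAMES:
        out[f"{rk.lower()}_dmax"] = metric_Dmax(dose, m[rk])
    return out


# ---------------------------------------------------------------------------
# RL state


def build_state(plan: PlanState) -> np.ndarray:
    """The 850 x 12 DVH state matrix in canonical structure order."""
    cols = []
    for name in STATE_STRUCTURES:
        cols.append(plan.dvh.column(name))
    return np.column_stack(cols)


def agent_view(dvh: DVHTable, ring: str) -> np.ndarray:
    """The 850 x 3 per-agent input: DVH columns of PTV, body and the agent's
    own ring structure."""
    if ring not in RING_NAMES:
        raise ValueError(f"unknown ring {ring!r}")
    return np.column_stack([dvh.column("PTV"), dvh.column("body"), dvh.column(ring)])
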