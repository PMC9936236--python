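"""Additive plan-quality score Eva(s).

Fourteen criteria, each a (piecewise) linear function of one plan metric:

======================  ==============  =======================================
criterion               metric          score
======================  ==============  =======================================
ptv_d95                 D95 (Gy)        100 if D95 >= 50, else 100*(D95-48.5)/1.5
ptv_ci                  CI              100*(CI - 0.75)/(1 - 0.75)
ptv_gi                  GI              100*(GI - 3.75)/(3 - 3.75)
ring1..ring5_dmax       Dmax (Gy)       100*(D_ref - Dmax)/500
chest_wall_dmax         Dmax (Gy)       50*(50 - Dmax)/(50 - 20)
spinal_cord_dmax        Dmax (Gy)       50*(15 - Dmax)/15
heart_dmax              Dmax (Gy)       50*(15 - Dmax)/15
lung_v5                 V5 (%)          50*(35 - V5)/35
bronchus_dmax           Dmax (Gy)       50*(15 - Dmax)/15
esophagus_dmax          Dmax (Gy)       50*(15 - Dmax)/15
======================  ==============  =======================================

Only the PTV D95 criterion is capped (at 100); all other criteria are
uncapped linear functions and may go negative, so the score keeps a
gradient everywhere.  The per-ring reference dose D_ref defaults to the
ring's initial optimization objective (the patient-specific starting
value), which makes the ring criteria measure improvement over the
initializer; fixed references can be configured instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .dvh_metrics import PlanState
from .phantom import RING_NAMES

__all__ = ["ScoringConfig", "score_criterion", "eva_breakdown", "eva_score",
           "CRITERIA"]

#: criterion name -> plan-metric key, in reporting order
CRITERIA: tuple[str, ...] = (
    "ptv_d95",
    "ptv_ci",
    "ptv_gi",
    "ring1_dmax",
    "ring2_dmax",
    "ring3_dmax",
    "ring4_dmax",
    "ring5_dmax",
    "chest_wall_dmax",
    "spinal_cord_dmax",
    "heart_dmax",
    "lung_v5",
    "bronchus_dmax",
    "esophagus_dmax",
)


@dataclass
class ScoringConfig:
    """Thresholds of the scoring table plus the per-ring reference doses."""

    d_ref: dict[str, float] = field(
        default_factory=lambda: {r: 50.0 for r in RING_NAMES}
    )
    d95_full_gy: float = 50.0
    d95_floor_gy: float = 48.5
    ci_low: float = 0.75
    gi_low: float = 3.75
    gi_best: float = 3.0
    chest_wall_zero_gy: float = 50.0
    chest_wall_span_gy: float = 30.0
    serial_zero_gy: float = 15.0
    lung_v5_zero_pct: float = 35.0

    def __post_init__(self) -> None:
        missing = [r for r in RING_NAMES if r not in self.d_ref]
        if missing:
            raise ValueError(f"d_ref missing rings: {missing}")
        if any(v <= 0 for v in self.d_ref.values()):
            raise ValueError("ring reference doses must be positive")

    @classmethod
    def from_ring_objectives(cls, ring_objectives: dict[str, float],
                             **kwargs) -> "ScoringConfig":
        """Tie each ring's D_ref to its initial optimization objective."""
        return cls(d_ref={r: float(v) for r, v in ring_objectives.items()}, **kwargs)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {k: v for k, v in self.__dict__.items()}
        path.write_text(yaml.safe_dump(payload))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScoringConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(**payload)


def score_criterion(
    name: str, metric_value: float, config: ScoringConfig | None = None
) -> float:
    """Score of one criterion at a metric value, per the scoring table."""
    cfg = config or ScoringConfig()
    v = float(metric_value)
    if name == "ptv_d95":
        if v >= cfg.d95_full_gy:
            return 100.0
        return 100.0 * (v - cfg.d95_floor_gy) / (cfg.d95_full_gy - cfg.d95_floor_gy)
    if name == "ptv_ci":
        return 100.0 * (v - cfg.ci_low) / (1.0 - cfg.ci_low)
    if name == "ptv_gi":
        return 100.0 * (v - cfg.gi_low) / (cfg.gi_best - cfg.gi_low)
    for k, ring in enumerate(RING_NAMES, start=1):
        if name == f"ring{k}_dmax":
            return 100.0 * (cfg.d_ref[ring] - v) / 500.0
    if name == "chest_wall_dmax":
        return 50.0 * (cfg.chest_wall_zero_gy - v) / cfg.chest_wall_span_gy
    if name in ("spinal_cord_dmax", "heart_dmax", "bronchus_dmax", "esophagus_dmax"):
        return 50.0 * (cfg.serial_zero_gy - v) / cfg.serial_zero_gy
    if name == "lung_v5":
        return 50.0 * (cfg.lung_v5_zero_pct - v) / cfg.lung_v5_zero_pct
    raise ValueError(f"unknown scoring criterion {name!r}")


def eva_breakdown(
    metrics: dict[str, float], config: ScoringConfig | None = None
) -> pd.DataFrame:
    """Per-criterion (metric, score) table for one plan."""
    missing = [c for c in CRITERIA if c not in metrics]
    if missing:
        raise ValueError(f"metrics missing for criteria: {missing}")
    rows = [
        {
            "criterion": c,
            "metric": float(metrics[c]),
            "score": score_criterion(c, metrics[c], config),
        }
        for c in CRITERIA
    ]
    return pd.DataFrame(rows)


def eva_score(
    plan: PlanState | dict[str, float], config: ScoringConfig | None = None
) -> float:
    """Total plan-quality score: the sum of all fourteen criterion scores."""
    metrics = plan.metrics if isinstance(plan, PlanState) else plan
    return float(eva_breakdown(metrics, config)["score"].sum())
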