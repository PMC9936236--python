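"""Patient-specific initial optimization objectives from a predicted dose.

Three steps: (1) predict a 3D dose distribution for the case, (2) reduce it
to smooth cumulative dose-volume curves, (3) read one statistic per
structure off the curves and emit it as that structure's starting
``D_EUD``.  Because every non-PTV objective is a gEUD objective, the
matching statistic is the gEUD (a = 40 for serial structures and rings,
a = 1 for lung) of the predicted dose.

Two predictors are available.  The default ``heuristic`` predictor places
the prescription dose (x 1.02) inside the PTV and decays it exponentially
with the physical distance to the PTV surface, with a falloff length
calibrated once against optimizer-generated reference plans on synthetic
cases.  The optional ``learned`` predictor is a gradient-boosted regressor
on per-voxel geometric features (structure-label encoding, distance to the
PTV, depth from the body surface), trained on pipeline-generated
(case, reference dose) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .dvh_metrics import DVHTable, compute_dvh
from .phantom import Case, OAR_NAMES, RING_NAMES, STATE_STRUCTURES
from .plan_optim import (
    GEUD_A_PARALLEL,
    GEUD_A_SERIAL,
    ObjectiveSet,
    default_objective_set,
    geud,
)

__all__ = [
    "StructureEncoding",
    "PredictedDose",
    "DosePredictor",
    "encode_case",
    "predict_dose",
    "fit_falloff",
    "dose_to_dvh_curves",
    "curves_to_objectives",
    "initial_objectives",
    "DEFAULT_FALLOFF_MM",
]

#: heuristic falloff length (mm), calibrated once with :func:`fit_falloff`
#: against optimizer-generated reference plans on default-geometry cases
DEFAULT_FALLOFF_MM = 13.0

#: PTV dose plateau of the heuristic predictor, as a fraction of prescription
_PTV_PLATEAU = 1.02


@dataclass(frozen=True)
class StructureEncoding:
    """Single-channel label values per structure; 0 outside the body.

    PTV 1.0, heart 0.88, spinal cord 0.75, esophagus 0.63, chest wall 0.5,
    bronchus 0.43; lung (0.3) and unlabeled body tissue (0.1) fill the
    remaining levels.  Overlaps resolve by priority PTV > OARs > lung > body.
    """

    label_values: dict[str, float] = field(
        default_factory=lambda: {
            "PTV": 1.0,
            "heart": 0.88,
            "spinal_cord": 0.75,
            "esophagus": 0.63,
            "chest_wall": 0.50,
            "bronchus": 0.43,
            "lung": 0.30,
            "body": 0.10,
        }
    )

    def __post_init__(self) -> None:
        vals = list(self.label_values.values())
        if len(set(vals)) != len(vals):
            raise ValueError("label values must be distinct")


@dataclass
class PredictedDose:
    """A predicted 3D dose distribution and where it came from."""

    dose: np.ndarray
    provenance: str  # "heuristic" | "learned"

    def __post_init__(self) -> None:
        if not np.isfinite(self.dose).all() or (self.dose < 0).any():
            raise ValueError("predicted dose must be finite and non-negative")


def encode_case(case: Case, encoding: StructureEncoding | None = None) -> np.ndarray:
    """Single-channel voxel encoding of the case's structures.

    Painted lowest-priority first (body, lung, then OARs in increasing label
    value, PTV last) so overlapping voxels keep the highest-priority label.
    """
    enc = encoding or StructureEncoding()
    present = [n for n in case.masks if n in enc.label_values]
    needed = [n for n in ("PTV", "body") if n not in present]
    if needed:
        raise ValueError(f"encoding is missing labels for {needed}")
    out = np.zeros(case.grid.shape)
    order = sorted(
        (n for n in present if n != "PTV"), key=lambda n: enc.label_values[n]
    ) + ["PTV"]
    for name in order:
        out[case.mask(name)] = enc.label_values[name]
    return out


def _distance_to_ptv_mm(case: Case) -> np.ndarray:
    return ndimage.distance_transform_edt(
        ~case.mask("PTV"), sampling=case.grid.spacing_mm
    )


def predict_dose(
    case: Case,
    prescription_gy: float = 50.0,
    mode: str = "heuristic",
    falloff_mm: float = DEFAULT_FALLOFF_MM,
    model: "DosePredictor | None" = None,
) -> PredictedDose:
    """Predict the 3D dose for a case.

    ``heuristic``: prescription plateau inside the PTV, exponential decay
    exp(-d / falloff) with distance d to the PTV outside, zero outside the
    body.  ``learned`` requires a fitted :class:`DosePredictor`.
    Deterministic in both modes.
    """
    if mode == "heuristic":
        dist = _distance_to_ptv_mm(case)
        dose = _PTV_PLATEAU * prescription_gy * np.exp(-dist / falloff_mm)
        dose[~case.mask("body")] = 0.0
        return PredictedDose(dose=dose, provenance="heuristic")
    if mode == "learned":
        if model is None or not model.is_fitted:
            raise ValueError(
                "learned mode needs a fitted DosePredictor; train one with "
                "DosePredictor.fit(cases, doses) or use mode='heuristic'"
            )
        return PredictedDose(dose=model.predict(case), provenance="learned")
    raise ValueError(f"unknown prediction mode {mode!r}")


def fit_falloff(
    cases: list[Case],
    doses: list[np.ndarray],
    prescription_gy: float = 50.0,
    max_distance_mm: float = 40.0,
    min_dose_gy: float = 0.5,
) -> float:
    """Calibrate the heuristic falloff length from reference plans.

    Regresses log(dose / plateau) against distance-to-PTV over body voxels
    outside the PTV; the slope's negative reciprocal is the falloff in mm.
    """
    xs, ys = [], []
    plateau = _PTV_PLATEAU * prescription_gy
    for case, dose in zip(cases, doses):
        dist = _distance_to_ptv_mm(case)
        sel = (
            case.mask("body")
            & ~case.mask("PTV")
            & (dist <= max_distance_mm)
            & (dose >= min_dose_gy)
        )
        xs.append(dist[sel])
        ys.append(np.log(dose[sel] / plateau))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if x.size < 10:
        raise ValueError("not enough falloff voxels to fit")
    slope = float(np.sum(x * y) / np.sum(x * x))  # zero-intercept fit
    if slope >= 0:
        raise ValueError("reference doses do not fall off with distance")
    return -1.0 / slope


class DosePredictor:
    """Per-voxel dose regressor on geometric features.

    Features: encoded structure label, distance to the PTV (mm), depth from
    the body surface (mm).  Fitted on pipeline-generated reference plans;
    deterministic given the seed.
    """

    def __init__(self, seed: int = 0, encoding: StructureEncoding | None = None):
        from sklearn.ensemble import HistGradientBoostingRegressor

        self.encoding = encoding or StructureEncoding()
        self._model = HistGradientBoostingRegressor(
            max_iter=150, random_state=int(seed)
        )
        self.is_fitted = False

    def _features(self, case: Case) -> tuple[np.ndarray, np.ndarray]:
        body = case.mask("body")
        labels = encode_case(case, self.encoding)
        dist_ptv = _distance_to_ptv_mm(case)
        depth = ndimage.distance_transform_edt(body, sampling=case.grid.spacing_mm)
        sel = body.ravel()
        X = np.column_stack(
            [labels.ravel()[sel], dist_ptv.ravel()[sel], depth.ravel()[sel]]
        )
        return X, sel

    def fit(self, cases: list[Case], doses: list[np.ndarray]) -> "DosePredictor":
        Xs, ys = [], []
        for case, dose in zip(cases, doses):
            X, sel = self._features(case)
            Xs.append(X)
            ys.append(np.asarray(dose, dtype=float).ravel()[sel])
        self._model.fit(np.vstack(Xs), np.concatenate(ys))
        self.is_fitted = True
        return self

    def predict(self, case: Case) -> np.ndarray:
        if not self.is_fitted:
            raise ValueError("DosePredictor is not fitted")
        X, sel = self._features(case)
        dose = np.zeros(int(np.prod(case.grid.shape)))
        dose[sel] = np.maximum(self._model.predict(X), 0.0)
        return dose.reshape(case.grid.shape)


def dose_to_dvh_curves(predicted: PredictedDose, case: Case) -> DVHTable:
    """Cumulative dose-volume curves of the predicted dose for the twelve
    state structures plus the body."""
    return compute_dvh(predicted.dose, case.masks, order=STATE_STRUCTURES + ("body",))


def _geud_from_curve(dvh: DVHTable, structure: str, a_param: float) -> float:
    """gEUD read off a cumulative DVH column via its differential weights."""
    cum = dvh.column(structure)
    edges = dvh.bin_edges
    width = edges[1] - edges[0]
    centers = edges + 0.5 * width
    frac = np.empty_like(cum)
    frac[:-1] = cum[:-1] - cum[1:]
    frac[-1] = cum[-1]
    frac = np.maximum(frac, 0.0)
    total = frac.sum()
    if total <= 0:
        return 0.0
    frac /= total
    if a_param == 1:
        return float(np.sum(frac * centers))
    top = centers[frac > 0].max()
    m = np.sum(frac * (centers / top) ** a_param)
    return float(top * m ** (1.0 / a_param))


def curves_to_objectives(
    dvh: DVHTable,
    case: Case,
    prescription_gy: float = 50.0,
    min_objective_gy: float = 0.5,
    relaxation: float = 1.2,
) -> ObjectiveSet:
    """Convert predicted dose-volume curves into the initial objective set.

    PTV: point lower at 1.04 x prescription (weight 300) and point upper at
    1.35 x prescription (weight 300).  Each ring and OAR: upper gEUD
    objective at ``relaxation`` times the gEUD of its predicted-dose curve
    (weight 150), floored at ``min_objective_gy``.

    The relaxation deliberately starts the gEUD objectives a little loose,
    like a clinical starting template: the first optimization then meets
    the prescription comfortably and the adjustment policy has room to
    tighten the rings over subsequent steps.
    """
    missing = [s for s in STATE_STRUCTURES if s not in dvh.structure_order]
    if missing:
        raise ValueError(f"DVH table missing structures: {missing}")
    if relaxation <= 0:
        raise ValueError("relaxation factor must be positive")
    d_eud: dict[str, float] = {}
    for name in RING_NAMES + OAR_NAMES:
        a = GEUD_A_PARALLEL if name == "lung" else GEUD_A_SERIAL
        d_eud[name] = max(
            relaxation * _geud_from_curve(dvh, name, a), min_objective_gy
        )
    return default_objective_set(d_eud, prescription_gy=prescription_gy)


def initial_objectives(
    case: Case,
    prescription_gy: float = 50.0,
    mode: str = "heuristic",
    falloff_mm: float = DEFAULT_FALLOFF_MM,
    model: DosePredictor | None = None,
) -> tuple[ObjectiveSet, PredictedDose]:
    """The full three-step initializer: predict, form curves, emit objectives."""
    predicted = predict_dose(
        case, prescription_gy, mode=mode, falloff_mm=falloff_mm, model=model
    )
    curves = dose_to_dvh_curves(predicted, case)
    return curves_to_objectives(curves, case, prescription_gy), predicted
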