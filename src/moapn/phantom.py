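"""Synthetic thoracic phantom generation.

Builds randomized voxelized cases for lung SBRT planning experiments: an
ellipsoidal clinical target volume (CTV) placed peripherally inside the
affected lung, surrounded by the usual thoracic organs at risk, a 5 mm
CTV-to-PTV expansion, five concentric dose-gradient ring structures outside
the PTV, and a ``D2cm`` evaluation shell.  Every distance is handled in
physical millimetres; dilations use a Euclidean distance transform so that
margins are exact regardless of voxel size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "GridSpec",
    "GeometryConfig",
    "Case",
    "expand_margin",
    "shrink_margin",
    "make_rings",
    "make_d2cm",
    "generate_case",
    "validate_case",
    "save_case",
    "load_case",
    "STATE_STRUCTURES",
    "OAR_NAMES",
    "RING_NAMES",
]

#: canonical structure order of the 850 x 12 planning state
STATE_STRUCTURES = (
    "PTV",
    "Ring1",
    "Ring2",
    "Ring3",
    "Ring4",
    "Ring5",
    "lung",
    "heart",
    "spinal_cord",
    "esophagus",
    "bronchus",
    "chest_wall",
)

OAR_NAMES = ("chest_wall", "spinal_cord", "heart", "lung", "esophagus", "bronchus")
RING_NAMES = ("Ring1", "Ring2", "Ring3", "Ring4", "Ring5")


@dataclass(frozen=True)
class GridSpec:
    """Voxel grid geometry: array shape and per-axis spacing in mm."""

    shape: tuple[int, int, int] = (64, 64, 48)
    spacing_mm: tuple[float, float, float] = (2.5, 2.5, 2.5)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.spacing_mm) != 3:
            raise ValueError("GridSpec is three-dimensional")
        if any(int(n) < 16 for n in self.shape):
            raise ValueError(f"all grid dimensions must be >= 16, got {self.shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("voxel spacing must be positive")

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.shape, self.spacing_mm))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def coords_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-centre coordinates (mm) on each axis, centred on the grid."""
        return tuple(
            (np.arange(n) - (n - 1) / 2.0) * s
            for n, s in zip(self.shape, self.spacing_mm)
        )


@dataclass(frozen=True)
class GeometryConfig:
    """Randomization ranges and fixed anatomy parameters for case generation.

    The defaults encode the study conditions: a 5 mm CTV-to-PTV margin, five
    4 mm-wide rings at 0.3 / 1.0 / 2.4 / 4.4 / 6.0 cm outside the PTV and a
    1 cm-wide D2cm shell starting 2 cm outside the PTV.  :meth:`small` gives a
    proportionally shrunk geometry for 16-cube smoke-scale grids where the
    full-size ring distances physically do not fit.
    """

    ctv_radius_range_mm: tuple[float, float] = (8.0, 15.0)
    ptv_margin_mm: float = 5.0
    ring_distances_cm: tuple[float, ...] = (0.3, 1.0, 2.4, 4.4, 6.0)
    ring_width_mm: float = 4.0
    d2cm_inner_cm: float = 2.0
    d2cm_width_cm: float = 1.0
    body_radius_fraction: float = 0.47
    lung_center_fraction: float = -0.40  # x offset of lung centre, in body radii
    lung_semiaxes_fraction: tuple[float, float, float] = (0.50, 0.62, 0.78)
    ctv_radial_fraction_range: tuple[float, float] = (0.40, 0.70)
    chest_wall_thickness_mm: float = 10.0
    cord_radius_mm: float = 5.0
    esophagus_radius_mm: float = 5.0
    bronchus_radius_mm: float = 6.0
    heart_radius_fraction: float = 0.33
    max_placement_attempts: int = 60

    @classmethod
    def default(cls) -> "GeometryConfig":
        return cls()

    @classmethod
    def small(cls) -> "GeometryConfig":
        """Scaled-down geometry for 16x16x16 grids at 5 mm spacing."""
        return cls(
            ctv_radius_range_mm=(4.0, 6.0),
            ptv_margin_mm=5.0,
            ring_distances_cm=(0.2, 0.7, 1.2, 1.7, 2.2),
            ring_width_mm=4.0,
            d2cm_inner_cm=0.8,
            d2cm_width_cm=0.5,
            ctv_radial_fraction_range=(0.25, 0.55),
            chest_wall_thickness_mm=8.0,
            cord_radius_mm=6.0,
            esophagus_radius_mm=6.0,
            bronchus_radius_mm=7.0,
        )


@dataclass
class Case:
    """One synthetic planning case: grid geometry plus named boolean masks."""

    grid: GridSpec
    masks: dict[str, np.ndarray]
    seed: int
    meta: dict = field(default_factory=dict)

    def mask(self, name: str) -> np.ndarray:
        try:
            return self.masks[name]
        except KeyError:
            raise KeyError(
                f"structure {name!r} not in case (have {sorted(self.masks)})"
            ) from None

    def volume_cc(self, name: str) -> float:
        return float(self.mask(name).sum()) * self.grid.voxel_volume_mm3 / 1000.0


# ---------------------------------------------------------------------------
# morphology


def expand_margin(mask: np.ndarray, margin_mm: float, grid: GridSpec) -> np.ndarray:
    """Isotropic 3D dilation of ``mask`` by ``margin_mm`` (physical units).

    Implemented as a threshold on the Euclidean distance transform of the
    complement, so the margin is exact in mm rather than a whole number of
    voxels.  ``margin_mm = 0`` returns the input unchanged.
    """
    mask = np.asarray(mask, dtype=bool)
    if margin_mm < 0:
        raise ValueError("margin must be non-negative")
    if not mask.any():
        raise ValueError("cannot expand an empty mask")
    if mask.shape != grid.shape:
        raise ValueError(f"mask shape {mask.shape} != grid shape {grid.shape}")
    if margin_mm > max(grid.extent_mm):
        raise ValueError(
            f"margin {margin_mm} mm exceeds grid extent {max(grid.extent_mm)} mm"
        )
    if margin_mm == 0:
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask, sampling=grid.spacing_mm)
    return dist <= margin_mm


def shrink_margin(mask: np.ndarray, margin_mm: float, grid: GridSpec) -> np.ndarray:
    """Isotropic erosion by ``margin_mm``; dual of :func:`expand_margin`."""
    mask = np.asarray(mask, dtype=bool)
    if margin_mm < 0:
        raise ValueError("margin must be non-negative")
    if margin_mm == 0:
        return mask.copy()
    dist = ndimage.distance_transform_edt(mask, sampling=grid.spacing_mm)
    return dist > margin_mm


def make_rings(
    ptv: np.ndarray,
    grid: GridSpec,
    distances_cm: tuple[float, ...] = (0.3, 1.0, 2.4, 4.4, 6.0),
    width_mm: float = 4.0,
    body: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Concentric ring structures outside the PTV.

    Ring_k is the shell between the ``d_k`` and ``d_k + width`` isotropic
    expansions of the PTV, clipped to the body contour.  Consecutive shells
    must not overlap.
    """
    if width_mm <= 0:
        raise ValueError("ring width must be positive")
    dist_mm = [10.0 * d for d in distances_cm]
    for i in range(len(dist_mm) - 1):
        if dist_mm[i + 1] <= dist_mm[i]:
            raise ValueError(
                f"ring distances must be strictly increasing: "
                f"d{i + 1}={distances_cm[i]} cm vs d{i + 2}={distances_cm[i + 1]} cm"
            )
        if dist_mm[i] + width_mm > dist_mm[i + 1]:
            raise ValueError(
                f"rings {i + 1} and {i + 2} overlap: {distances_cm[i]} cm + "
                f"{width_mm} mm width reaches past {distances_cm[i + 1]} cm"
            )
    rings: dict[str, np.ndarray] = {}
    for k, d in enumerate(dist_mm, start=1):
        outer = expand_margin(ptv, d + width_mm, grid)
        inner = expand_margin(ptv, d, grid)
        ring = outer & ~inner
        if body is not None:
            ring &= body
        rings[f"Ring{k}"] = ring
    return rings


def make_d2cm(
    ptv: np.ndarray,
    grid: GridSpec,
    body: np.ndarray | None = None,
    inner_cm: float = 2.0,
    width_cm: float = 1.0,
) -> np.ndarray:
    """Evaluation shell between the ``inner`` and ``inner + width`` expansions
    of the PTV (2-3 cm by default); used for dose-gradient reporting only."""
    if width_cm <= 0:
        raise ValueError("D2cm width must be positive")
    outer = expand_margin(ptv, 10.0 * (inner_cm + width_cm), grid)
    inner = expand_margin(ptv, 10.0 * inner_cm, grid)
    shell = outer & ~inner
    if body is not None:
        shell &= body
    if not shell.any():
        raise ValueError(
            "D2cm shell is empty: the PTV is too close to the body surface or "
            "grid boundary for the requested expansion"
        )
    return shell


# ---------------------------------------------------------------------------
# case generation


def _ellipsoid(
    coords: tuple[np.ndarray, np.ndarray, np.ndarray],
    center: tuple[float, float, float],
    semiaxes: tuple[float, float, float],
) -> np.ndarray:
    x, y, z = coords
    u = (x[:, None, None] - center[0]) / semiaxes[0]
    v = (y[None, :, None] - center[1]) / semiaxes[1]
    w = (z[None, None, :] - center[2]) / semiaxes[2]
    return u**2 + v**2 + w**2 <= 1.0


def _cylinder_z(
    coords: tuple[np.ndarray, np.ndarray, np.ndarray],
    center_xy: tuple[float, float],
    radius_mm: float,
    z_range: tuple[float, float] | None = None,
) -> np.ndarray:
    x, y, z = coords
    r2 = (x[:, None, None] - center_xy[0]) ** 2 + (y[None, :, None] - center_xy[1]) ** 2
    m = np.broadcast_to(r2 <= radius_mm**2, (x.size, y.size, z.size)).copy()
    if z_range is not None:
        zmask = (z >= z_range[0]) & (z <= z_range[1])
        m &= zmask[None, None, :]
    return m


def generate_case(
    seed: int,
    grid: GridSpec | None = None,
    geometry: GeometryConfig | None = None,
) -> Case:
    """Generate one randomized synthetic thoracic case.

    Deterministic given ``seed``.  Raises ``RuntimeError`` if no feasible CTV
    placement (all rings non-empty, PTV inside body) is found within the
    configured number of attempts.
    """
    grid = grid or GridSpec()
    geo = geometry or GeometryConfig()
    rng = np.random.default_rng(seed)
    coords = grid.coords_mm()
    x, y, z = coords
    ext = grid.extent_mm

    body_radius = geo.body_radius_fraction * min(ext[0], ext[1])
    body = _cylinder_z(coords, (0.0, 0.0), body_radius)

    lung_c = (geo.lung_center_fraction * body_radius, 0.0, 0.0)
    lung_semi = (
        geo.lung_semiaxes_fraction[0] * body_radius,
        geo.lung_semiaxes_fraction[1] * body_radius,
        geo.lung_semiaxes_fraction[2] * ext[2] / 2.0,
    )
    lung = _ellipsoid(coords, lung_c, lung_semi) & body

    # organs at risk (built first: a peripheral lesion's PTV must not touch
    # the serial organs, so placement below rejects overlapping draws)
    cw_shell = body & ~shrink_margin(body, geo.chest_wall_thickness_mm, grid)
    ipsi = x[:, None, None] <= 0.0 if lung_c[0] <= 0 else x[:, None, None] >= 0.0
    zin = (z >= lung_c[2] - lung_semi[2]) & (z <= lung_c[2] + lung_semi[2])
    chest_wall = cw_shell & np.broadcast_to(ipsi, grid.shape) & zin[None, None, :]

    spinal_cord = (
        _cylinder_z(coords, (0.0, -0.78 * body_radius), geo.cord_radius_mm) & body
    )
    esophagus = (
        _cylinder_z(coords, (0.12 * body_radius, -0.35 * body_radius),
                    geo.esophagus_radius_mm)
        & body
    )
    bronchus = (
        _cylinder_z(
            coords,
            (0.15 * body_radius * np.sign(lung_c[0] or -1.0), 0.05 * body_radius),
            geo.bronchus_radius_mm,
            z_range=(-0.4 * ext[2] / 2, 0.4 * ext[2] / 2),
        )
        & body
    )
    heart_r = geo.heart_radius_fraction * body_radius * rng.uniform(0.9, 1.1)
    heart_c = (-0.15 * lung_c[0], 0.22 * body_radius, -0.1 * ext[2] / 2)
    heart = _ellipsoid(coords, heart_c, (heart_r, heart_r, 1.2 * heart_r)) & body
    serial_oars = spinal_cord | esophagus | bronchus | heart

    last_error = "no attempt made"
    for _ in range(geo.max_placement_attempts):
        r_ctv = rng.uniform(*geo.ctv_radius_range_mm)
        # mild anisotropy around the sampled equivalent radius
        ax = r_ctv * rng.uniform(0.85, 1.15, size=3)
        frac = rng.uniform(*geo.ctv_radial_fraction_range)
        theta = rng.uniform(0.0, 2.0 * np.pi)
        phi = np.arccos(rng.uniform(-0.6, 0.6))  # keep away from lung poles
        direction = np.array(
            [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
        )
        ctv_c = (
            lung_c[0] + frac * lung_semi[0] * direction[0],
            lung_c[1] + frac * lung_semi[1] * direction[1],
            lung_c[2] + frac * lung_semi[2] * direction[2],
        )
        ctv = _ellipsoid(coords, ctv_c, tuple(ax))
        if not ctv.any() or not (ctv & lung).sum() == ctv.sum():
            last_error = "CTV not fully inside lung"
            continue
        ptv = expand_margin(ctv, geo.ptv_margin_mm, grid)
        if (ptv & ~body).any():
            last_error = "PTV extends outside body"
            continue
        if (ptv & serial_oars).any():
            last_error = "PTV touches a serial organ at risk"
            continue
        try:
            rings = make_rings(
                ptv, grid, geo.ring_distances_cm, geo.ring_width_mm, body=body
            )
            d2cm = make_d2cm(
                ptv, grid, body=body, inner_cm=geo.d2cm_inner_cm,
                width_cm=geo.d2cm_width_cm,
            )
        except ValueError as exc:
            last_error = str(exc)
            continue
        if any(not m.any() for m in rings.values()):
            last_error = "an empty ring structure"
            continue
        break
    else:
        raise RuntimeError(
            f"no feasible CTV placement after {geo.max_placement_attempts} "
            f"attempts (last failure: {last_error})"
        )

    masks: dict[str, np.ndarray] = {
        "CTV": ctv,
        "PTV": ptv,
        "lung": lung,
        "chest_wall": chest_wall,
        "spinal_cord": spinal_cord,
        "heart": heart,
        "esophagus": esophagus,
        "bronchus": bronchus,
        "body": body,
        "D2cm": d2cm,
        **rings,
    }
    case = Case(
        grid=grid,
        masks=masks,
        seed=int(seed),
        meta={
            "ctv_radius_mm": float(r_ctv),
            "ctv_center_mm": [float(c) for c in ctv_c],
            "geometry": asdict(geo),
        },
    )
    validate_case(case)
    return case


def validate_case(case: Case) -> None:
    """Check the structural invariants every case must satisfy."""
    m = case.masks
    required = set(STATE_STRUCTURES) | {"CTV", "body", "D2cm"}
    missing = required - set(m)
    if missing:
        raise ValueError(f"case is missing structures: {sorted(missing)}")
    for name, mask in m.items():
        if mask.shape != case.grid.shape:
            raise ValueError(f"{name} mask shape {mask.shape} != grid {case.grid.shape}")
        if not mask.any():
            raise ValueError(f"structure {name!r} is empty")
    if (m["CTV"] & ~m["PTV"]).any():
        raise ValueError("PTV does not contain CTV")
    body = m["body"]
    for name, mask in m.items():
        if name != "body" and (mask & ~body).any():
            raise ValueError(f"structure {name!r} extends outside body")
    ptv = m["PTV"]
    for rk in RING_NAMES:
        if (m[rk] & ptv).any():
            raise ValueError(f"{rk} overlaps the PTV")
    for i, ra in enumerate(RING_NAMES):
        for rb in RING_NAMES[i + 1:]:
            if (m[ra] & m[rb]).any():
                raise ValueError(f"rings {ra} and {rb} overlap")


# ---------------------------------------------------------------------------
# serialization


def save_case(case: Case, path: str | Path) -> Path:
    """Write the case as NPZ (one boolean array per structure) + JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        path,
        spacing_mm=np.asarray(case.grid.spacing_mm, dtype=float),
        **{f"mask_{k}": v for k, v in case.masks.items()},
    )
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({"seed": case.seed, "meta": case.meta}, indent=2))
    return path


def load_case(path: str | Path) -> Case:
    path = Path(path)
    with np.load(path) as data:
        spacing = tuple(float(s) for s in data["spacing_mm"])
        masks = {
            k[len("mask_"):]: data[k].astype(bool)
            for k in data.files
            if k.startswith("mask_")
        }
    shape = next(iter(masks.values())).shape
    sidecar = path.with_suffix(".json")
    seed, meta = -1, {}
    if sidecar.exists():
        info = json.loads(sidecar.read_text())
        seed, meta = info.get("seed", -1), info.get("meta", {})
    return Case(grid=GridSpec(shape, spacing), masks=masks, seed=seed, meta=meta)
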