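"""Surrogate beamlet dose engine.

A pencil-beam model standing in for a commercial optimizer's dose
calculation: equispaced coplanar 6 MV beams are decomposed into a grid of
beamlets, and each beamlet deposits

    dose(voxel) = exp(-mu * depth) * exp(-lateral^2 / (2 sigma^2))

where ``depth`` is the radiological path length along the beamlet's central
axis measured inside the body, and ``lateral`` is the distance of the voxel
from that axis.  The result is a sparse non-negative influence matrix
(body voxels x beamlets); dose is the linear map ``influence @ weights``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import sparse

from .phantom import Case, GridSpec

__all__ = [
    "BeamConfig",
    "KernelParams",
    "InfluenceMatrix",
    "build_influence",
    "compute_dose",
    "save_influence",
    "load_influence",
]


@dataclass(frozen=True)
class BeamConfig:
    """Coplanar equispaced beam arrangement (default: 9 fields, 40 deg apart)."""

    n_beams: int = 9
    angular_interval_deg: float = 40.0
    beamlet_size_mm: tuple[float, float] = (5.0, 5.0)
    energy_label: str = "6MV"

    def __post_init__(self) -> None:
        if self.n_beams < 1:
            raise ValueError("need at least one beam")
        if self.n_beams * self.angular_interval_deg > 360.0 + 1e-9:
            raise ValueError("beams would wrap past 360 degrees")
        if any(s <= 0 for s in self.beamlet_size_mm):
            raise ValueError("beamlet size must be positive")

    @property
    def angles_deg(self) -> np.ndarray:
        return np.arange(self.n_beams) * self.angular_interval_deg


@dataclass(frozen=True)
class KernelParams:
    """Pencil-beam kernel: linear attenuation mu (1/mm), lateral Gaussian
    sigma (mm), the lateral cutoff in sigmas, and the beamlet-selection
    margin around the PTV projection (mm)."""

    mu_per_mm: float = 0.005
    sigma_mm: float = 3.0
    lateral_cutoff_sigma: float = 3.0
    selection_margin_mm: float = 5.0
    ray_step_mm: float | None = None  # default: half the smallest voxel spacing


@dataclass
class InfluenceMatrix:
    """Sparse voxels-in-body x beamlets dose-deposition operator."""

    entries: sparse.csr_matrix
    voxel_index: np.ndarray  # flat indices into the case grid (body voxels)
    beamlet_angle_deg: np.ndarray
    beamlet_offset_u_mm: np.ndarray
    beamlet_offset_v_mm: np.ndarray
    grid_shape: tuple[int, int, int]

    @property
    def n_beamlets(self) -> int:
        return self.entries.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.entries.shape[0]


def _beam_frame(angle_deg: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Direction of propagation and the two lateral axes of a coplanar beam."""
    a = np.deg2rad(angle_deg)
    d = np.array([np.cos(a), np.sin(a), 0.0])
    u = np.array([-np.sin(a), np.cos(a), 0.0])
    v = np.array([0.0, 0.0, 1.0])
    return d, u, v


def _central_axis_depth(
    origin: np.ndarray,
    direction: np.ndarray,
    body: np.ndarray,
    grid: GridSpec,
    t_query: np.ndarray,
    step_mm: float,
) -> np.ndarray:
    """Path length inside the body along the ray up to each query parameter.

    Marches the central axis at ``step_mm`` resolution, accumulating the
    in-body path, then evaluates the cumulative depth at ``t_query``.
    """
    half_diag = 0.5 * float(np.linalg.norm(grid.extent_mm))
    t_grid = np.arange(-half_diag, half_diag + step_mm, step_mm)
    pts = origin[None, :] + t_grid[:, None] * direction[None, :]
    # nearest-voxel membership lookup
    idx = np.empty((t_grid.size, 3), dtype=np.int64)
    inside = np.ones(t_grid.size, dtype=bool)
    for ax in range(3):
        n, s = grid.shape[ax], grid.spacing_mm[ax]
        i = np.rint(pts[:, ax] / s + (n - 1) / 2.0).astype(np.int64)
        inside &= (i >= 0) & (i < n)
        idx[:, ax] = np.clip(i, 0, n - 1)
    in_body = inside & body[idx[:, 0], idx[:, 1], idx[:, 2]]
    depth_grid = np.concatenate(([0.0], np.cumsum(in_body.astype(float) * step_mm)))[:-1]
    return np.interp(t_query, t_grid, depth_grid)


def build_influence(
    case: Case,
    beams: BeamConfig | None = None,
    kernel: KernelParams | None = None,
) -> InfluenceMatrix:
    """Build the beamlet influence matrix for a case.

    Beamlets are laid out on a regular grid in the plane perpendicular to
    each beam, covering the PTV's projected extent plus the selection
    margin; the isocenter is the PTV centroid.  Deterministic.
    """
    beams = beams or BeamConfig()
    kernel = kernel or KernelParams()
    grid = case.grid
    body = case.mask("body")
    ptv = case.mask("PTV")
    step = kernel.ray_step_mm or 0.5 * min(grid.spacing_mm)

    cx, cy, cz = grid.coords_mm()
    vox_flat = np.flatnonzero(body.ravel())
    ii, jj, kk = np.unravel_index(vox_flat, grid.shape)
    coords = np.column_stack([cx[ii], cy[jj], cz[kk]])  # (n_body, 3), mm

    pi, pj, pk = np.nonzero(ptv)
    ptv_coords = np.column_stack([cx[pi], cy[pj], cz[pk]])
    iso = ptv_coords.mean(axis=0)
    ptv_rows = body.ravel()[np.ravel_multi_index((pi, pj, pk), grid.shape)]
    if not ptv_rows.all():
        raise ValueError("PTV must lie inside the body")

    cutoff = kernel.lateral_cutoff_sigma * kernel.sigma_mm
    bs_u, bs_v = beams.beamlet_size_mm
    margin = kernel.selection_margin_mm

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    b_ang: list[float] = []
    b_ou: list[float] = []
    b_ov: list[float] = []

    rel = coords - iso
    ptv_rel = ptv_coords - iso
    col = 0
    for angle in beams.angles_deg:
        d, u, v = _beam_frame(float(angle))
        pu = rel @ u
        pv = rel @ v
        pt = rel @ d
        ptv_u = ptv_rel @ u
        ptv_v = ptv_rel @ v
        offs_u = np.arange(
            np.floor((ptv_u.min() - margin) / bs_u),
            np.floor((ptv_u.max() + margin) / bs_u) + 1,
        ) * bs_u + bs_u / 2.0
        offs_v = np.arange(
            np.floor((ptv_v.min() - margin) / bs_v),
            np.floor((ptv_v.max() + margin) / bs_v) + 1,
        ) * bs_v + bs_v / 2.0
        for ou in offs_u:
            du2 = (pu - ou) ** 2
            for ov in offs_v:
                lat2 = du2 + (pv - ov) ** 2
                sel = np.flatnonzero(lat2 <= cutoff**2)
                if sel.size == 0:
                    continue
                origin = iso + ou * u + ov * v
                depth = _central_axis_depth(
                    origin, d, body, grid, pt[sel], step
                )
                dep = np.exp(-kernel.mu_per_mm * depth) * np.exp(
                    -lat2[sel] / (2.0 * kernel.sigma_mm**2)
                )
                rows.append(sel)
                cols.append(np.full(sel.size, col, dtype=np.int64))
                vals.append(dep)
                b_ang.append(float(angle))
                b_ou.append(float(ou))
                b_ov.append(float(ov))
                col += 1

    if col == 0:
        raise ValueError("no beamlet ray intersects the PTV region")

    entries = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(vox_flat.size, col),
    )
    infl = InfluenceMatrix(
        entries=entries,
        voxel_index=vox_flat,
        beamlet_angle_deg=np.asarray(b_ang),
        beamlet_offset_u_mm=np.asarray(b_ou),
        beamlet_offset_v_mm=np.asarray(b_ov),
        grid_shape=grid.shape,
    )
    # every PTV voxel must see at least one beamlet
    body_pos = np.full(np.prod(grid.shape), -1, dtype=np.int64)
    body_pos[vox_flat] = np.arange(vox_flat.size)
    ptv_row_idx = body_pos[np.flatnonzero(ptv.ravel())]
    row_hits = np.diff(entries.indptr)[ptv_row_idx]
    if (row_hits == 0).any():
        raise ValueError("some PTV voxels receive no beamlet influence")
    return infl


def compute_dose(influence: InfluenceMatrix, weights: np.ndarray) -> np.ndarray:
    """Map beamlet weights to a 3D dose grid (Gy).  Linear and non-negative."""
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (influence.n_beamlets,):
        raise ValueError(
            f"expected {influence.n_beamlets} weights, got shape {weights.shape}"
        )
    if (weights < 0).any():
        raise ValueError("beamlet weights must be non-negative")
    dose = np.zeros(int(np.prod(influence.grid_shape)))
    dose[influence.voxel_index] = influence.entries @ weights
    return dose.reshape(influence.grid_shape)


def save_influence(influence: InfluenceMatrix, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    coo = influence.entries.tocoo()
    np.savez_compressed(
        path,
        row=coo.row,
        col=coo.col,
        val=coo.data,
        shape=np.asarray(coo.shape),
        voxel_index=influence.voxel_index,
        beamlet_angle_deg=influence.beamlet_angle_deg,
        beamlet_offset_u_mm=influence.beamlet_offset_u_mm,
        beamlet_offset_v_mm=influence.beamlet_offset_v_mm,
        grid_shape=np.asarray(influence.grid_shape),
    )
    return path


def load_influence(path: str | Path) -> InfluenceMatrix:
    with np.load(Path(path)) as d:
        entries = sparse.csr_matrix(
            (d["val"], (d["row"], d["col"])), shape=tuple(d["shape"])
        )
        return InfluenceMatrix(
            entries=entries,
            voxel_index=d["voxel_index"],
            beamlet_angle_deg=d["beamlet_angle_deg"],
            beamlet_offset_u_mm=d["beamlet_offset_u_mm"],
            beamlet_offset_v_mm=d["beamlet_offset_v_mm"],
            grid_shape=tuple(int(n) for n in d["grid_shape"]),
        )
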