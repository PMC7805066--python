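"""Toy beamlet dose-influence engine for coplanar photon IMRT.

Produces the sparse dose-influence matrix mapping beamlet weights to
per-fraction voxel dose that both optimisers consume.  The kernel is
photon-physics-inspired but deliberately simple and NOT clinically
validated: water-equivalent geometry, a linear build-up ramp followed by
exponential depth attenuation, and a Gaussian lateral penumbra about each
divergent ray, normalised so a unit-weight beamlet delivers 1 Gy at the
isocentre-plane depth on its central axis.  Any positive linear operator
exercises the optimisation objectives; the physics constants are
configuration with stated defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse

from .grids import StructureSet, VoxelGrid

__all__ = [
    "BeamGeometry",
    "EngineParams",
    "DoseInfluence",
    "FluencePlan",
    "build_influence",
    "compute_dose",
]

#: default 7-field coplanar gantry arrangement (degrees)
DEFAULT_GANTRY_ANGLES = (0.0, 40.0, 80.0, 110.0, 250.0, 280.0, 310.0)


@dataclass(frozen=True)
class BeamGeometry:
    """Coplanar beam arrangement rotating about the SI (z) axis.

    Gantry 0 deg enters from the anterior; the beamlet grid lives in the
    beam's-eye view at the isocentre plane with the given width (mm).
    """

    gantry_angles_deg: tuple[float, ...] = DEFAULT_GANTRY_ANGLES
    beamlet_width_mm: float = 2.5
    sad_mm: float = 1000.0
    isocenter_mm: tuple[float, float, float] | None = None  # default: CTV centroid

    def __post_init__(self) -> None:
        if len(self.gantry_angles_deg) < 1:
            raise ValueError("need at least one beam")
        if self.beamlet_width_mm <= 0 or self.sad_mm <= 0:
            raise ValueError("beamlet width and SAD must be positive")


@dataclass(frozen=True)
class EngineParams:
    """Toy kernel parameters (documented defaults, all configurable)."""

    mu_per_mm: float = 0.005          # effective attenuation coefficient
    buildup_mm: float = 15.0          # linear build-up ramp depth
    penumbra_sd_mm: float = 3.0       # lateral Gaussian penumbra SD
    cutoff_rel: float = 1e-4          # drop entries below this fraction of column max
    bev_margin_mm: float = 10.0       # beamlet grid margin around the target
    depth_step_mm: float = 1.0        # ray-marching step for depth


@dataclass
class DoseInfluence:
    """Sparse beamlet->voxel per-fraction dose operator.

    ``matrix`` has shape (n_voxels, n_beamlets); ``beamlets`` records
    (beam index, u, v) of each column (BEV coordinates in mm at the
    isocentre plane).
    """

    grid: VoxelGrid
    geometry: BeamGeometry
    params: EngineParams
    matrix: sparse.csr_matrix
    beamlets: np.ndarray  # structured: beam, u_mm, v_mm
    isocenter: np.ndarray

    @property
    def n_beamlets(self) -> int:
        return self.matrix.shape[1]

    def dose_per_fraction(self, weights: np.ndarray) -> np.ndarray:
        w = np.asarray(weights, dtype=float).ravel()
        if w.shape[0] != self.n_beamlets:
            raise ValueError(
                f"weight vector length {w.shape[0]} != {self.n_beamlets} beamlets"
            )
        if np.any(w < 0):
            raise ValueError("beamlet weights must be non-negative")
        return np.asarray(self.matrix @ w).reshape(self.grid.shape)

    def adjoint(self, voxel_values: np.ndarray) -> np.ndarray:
        """A^T y — gradient backprojection from voxel to beamlet space."""
        return np.asarray(self.matrix.T @ np.asarray(voxel_values, dtype=float).ravel())


@dataclass
class FluencePlan:
    """Optimised per-fraction beamlet weights plus the fraction count."""

    influence: DoseInfluence
    weights: np.ndarray
    n_fractions: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float).ravel()
        if np.any(w < 0):
            raise ValueError("beamlet weights must be non-negative")
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")
        self.weights = w

    def scaled(self, s: float) -> "FluencePlan":
        return FluencePlan(self.influence, self.weights * float(s), self.n_fractions,
                           dict(self.meta, scale_factor=float(s)))


def compute_dose(plan: FluencePlan) -> tuple[np.ndarray, np.ndarray]:
    """Per-fraction dose map ``d`` and total dose map ``D = n d``."""
    d = plan.influence.dose_per_fraction(plan.weights)
    return d, plan.n_fractions * d


def _beam_frame(angle_deg: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unit vectors (e_b beam direction, e_u in-plane lateral, e_v = z)."""
    th = np.deg2rad(angle_deg)
    e_b = np.array([np.sin(th), np.cos(th), 0.0])
    e_u = np.array([np.cos(th), -np.sin(th), 0.0])
    e_v = np.array([0.0, 0.0, 1.0])
    return e_b, e_u, e_v


def _march_depth(
    points: np.ndarray, e_b: np.ndarray, external: np.ndarray, grid: VoxelGrid,
    step: float,
) -> np.ndarray:
    """Water-equivalent depth of each point: external path length upstream."""
    # longest possible chord through the box plus margin
    max_len = float(np.linalg.norm(np.asarray(grid.extent))) + 4 * step
    n_steps = int(np.ceil(max_len / step))
    ks = (np.arange(n_steps) + 0.5) * step
    depth = np.zeros(points.shape[0])
    ext = external.astype(np.uint8)
    # chunk over steps to bound memory
    chunk = 32
    for s0 in range(0, n_steps, chunk):
        kk = ks[s0 : s0 + chunk]
        sample = points[None, :, :] - kk[:, None, None] * e_b[None, None, :]
        idx = grid.world_to_index(sample.reshape(-1, 3)).T
        inside = ndimage.map_coordinates(ext, idx, order=0, mode="constant", cval=0)
        depth += step * inside.reshape(len(kk), -1).sum(axis=0)
    return depth


def _profile(depth: np.ndarray, params: EngineParams) -> np.ndarray:
    """Depth-dose: linear build-up ramp times exponential attenuation."""
    depth = np.asarray(depth, dtype=float)
    ramp = np.clip(depth / params.buildup_mm, 0.0, 1.0)
    return ramp * np.exp(-params.mu_per_mm * depth)


def build_influence(
    grid: VoxelGrid,
    structures: StructureSet,
    geometry: BeamGeometry = BeamGeometry(),
    params: EngineParams = EngineParams(),
    target_name: str | None = None,
) -> DoseInfluence:
    """Build the sparse per-fraction dose-influence matrix.

    The beamlet grid of each beam covers the target structure (PTV when
    present, else CTV) plus a penumbra margin in the beam's-eye view;
    beamlets that deposit no dose in the target are culled.  Matrix
    entries below ``cutoff_rel`` of each column's maximum are dropped.
    """
    external = structures["external"]
    if not external.any():
        raise ValueError("external mask is empty")
    if target_name is None:
        target_name = "ptv" if "ptv" in structures else "ctv"
    target = structures[target_name]
    if geometry.isocenter_mm is not None:
        iso = np.asarray(geometry.isocenter_mm, dtype=float)
    else:
        iso = grid.voxel_centers(structures["ctv"]).mean(axis=0)
    ext_lin = np.flatnonzero(external.ravel())
    ext_pts = grid.voxel_centers(external)
    target_flat = target.ravel()[ext_lin]

    sad = geometry.sad_mm
    w_b = geometry.beamlet_width_mm
    pen = params.penumbra_sd_mm
    lateral_cut = 5.0 * pen

    data_parts, row_parts, indptr = [], [], [0]
    beamlet_info = []
    for bi, ang in enumerate(geometry.gantry_angles_deg):
        e_b, e_u, e_v = _beam_frame(ang)
        src = iso - sad * e_b
        rel = ext_pts - src
        s_ax = rel @ e_b
        if np.any(s_ax <= 0):
            raise ValueError("source inside the computation box; increase SAD")
        mag = s_ax / sad
        pu = (rel @ e_u) / mag  # BEV u at the isocentre plane
        pv = (rel @ e_v) / mag
        depth = _march_depth(ext_pts, e_b, external, grid, params.depth_step_mm)
        prof = _profile(depth, params)

        # beamlet grid: symmetric about the target's BEV midpoint
        tgt_pts = grid.voxel_centers(target)
        rel_t = tgt_pts - src
        mag_t = (rel_t @ e_b) / sad
        tu = (rel_t @ e_u) / mag_t
        tv = (rel_t @ e_v) / mag_t
        centers = []
        for lo, hi in ((tu.min(), tu.max()), (tv.min(), tv.max())):
            mid = 0.5 * (lo + hi)
            n_half = int(np.ceil((0.5 * (hi - lo) + params.bev_margin_mm) / w_b))
            centers.append(mid + w_b * np.arange(-n_half, n_half + 1))
        u_centers, v_centers = centers

        # depth at the isocentre plane on each beamlet's central axis
        uu, vv = np.meshgrid(u_centers, v_centers, indexing="ij")
        bl_pts = iso[None, :] + uu.ravel()[:, None] * e_u + vv.ravel()[:, None] * e_v
        bl_depth = _march_depth(bl_pts, e_b, external, grid, params.depth_step_mm)
        bl_prof = _profile(bl_depth, params)

        for k, (u, v) in enumerate(zip(uu.ravel(), vv.ravel())):
            if bl_prof[k] <= 1e-6:  # ray effectively misses the body
                continue
            du = (pu - u) * mag
            m1 = np.abs(du) < lateral_cut
            dv = (pv[m1] - v) * mag[m1]
            m2 = np.abs(dv) < lateral_cut
            sel = np.flatnonzero(m1)[m2]
            if sel.size == 0:
                continue
            r2 = du[sel] ** 2 + dv[m2] ** 2
            vals = (prof[sel] / bl_prof[k]) * np.exp(-0.5 * r2 / pen**2)
            keep = vals >= params.cutoff_rel * vals.max()
            sel, vals = sel[keep], vals[keep]
            if not np.any(target_flat[sel] & (vals > 0)):
                continue  # beamlet does not hit the target
            data_parts.append(vals)
            row_parts.append(ext_lin[sel])
            indptr.append(indptr[-1] + sel.size)
            beamlet_info.append((bi, float(u), float(v)))

    if not beamlet_info:
        raise ValueError("no beamlet reaches the target; check geometry")
    data = np.concatenate(data_parts)
    rows = np.concatenate(row_parts)
    mat = sparse.csc_matrix(
        (data, rows, np.asarray(indptr)), shape=(grid.n_voxels, len(beamlet_info))
    ).tocsr()
    beamlets = np.array(
        beamlet_info, dtype=[("beam", int), ("u_mm", float), ("v_mm", float)]
    )
    return DoseInfluence(
        grid=grid, geometry=geometry, params=params, matrix=mat,
        beamlets=beamlets, isocenter=iso,
    )
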