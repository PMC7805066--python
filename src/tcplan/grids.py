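"""Regular 3D voxel lattices and named structure masks.

Axis convention used throughout the package: ``x`` = left-right (LR),
``y`` = anterior-posterior (AP, +y posterior), ``z`` = inferior-superior
(SI).  All physical quantities are in millimetres and Gray.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelGrid", "StructureSet", "GridMismatchError"]

#: grid axis order (x, y, z) expressed as anatomical axis labels
GRID_AXIS_LABELS = ("lr", "ap", "si")


class GridMismatchError(ValueError):
    """Raised when two voxel fields do not live on congruent grids."""


@dataclass(frozen=True)
class VoxelGrid:
    """A regular 3D lattice of voxel centres.

    Parameters
    ----------
    shape
        Number of voxels along (x, y, z).
    spacing
        Voxel pitch in mm along (x, y, z).  The default 2 x 2 x 2.5 mm
        matches the planning resolution used for prostate voxel maps.
    origin
        World coordinate (mm) of the centre of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.5)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) <= 0 for n in self.shape):
            raise ValueError(f"grid shape must be three positive integers, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"grid spacing must be positive, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3 (10 mm^3 at the default spacing)."""
        return float(np.prod(self.spacing))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical size of the lattice (mm) from first to last voxel centre."""
        return tuple((n - 1) * s for n, s in zip(self.shape, self.spacing))

    @property
    def center(self) -> np.ndarray:
        """World coordinate of the lattice centre (mm)."""
        return np.asarray(self.origin) + 0.5 * np.asarray(self.extent)

    def coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Meshgrid (ij-indexed) of voxel-centre world coordinates."""
        axes = [
            self.origin[k] + self.spacing[k] * np.arange(self.shape[k])
            for k in range(3)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij"))

    def voxel_centers(self, mask: np.ndarray | None = None) -> np.ndarray:
        """(N, 3) array of voxel-centre coordinates, optionally masked."""
        xx, yy, zz = self.coordinates()
        if mask is None:
            return np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)
        mask = np.asarray(mask, dtype=bool)
        self.check_congruent(mask)
        return np.stack([xx[mask], yy[mask], zz[mask]], axis=1)

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Convert world coordinates (mm) to fractional voxel indices."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    @property
    def affine(self) -> np.ndarray:
        """NIfTI-style affine mapping voxel indices to world mm."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def check_congruent(self, array: np.ndarray) -> None:
        if tuple(array.shape) != self.shape:
            raise GridMismatchError(
                f"array shape {array.shape} does not match grid shape {self.shape}"
            )


# names every structure set must carry; PTV is optional
REQUIRED_STRUCTURES = ("ctv", "rectum", "bladder", "hof_left", "hof_right", "external")


@dataclass
class StructureSet:
    """Named boolean organ masks on a common :class:`VoxelGrid`.

    Invariants enforced on construction: every non-external mask is
    contained in the external (body) mask, the CTV is non-empty, and all
    masks are congruent with the grid.
    """

    grid: VoxelGrid
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [n for n in REQUIRED_STRUCTURES if n not in self.masks]
        if missing:
            raise ValueError(f"structure set missing required masks: {missing}")
        for name, mask in self.masks.items():
            mask = np.asarray(mask, dtype=bool)
            self.grid.check_congruent(mask)
            self.masks[name] = mask
        external = self.masks["external"]
        for name, mask in self.masks.items():
            if name == "external":
                continue
            if np.any(mask & ~external):
                n_out = int(np.sum(mask & ~external))
                raise ValueError(
                    f"structure '{name}' has {n_out} voxel(s) outside the external contour"
                )
        if not self.masks["ctv"].any():
            raise ValueError("CTV mask is empty")

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.masks[name]
        except KeyError:
            raise KeyError(f"unknown structure '{name}'; have {sorted(self.masks)}") from None

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    @property
    def names(self) -> list[str]:
        return sorted(self.masks)

    def volume_cc(self, name: str) -> float:
        """Structure volume in cm^3."""
        return float(self[name].sum()) * self.grid.voxel_volume / 1000.0

    def with_mask(self, name: str, mask: np.ndarray) -> "StructureSet":
        """Return a new set with ``name`` added/replaced (re-validated)."""
        masks = dict(self.masks)
        masks[name] = np.asarray(mask, dtype=bool)
        return StructureSet(self.grid, masks)
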