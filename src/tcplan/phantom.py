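"""Seeded synthetic pelvis phantoms emulating mpMRI-surrogate voxel maps.

Real planning data for this kind of study (registered tumour-probability
and cell-density prediction maps with ground-truth histology masks) are
not publicly deposited, so the study pipeline runs on synthetic patients:
simple solid organs on a 2 x 2 x 2.5 mm lattice, one or more ellipsoidal
focal lesions inside the prostate CTV, a probability map built from a
smoothed lesion indicator plus spatially correlated noise, and an areal
cell-density map elevated inside lesions.  Everything is deterministic in
``(config, seed)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .grids import StructureSet, VoxelGrid

__all__ = ["PhantomConfig", "SyntheticPatient", "generate_phantom", "generate_cohort"]


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and statistical parameters of the synthetic pelvis.

    Lengths in mm; densities in cells/mm^2.  Organ centres are offsets
    from the grid centre in grid (x=LR, y=AP(+posterior), z=SI(+superior))
    coordinates.  The default organ sizes give a ~15 cm^3 prostate CTV
    inside a body ellipsoid nearly filling the default 48 x 48 x 24 grid.
    """

    shape: tuple[int, int, int] = (48, 48, 24)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.5)
    # organ geometry (semi-axes / radii and centre offsets, mm)
    external_radii: tuple[float, float, float] = (45.0, 45.0, 28.5)
    ctv_radii: tuple[float, float, float] = (18.0, 16.0, 13.0)
    rectum_radius: float = 6.5
    rectum_offset_y: float = 28.0
    rectum_half_length: float = 16.0
    bladder_radii: tuple[float, float, float] = (13.0, 10.0, 8.0)
    bladder_offset: tuple[float, float, float] = (0.0, -24.0, 12.0)
    hof_radius: float = 7.5
    hof_offset_x: float = 34.0
    # lesions
    n_lesions: int = 2
    lesion_radius_range: tuple[float, float] = (5.0, 9.0)
    lesion_size_mult: float = 1.0
    explicit_lesions: tuple[tuple[tuple[float, float, float], tuple[float, float, float]], ...] | None = None
    # probability map
    prob_baseline: float = 0.10
    prob_amplitude: float = 0.75
    prob_smooth_mm: float = 3.0
    prob_noise_sd: float = 0.12
    # areal density map (cells/mm^2)
    density_background: float = 150.0
    density_lesion: float = 250.0
    density_noise_sd: float = 40.0
    noise_corr_mm: float = 6.0

    def __post_init__(self) -> None:
        if any(int(n) <= 0 for n in self.shape) or any(s <= 0 for s in self.spacing):
            raise ValueError("phantom grid shape and spacing must be positive")
        if self.n_lesions < 0:
            raise ValueError("n_lesions must be >= 0")
        if self.lesion_radius_range[0] <= 0 or self.lesion_radius_range[1] < self.lesion_radius_range[0]:
            raise ValueError("invalid lesion radius range")
        if self.density_background < 0 or self.density_lesion < 0:
            raise ValueError("densities must be non-negative")

    @property
    def grid(self) -> VoxelGrid:
        return VoxelGrid(shape=self.shape, spacing=self.spacing)


@dataclass(frozen=True)
class SyntheticPatient:
    """One synthetic patient: geometry, surrogate maps and ground truth."""

    grid: VoxelGrid
    structures: StructureSet
    probability_map: np.ndarray
    density_area_map: np.ndarray
    truth_tumour_mask: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        for name in ("probability_map", "density_area_map"):
            self.grid.check_congruent(getattr(self, name))
        self.grid.check_congruent(self.truth_tumour_mask)
        if np.any(self.probability_map < 0) or np.any(self.probability_map > 1):
            raise ValueError("probability map must lie in [0, 1]")
        if np.any(self.density_area_map < 0):
            raise ValueError("areal density map must be non-negative")
        if np.any(np.asarray(self.truth_tumour_mask) & ~self.structures["ctv"]):
            raise ValueError("truth tumour mask extends outside the CTV")


def _ellipsoid_mask(grid: VoxelGrid, center: np.ndarray, radii: np.ndarray) -> np.ndarray:
    xx, yy, zz = grid.coordinates()
    return (
        ((xx - center[0]) / radii[0]) ** 2
        + ((yy - center[1]) / radii[1]) ** 2
        + ((zz - center[2]) / radii[2]) ** 2
    ) <= 1.0


def _build_structures(config: PhantomConfig) -> StructureSet:
    grid = config.grid
    c = grid.center
    external = _ellipsoid_mask(grid, c, np.asarray(config.external_radii))
    ctv = _ellipsoid_mask(grid, c, np.asarray(config.ctv_radii))
    xx, yy, zz = grid.coordinates()
    rectum = (
        ((xx - c[0]) ** 2 + (yy - (c[1] + config.rectum_offset_y)) ** 2)
        <= config.rectum_radius**2
    ) & (np.abs(zz - c[2]) <= config.rectum_half_length)
    bladder = _ellipsoid_mask(
        grid, c + np.asarray(config.bladder_offset), np.asarray(config.bladder_radii)
    )
    hof_l = _ellipsoid_mask(
        grid, c + np.array([-config.hof_offset_x, 0.0, 0.0]), np.full(3, config.hof_radius)
    )
    hof_r = _ellipsoid_mask(
        grid, c + np.array([config.hof_offset_x, 0.0, 0.0]), np.full(3, config.hof_radius)
    )
    masks = {
        "ctv": ctv,
        "rectum": rectum,
        "bladder": bladder,
        "hof_left": hof_l,
        "hof_right": hof_r,
        "external": external,
    }
    for name, mask in masks.items():
        if name in ("ctv", "external"):
            continue
        if np.any(mask & ctv):
            raise ValueError(
                f"organ specification invalid: '{name}' overlaps the CTV; "
                "adjust offsets/radii"
            )
    # StructureSet validation rejects masks escaping the external contour
    return StructureSet(grid, masks)


def _correlated_noise(
    rng: np.random.Generator, grid: VoxelGrid, sd: float, corr_mm: float
) -> np.ndarray:
    """Gaussian random field: Gaussian-filtered white noise, rescaled to sd."""
    if sd == 0:
        return np.zeros(grid.shape)
    white = rng.standard_normal(grid.shape)
    sigma_vox = np.asarray(corr_mm) / np.asarray(grid.spacing)
    smooth = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="reflect")
    s = smooth.std()
    return smooth * (sd / s) if s > 0 else np.zeros(grid.shape)


def _sample_lesions(
    rng: np.random.Generator, config: PhantomConfig, grid: VoxelGrid
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Lesion (centre, semi-axes) pairs, centres sampled inside the CTV."""
    if config.explicit_lesions is not None:
        out = []
        for center_frac, radii in config.explicit_lesions:
            center = grid.center + np.asarray(center_frac) * np.asarray(config.ctv_radii)
            out.append((center, np.asarray(radii, dtype=float)))
        return out
    lesions = []
    lo, hi = config.lesion_radius_range
    ctv_r = np.asarray(config.ctv_radii)
    for _ in range(config.n_lesions):
        radii = rng.uniform(lo, hi, size=3) * config.lesion_size_mult
        # keep the lesion centre deep enough that most of it stays in the CTV
        room = np.clip(1.0 - 0.7 * radii / ctv_r, 0.05, 1.0)
        while True:
            u = rng.uniform(-1.0, 1.0, size=3)
            if np.sum(u**2) <= 1.0:
                break
        center = grid.center + u * room * ctv_r
        lesions.append((center, radii))
    return lesions


def generate_phantom(config: PhantomConfig, seed: int) -> SyntheticPatient:
    """Generate one synthetic patient, bit-identical for equal (config, seed)."""
    grid = config.grid
    structures = _build_structures(config)
    ctv = structures["ctv"]
    rng = np.random.default_rng(int(seed))

    lesions = _sample_lesions(rng, config, grid)
    lesion_mask = np.zeros(grid.shape, dtype=bool)
    for center, radii in lesions:
        lesion_mask |= _ellipsoid_mask(grid, center, radii)
    truth = lesion_mask & ctv

    sigma_vox = np.asarray(config.prob_smooth_mm) / np.asarray(grid.spacing)
    smooth_ind = ndimage.gaussian_filter(lesion_mask.astype(float), sigma=sigma_vox)
    prob_noise = _correlated_noise(rng, grid, config.prob_noise_sd, config.noise_corr_mm)
    probability = np.clip(
        config.prob_baseline + config.prob_amplitude * smooth_ind + prob_noise, 0.0, 1.0
    )

    dens_noise = _correlated_noise(rng, grid, config.density_noise_sd, config.noise_corr_mm)
    density = np.clip(
        config.density_background
        + config.density_lesion * smooth_ind
        + dens_noise,
        0.0,
        None,
    )
    density[~structures["external"]] = 0.0

    return SyntheticPatient(
        grid=grid,
        structures=structures,
        probability_map=probability,
        density_area_map=density,
        truth_tumour_mask=truth,
        seed=int(seed),
    )


def generate_cohort(
    n_patients: int, config: PhantomConfig, master_seed: int
) -> list[SyntheticPatient]:
    """Deterministic cohort with lesion burden spanning >= 1 order of magnitude.

    Per-patient seeds derive from ``master_seed`` via a seed sequence;
    lesion counts cycle 1-3 and lesion size multipliers are geometrically
    spaced so total-cell counts across the cohort spread by more than a
    factor of ten, mirroring the variability of real high-risk cohorts.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    seeds = np.random.SeedSequence(int(master_seed)).generate_state(n_patients)
    if n_patients == 1:
        size_mults = np.array([1.0])
    else:
        size_mults = np.geomspace(0.6, 2.1, n_patients)
    patients = []
    for i in range(n_patients):
        cfg_i = replace(
            config,
            lesion_size_mult=float(config.lesion_size_mult * size_mults[i]),
            n_lesions=(config.n_lesions + i) % 3 + 1 if config.n_lesions > 0 else 0,
        )
        patients.append(generate_phantom(cfg_i, int(seeds[i] % (2**31))))
    return patients
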