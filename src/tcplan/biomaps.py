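"""From imaging-surrogate voxel maps to scaled clonogen distribution maps.

Inputs are a tumour-probability map (per-voxel probability of containing
tumour, in [0, 1]) and a cell-density-per-area map (cells/mm^2).  The
pipeline: convert areal to volumetric density (3/2-power), pick the
probability threshold maximising sensitivity + specificity against a
ground-truth tumour mask (ROC Youden point, scanned on a 0.01 grid),
binarise, multiply density by the binary prediction inside the CTV, and
linearly scale the whole cohort so the median total cell count equals a
target clonogen number (1e7 for high-risk prostate cancer).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import GridMismatchError, VoxelGrid

__all__ = [
    "ClonogenMap",
    "area_to_volumetric",
    "select_threshold",
    "build_cell_map",
    "scale_cohort",
    "resample_map",
    "cohort_median",
]


@dataclass(frozen=True)
class ClonogenMap:
    """Per-voxel clonogen density (cells/mm^3) with provenance.

    ``rho`` is zero outside the predicted-tumour-within-CTV support;
    ``total_cells`` integrates ``rho`` against the voxel volume.
    """

    grid: VoxelGrid
    rho: np.ndarray
    threshold: float
    scale_factor: float

    def __post_init__(self) -> None:
        rho = np.asarray(self.rho, dtype=float)
        self.grid.check_congruent(rho)
        if np.any(rho < 0) or not np.all(np.isfinite(rho)):
            raise ValueError("clonogen density must be finite and non-negative")
        object.__setattr__(self, "rho", rho)

    @property
    def total_cells(self) -> float:
        return float(self.rho.sum() * self.grid.voxel_volume)


def area_to_volumetric(density_area_map: np.ndarray) -> np.ndarray:
    """Areal cell density (cells/mm^2) to volumetric (cells/mm^3).

    Each voxel value ``v`` is raised to the power 3/2 (uniform density
    assumed across the slice thickness): 100 cells/mm^2 -> 1000 cells/mm^3.
    """
    arr = np.asarray(density_area_map, dtype=float)
    if np.any(arr < 0):
        raise ValueError("areal density must be non-negative")
    return arr**1.5


def select_threshold(
    probability_map: np.ndarray,
    truth_mask: np.ndarray,
    ctv_mask: np.ndarray,
    step: float = 0.01,
) -> float:
    """Probability threshold maximising sensitivity + specificity.

    Evaluated over CTV voxels only, scanning t in {0, step, ..., 1}
    incrementally; a voxel is called positive when its probability is
    >= t.  Ties are broken toward the smallest optimal threshold (the
    most sensitive of the optima).
    """
    prob = np.asarray(probability_map, dtype=float)
    ctv = np.asarray(ctv_mask, dtype=bool)
    truth = np.asarray(truth_mask, dtype=bool)
    if prob.shape != truth.shape or prob.shape != ctv.shape:
        raise GridMismatchError("probability, truth and CTV masks must share a grid")
    p = prob[ctv]
    t = truth[ctv]
    n_pos = int(t.sum())
    n_neg = t.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            "threshold selection needs both tumour and non-tumour voxels in the CTV"
        )
    n_steps = int(round(1.0 / step))
    thresholds = np.round(np.arange(n_steps + 1) * step, 10)
    best_t, best_j = 0.0, -np.inf
    for thr in thresholds:
        called = p >= thr
        sens = np.count_nonzero(called & t) / n_pos
        spec = np.count_nonzero(~called & ~t) / n_neg
        j = sens + spec
        if j > best_j + 1e-12:
            best_j, best_t = j, float(thr)
    return best_t


def build_cell_map(
    probability_map: np.ndarray,
    density_area_map: np.ndarray,
    truth_mask: np.ndarray,
    ctv_mask: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Unscaled cell distribution map (cells/mm^3) and the threshold used.

    Volumetric density x binary tumour prediction x CTV mask; zero
    everywhere outside the predicted tumour within the CTV.
    """
    prob = np.asarray(probability_map, dtype=float)
    dens = np.asarray(density_area_map, dtype=float)
    ctv = np.asarray(ctv_mask, dtype=bool)
    if prob.shape != dens.shape or prob.shape != ctv.shape:
        raise GridMismatchError("maps and masks must share a grid")
    thr = select_threshold(prob, truth_mask, ctv)
    binary = prob >= thr
    cell_map = area_to_volumetric(dens) * binary * ctv
    return cell_map, thr


def cohort_median(values: np.ndarray, even_rule: str = "lower") -> float:
    """Median with a configurable even-size rule.

    ``lower`` (default) returns the lower of the two middle order
    statistics for even cohorts; ``midmean`` averages them.  Odd cohorts
    are unaffected.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n == 0:
        raise ValueError("median of empty cohort")
    if n % 2 == 1:
        return float(v[n // 2])
    if even_rule == "lower":
        return float(v[n // 2 - 1])
    if even_rule == "midmean":
        return float(0.5 * (v[n // 2 - 1] + v[n // 2]))
    raise ValueError(f"unknown even-size median rule {even_rule!r}")


def scale_cohort(
    cell_maps: list[np.ndarray],
    grid: VoxelGrid,
    thresholds: list[float] | None = None,
    target_median: float = 1e7,
    even_rule: str = "lower",
) -> tuple[list[ClonogenMap], float]:
    """Linearly scale a cohort so its median total cell count hits a target.

    One global scalar ``s = target / median(totals)`` multiplies every map,
    preserving each patient's relative burden and the ordering of totals.
    """
    if not cell_maps:
        raise ValueError("need at least one cell map")
    totals = np.array([float(np.sum(m) * grid.voxel_volume) for m in cell_maps])
    if np.any(totals <= 0):
        raise ValueError(f"all cohort totals must be positive, got {totals}")
    s = target_median / cohort_median(totals, even_rule)
    if thresholds is None:
        thresholds = [float("nan")] * len(cell_maps)
    scaled = [
        ClonogenMap(grid=grid, rho=np.asarray(m, dtype=float) * s, threshold=t, scale_factor=s)
        for m, t in zip(cell_maps, thresholds)
    ]
    return scaled, float(s)


def resample_map(
    map_array: np.ndarray,
    source_spacing: tuple[float, float, float],
    target_spacing: tuple[float, float, float],
) -> np.ndarray:
    """Downsample an intensive map (probability, density) to a coarser grid.

    Integer downsampling factors use block averaging (exactly mass
    preserving for densities); non-integer factors fall back to linear
    interpolation of block-averaged data.  Upsampling is rejected.
    """
    src = np.asarray(source_spacing, dtype=float)
    tgt = np.asarray(target_spacing, dtype=float)
    if np.any(src <= 0) or np.any(tgt <= 0):
        raise ValueError("spacings must be positive")
    if np.any(tgt < src - 1e-9):
        raise ValueError("upsampling to a finer grid is not supported")
    arr = np.asarray(map_array, dtype=float)
    factors = tgt / src
    int_factors = np.round(factors).astype(int)
    if np.allclose(factors, int_factors, atol=1e-9):
        # block average; trim any remainder voxels at the high edge
        f = int_factors
        trimmed = arr[
            : (arr.shape[0] // f[0]) * f[0],
            : (arr.shape[1] // f[1]) * f[1],
            : (arr.shape[2] // f[2]) * f[2],
        ]
        if trimmed.shape != arr.shape:
            warnings.warn(
                "resample_map trimmed edge voxels not filling a whole block",
                stacklevel=2,
            )
        new_shape = (
            trimmed.shape[0] // f[0], f[0],
            trimmed.shape[1] // f[1], f[1],
            trimmed.shape[2] // f[2], f[2],
        )
        return trimmed.reshape(new_shape).mean(axis=(1, 3, 5))
    return ndimage.zoom(arr, 1.0 / factors, order=1, prefilter=False, grid_mode=True, mode="nearest")
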