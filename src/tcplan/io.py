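"""NIfTI / JSON artifact I/O for voxel maps, masks and cohort manifests."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .grids import StructureSet, VoxelGrid
from .phantom import SyntheticPatient

__all__ = [
    "save_map",
    "load_map",
    "save_patient",
    "load_patient",
    "save_cohort",
]


def save_map(array: np.ndarray, grid: VoxelGrid, path: str | Path) -> None:
    """Write a voxel map (or boolean mask) as a NIfTI volume."""
    grid.check_congruent(np.asarray(array))
    data = np.asarray(array)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    nib.save(nib.Nifti1Image(data.astype(np.float64) if data.dtype != np.uint8 else data,
                             grid.affine), str(path))


def load_map(path: str | Path) -> tuple[np.ndarray, VoxelGrid]:
    """Read a NIfTI volume back into (array, grid)."""
    img = nib.load(str(path))
    aff = img.affine
    spacing = tuple(float(aff[i, i]) for i in range(3))
    origin = tuple(float(aff[i, 3]) for i in range(3))
    data = np.asarray(img.dataobj)
    grid = VoxelGrid(shape=tuple(data.shape), spacing=spacing, origin=origin)
    return data, grid


def save_patient(patient: SyntheticPatient, out_dir: str | Path) -> dict:
    """Write one patient's maps and masks; returns the manifest entry."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    save_map(patient.probability_map, patient.grid, out / "probability.nii.gz")
    files["probability"] = "probability.nii.gz"
    save_map(patient.density_area_map, patient.grid, out / "density_area.nii.gz")
    files["density_area"] = "density_area.nii.gz"
    save_map(patient.truth_tumour_mask, patient.grid, out / "truth_tumour.nii.gz")
    files["truth_tumour"] = "truth_tumour.nii.gz"
    for name in patient.structures.names:
        fname = f"mask_{name}.nii.gz"
        save_map(patient.structures[name], patient.grid, out / fname)
        files[f"mask_{name}"] = fname
    return {"seed": patient.seed, "dir": str(out), "files": files}


def load_patient(manifest_entry: dict) -> SyntheticPatient:
    """Rebuild a patient from a manifest entry written by :func:`save_patient`."""
    base = Path(manifest_entry["dir"])
    files = manifest_entry["files"]
    prob, grid = load_map(base / files["probability"])
    dens, _ = load_map(base / files["density_area"])
    truth, _ = load_map(base / files["truth_tumour"])
    masks = {
        name.removeprefix("mask_"): load_map(base / fname)[0].astype(bool)
        for name, fname in files.items()
        if name.startswith("mask_")
    }
    return SyntheticPatient(
        grid=grid,
        structures=StructureSet(grid, masks),
        probability_map=prob,
        density_area_map=dens,
        truth_tumour_mask=truth.astype(bool),
        seed=int(manifest_entry["seed"]),
    )


def save_cohort(patients: list[SyntheticPatient], out_dir: str | Path) -> Path:
    """Write a cohort and its JSON manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        f"patient_{i + 1}": save_patient(p, out / f"patient_{i + 1}")
        for i, p in enumerate(patients)
    }
    path = out / "cohort_manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
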