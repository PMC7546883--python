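"""NIfTI volume I/O for masks and dose grids, plus structure-set manifests.

Volumes are written with a diagonal affine carrying the grid spacing and
origin; masks as 0/1 uint8, dose in Gy as float32.  Loading requires a
diagonal affine (no oblique orientations) so the voxel grid round-trips
exactly.
"""
from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .grid import StructureMask, StructureSet, VoxelGrid
from .planner import DoseGrid

__all__ = [
    "save_mask",
    "load_mask",
    "save_dose",
    "load_dose",
    "save_structure_set",
    "load_structure_set",
]


def _affine(grid: VoxelGrid) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(grid.spacing)
    aff[:3, 3] = grid.origin
    return aff


def _grid_from_affine(affine: np.ndarray, shape) -> VoxelGrid:
    rot = affine[:3, :3]
    if not np.allclose(rot, np.diag(np.diag(rot))):
        raise ValueError("only diagonal (axis-aligned) affines are supported")
    spacing = tuple(float(v) for v in np.diag(rot))
    if any(s <= 0 for s in spacing):
        raise ValueError(f"affine implies non-positive spacing {spacing}")
    return VoxelGrid(tuple(shape), spacing, tuple(float(v) for v in affine[:3, 3]))


def save_mask(mask: StructureMask, path) -> None:
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), _affine(mask.grid))
    nib.save(img, str(path))


def load_mask(path, name: str, role: str = "oar") -> StructureMask:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    grid = _grid_from_affine(img.affine, data.shape)
    return StructureMask(grid, data > 0, name, role)


def save_dose(dose: DoseGrid, path) -> None:
    img = nib.Nifti1Image(dose.dose.astype(np.float32), _affine(dose.grid))
    nib.save(img, str(path))


def load_dose(path) -> DoseGrid:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    grid = _grid_from_affine(img.affine, data.shape)
    return DoseGrid(grid, data)


def save_structure_set(struct_set: StructureSet, out_dir, seed: int | None = None,
                       roles: bool = True) -> Path:
    """Write one NIfTI per structure plus a JSON manifest; returns the
    manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for mask in struct_set:
        fname = f"{struct_set.subject_id}_{struct_set.source}_" \
                f"{mask.name.replace(' ', '_')}.nii.gz"
        save_mask(mask, out_dir / fname)
        entries.append({"name": mask.name, "role": mask.role, "file": fname,
                        "n_voxels": mask.count, "volume_mm3": mask.volume_mm3})
    manifest = {
        "subject_id": struct_set.subject_id,
        "source": struct_set.source,
        "grid": {"shape": list(struct_set.grid.shape),
                 "spacing_mm": list(struct_set.grid.spacing),
                 "origin_mm": list(struct_set.grid.origin)},
        "structures": entries,
    }
    if seed is not None:
        manifest["seed"] = seed
    mpath = out_dir / f"{struct_set.subject_id}_{struct_set.source}_manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return mpath


def load_structure_set(manifest_path) -> StructureSet:
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    structures = {}
    for entry in manifest["structures"]:
        mask = load_mask(manifest_path.parent / entry["file"], entry["name"],
                         entry["role"])
        structures[entry["name"]] = mask
    return StructureSet(manifest["subject_id"], manifest["source"], structures)
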