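"""Optional DICOM-RT import: RTDOSE grids and RTSTRUCT contour rasterisation.

RTDOSE pixel data are stored as scaled integers; the header's
``DoseGridScaling`` factor is applied on load.  Grid congruence with an
existing voxel grid is checked to nearest-neighbour tolerance only — a
mismatch is an error, never a silent resample.

RTSTRUCT contours are rasterised to a given grid by per-slice voxel-centre
point-in-polygon tests, matching the voxel-centre occupancy rule used by
the phantom rasterisers.
"""
from __future__ import annotations

import numpy as np
import pydicom
from matplotlib.path import Path as MplPath

from .errors import EmptyStructureError, IncompatibleGridsError
from .grid import StructureMask, VoxelGrid
from .planner import DoseGrid

__all__ = ["load_rtdose", "check_congruent", "rasterize_rtstruct_roi"]


def _read(ds_or_path) -> pydicom.Dataset:
    if isinstance(ds_or_path, pydicom.Dataset):
        return ds_or_path
    return pydicom.dcmread(str(ds_or_path))


def load_rtdose(ds_or_path) -> DoseGrid:
    """Load an RTDOSE dataset into a :class:`DoseGrid` in Gy.

    The pixel array (frames, rows, cols) is transposed to this package's
    (x, y, z) axis order; frame offsets must be uniformly spaced.
    """
    ds = _read(ds_or_path)
    if getattr(ds, "Modality", None) != "RTDOSE":
        raise ValueError(f"expected Modality RTDOSE, got {getattr(ds, 'Modality', None)!r}")
    scaling = float(ds.DoseGridScaling)
    dose = ds.pixel_array.astype(float) * scaling  # (z, y, x)
    dose = np.transpose(dose, (2, 1, 0))           # -> (x, y, z)
    row_spacing, col_spacing = (float(v) for v in ds.PixelSpacing)
    offsets = np.asarray([float(v) for v in ds.GridFrameOffsetVector])
    dz = np.diff(offsets)
    if len(dz) == 0:
        raise ValueError("RTDOSE must contain at least 2 frames")
    if not np.allclose(dz, dz[0]):
        raise ValueError("non-uniform GridFrameOffsetVector is not supported")
    origin = tuple(float(v) for v in ds.ImagePositionPatient)
    grid = VoxelGrid(dose.shape, (col_spacing, row_spacing, float(dz[0])), origin)
    return DoseGrid(grid, dose, meta={"dose_grid_scaling": scaling})


def check_congruent(grid_a: VoxelGrid, grid_b: VoxelGrid, tol_mm: float = 0.5) -> None:
    """Require two grids to agree in shape, spacing and origin to within
    ``tol_mm`` (nearest-neighbour congruence).  Mismatch raises — callers
    must resample explicitly if they want to."""
    if grid_a.shape != grid_b.shape:
        raise IncompatibleGridsError(
            f"grid shapes differ: {grid_a.shape} vs {grid_b.shape}")
    for name, a, b in (("spacing", grid_a.spacing, grid_b.spacing),
                       ("origin", grid_a.origin, grid_b.origin)):
        if np.max(np.abs(np.subtract(a, b))) > tol_mm:
            raise IncompatibleGridsError(
                f"grid {name} differs beyond {tol_mm} mm: {a} vs {b}")


def rasterize_rtstruct_roi(ds_or_path, roi_name: str, grid: VoxelGrid,
                           role: str = "oar") -> StructureMask:
    """Rasterise one RTSTRUCT ROI onto ``grid`` by voxel-centre
    point-in-polygon per axial slice.

    Contour points are matched to the nearest grid slice; a contour whose z
    lies more than half a slice spacing from every grid slice is an error.
    Multiple contours on one slice are OR-combined.
    """
    ds = _read(ds_or_path)
    roi_number = None
    for roi in ds.StructureSetROISequence:
        if roi.ROIName == roi_name:
            roi_number = roi.ROINumber
            break
    if roi_number is None:
        names = [r.ROIName for r in ds.StructureSetROISequence]
        raise ValueError(f"ROI {roi_name!r} not found (has: {names})")
    contour_seq = None
    for rc in ds.ROIContourSequence:
        if rc.ReferencedROINumber == roi_number:
            contour_seq = getattr(rc, "ContourSequence", [])
            break
    if not contour_seq:
        raise EmptyStructureError(f"ROI {roi_name!r} has no contour data")

    voxels = np.zeros(grid.shape, dtype=bool)
    zc = grid.axis_centers(2)
    x = grid.axis_centers(0)
    y = grid.axis_centers(1)
    xx, yy = np.meshgrid(x, y, indexing="ij")
    centers_xy = np.column_stack([xx.ravel(), yy.ravel()])
    for contour in contour_seq:
        pts = np.asarray([float(v) for v in contour.ContourData]).reshape(-1, 3)
        z = pts[:, 2].mean()
        k = int(np.argmin(np.abs(zc - z)))
        if abs(zc[k] - z) > grid.spacing[2] / 2.0:
            raise ValueError(
                f"contour at z={z:.2f} mm lies off the grid slices of "
                f"ROI {roi_name!r}")
        inside = MplPath(pts[:, :2]).contains_points(centers_xy)
        voxels[:, :, k] |= inside.reshape(len(x), len(y))
    if not voxels.any():
        raise EmptyStructureError(f"ROI {roi_name!r} rasterised to an empty mask")
    return StructureMask(grid, voxels, roi_name, role)
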