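"""Synthetic phantom cohorts: paired manual ("truth") and auto-segmented
structure sets with controllable geometric discrepancy.

Real paired MS/AS structure sets from clinical archives are not publicly
available, so the study runs on phantoms.  Each subject is built from shape
templates (spheres, ellipsoids, tubes) rasterised on a physically-spaced
voxel grid with per-subject jitter; the auto-segmented (AS) set is then a
per-structure perturbation of the manual (MS) set.  The perturbation kinds —
rigid translation, dilation/erosion, superior axial truncation, boundary
noise — span the error patterns reported for atlas-based segmentation:
offsets of small structures, systematic over/under-segmentation, and large
superior–inferior variation of elongated structures such as cord and
esophagus.

Occupancy follows the voxel-centre-in-shape rule: a voxel belongs to a
structure iff its centre lies inside the analytic shape.  This makes every
rasterisation exactly testable by counting centres.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import EmptyStructureError
from .grid import StructureMask, StructureSet, VoxelGrid, make_grid

__all__ = [
    "PerturbationSpec",
    "StructureTemplate",
    "CohortSpec",
    "make_grid",
    "rasterize_sphere",
    "rasterize_ellipsoid",
    "rasterize_tube",
    "perturb",
    "simulate_subject",
    "simulate_cohort",
]

PERTURBATION_KINDS = ("translate", "dilate", "erode", "truncate_axial", "surface_noise")

# 6-connectivity structuring element used for boundary extraction.
_CROSS = ndimage.generate_binary_structure(3, 1)


def _require_nonempty(voxels: np.ndarray, name: str, what: str) -> None:
    if not voxels.any():
        raise EmptyStructureError(f"{what} produced an empty structure for {name!r}")


def rasterize_sphere(grid: VoxelGrid, center, radius: float, name: str,
                     role: str = "oar") -> StructureMask:
    """Rasterise a sphere: a voxel is occupied iff its centre is within
    ``radius`` mm of ``center``."""
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    center = np.asarray(center, dtype=float)
    if not grid.contains_point(center):
        raise ValueError(f"sphere centre {center.tolist()} lies outside the grid extent")
    x, y, z = grid.coordinate_arrays()
    d2 = (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2
    voxels = d2 <= radius ** 2
    _require_nonempty(voxels, name, f"sphere r={radius} mm")
    return StructureMask(grid, voxels, name, role)


def rasterize_ellipsoid(grid: VoxelGrid, center, semi_axes, name: str,
                        role: str = "oar") -> StructureMask:
    """Axis-aligned ellipsoid with the same voxel-centre occupancy rule."""
    a = np.asarray(semi_axes, dtype=float)
    if a.shape != (3,) or np.any(a <= 0):
        raise ValueError(f"semi_axes must be 3 positive lengths, got {semi_axes}")
    center = np.asarray(center, dtype=float)
    if not grid.contains_point(center):
        raise ValueError(f"ellipsoid centre {center.tolist()} lies outside the grid extent")
    x, y, z = grid.coordinate_arrays()
    q = ((x - center[0]) / a[0]) ** 2 + ((y - center[1]) / a[1]) ** 2 + \
        ((z - center[2]) / a[2]) ** 2
    voxels = q <= 1.0
    _require_nonempty(voxels, name, f"ellipsoid {a.tolist()} mm")
    return StructureMask(grid, voxels, name, role)


def rasterize_tube(grid: VoxelGrid, axis, center, radius: float, length: float,
                   name: str, role: str = "oar") -> StructureMask:
    """Capsule (tube with hemispherical caps): occupied iff the voxel centre
    is within ``radius`` mm of the axis segment of ``length`` mm centred at
    ``center``.  A zero-length tube degenerates to a sphere."""
    if radius <= 0 or length < 0:
        raise ValueError(f"need radius > 0 and length >= 0, got r={radius}, L={length}")
    u = np.asarray(axis, dtype=float)
    nrm = np.linalg.norm(u)
    if nrm == 0:
        raise ValueError("tube axis must be a non-zero vector")
    u = u / nrm
    center = np.asarray(center, dtype=float)
    if not grid.contains_point(center):
        raise ValueError(f"tube centre {center.tolist()} lies outside the grid extent")
    x, y, z = grid.coordinate_arrays()
    dx, dy, dz = x - center[0], y - center[1], z - center[2]
    # Parameter along the axis, clipped to the segment; then squared distance
    # to the closest segment point.
    t = np.clip(dx * u[0] + dy * u[1] + dz * u[2], -length / 2.0, length / 2.0)
    d2 = (dx - t * u[0]) ** 2 + (dy - t * u[1]) ** 2 + (dz - t * u[2]) ** 2
    voxels = d2 <= radius ** 2
    _require_nonempty(voxels, name, f"tube r={radius} L={length} mm")
    return StructureMask(grid, voxels, name, role)


@dataclass(frozen=True)
class PerturbationSpec:
    """One geometric perturbation applied to a structure.

    ``magnitude`` is in mm for translate/dilate/erode (ball radius) and
    truncate_axial (length of the superior extent removed); for
    surface_noise it is the expected fraction of boundary voxels toggled,
    in [0, 1].  ``axis`` (unit vector) applies to translate only; ``seed``
    to surface_noise only.
    """

    kind: str
    magnitude: float
    axis: tuple[float, float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in PERTURBATION_KINDS:
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.magnitude < 0:
            raise ValueError(f"magnitude must be >= 0, got {self.magnitude}")
        if self.kind == "surface_noise" and self.magnitude > 1:
            raise ValueError(
                f"surface_noise magnitude is a fraction in [0, 1], got {self.magnitude}"
            )
        if self.axis is not None:
            a = np.asarray(self.axis, dtype=float)
            if abs(np.linalg.norm(a) - 1.0) > 1e-6:
                raise ValueError(f"axis must have unit norm, got {self.axis}")
            object.__setattr__(self, "axis", tuple(float(v) for v in a))
        elif self.kind == "translate" and self.magnitude > 0:
            raise ValueError("translate requires an axis")


def _ball_footprint(spacing, radius_mm: float) -> np.ndarray:
    """Structuring element of all integer offsets within radius_mm (physical)."""
    r = [int(np.floor(radius_mm / s)) for s in spacing]
    oi = np.arange(-r[0], r[0] + 1)[:, None, None] * spacing[0]
    oj = np.arange(-r[1], r[1] + 1)[None, :, None] * spacing[1]
    ok = np.arange(-r[2], r[2] + 1)[None, None, :] * spacing[2]
    return oi ** 2 + oj ** 2 + ok ** 2 <= radius_mm ** 2


def _shift_clip(voxels: np.ndarray, offset: tuple[int, int, int]) -> np.ndarray:
    """Integer-voxel shift; occupancy pushed past the boundary is dropped."""
    out = np.zeros_like(voxels)
    src = []
    dst = []
    for n, o in zip(voxels.shape, offset):
        if abs(o) >= n:
            return out
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    out[tuple(dst)] = voxels[tuple(src)]
    return out


def boundary_voxels(voxels: np.ndarray) -> np.ndarray:
    """Occupied voxels with at least one unoccupied 6-neighbour (the grid
    border counts as unoccupied)."""
    interior = ndimage.binary_erosion(voxels, structure=_CROSS, border_value=0)
    return voxels & ~interior


def perturb(mask: StructureMask, spec: PerturbationSpec) -> StructureMask:
    """Apply one perturbation, returning a new mask on the same grid.

    Deterministic given ``spec`` (including its seed).  Translation is
    rounded to whole-voxel offsets per axis so masks stay binary without
    resampling; the realised offset is therefore ``round(m*axis/spacing)``
    voxels.
    """
    spacing = mask.grid.spacing
    v = mask.voxels
    if spec.kind == "translate":
        if spec.magnitude == 0:
            return mask.with_voxels(v.copy())
        shift_mm = spec.magnitude * np.asarray(spec.axis)
        offset = tuple(int(np.rint(shift_mm[i] / spacing[i])) for i in range(3))
        return mask.with_voxels(_shift_clip(v, offset))
    if spec.kind in ("dilate", "erode"):
        foot = _ball_footprint(spacing, spec.magnitude)
        if spec.kind == "dilate":
            out = ndimage.binary_dilation(v, structure=foot)
        else:
            out = ndimage.binary_erosion(v, structure=foot, border_value=0)
            _require_nonempty(out, mask.name, f"erode {spec.magnitude} mm")
        return mask.with_voxels(out)
    if spec.kind == "truncate_axial":
        if spec.magnitude == 0:
            return mask.with_voxels(v.copy())
        z = mask.grid.axis_centers(2)
        occ_z = v.any(axis=(0, 1))
        z_max = z[occ_z].max()
        keep = z <= z_max - spec.magnitude  # drop the top `magnitude` mm of extent
        out = v & keep[None, None, :]
        _require_nonempty(out, mask.name, f"truncate_axial {spec.magnitude} mm")
        return mask.with_voxels(out)
    # surface_noise: toggle boundary voxels at an expected fraction `m`.
    m = spec.magnitude
    if m == 0:
        return mask.with_voxels(v.copy())
    rng = np.random.default_rng(spec.seed)
    inner = boundary_voxels(v)
    outer = ndimage.binary_dilation(v, structure=_CROSS) & ~v
    n_inner = int(inner.sum())
    n_outer = int(outer.sum())
    out = v.copy()
    # Half the expected toggles are removals of inner-boundary voxels, half
    # additions on the outer shell; expected toggle count is m * n_inner.
    remove = inner & (rng.random(v.shape) < m / 2.0)
    out &= ~remove
    if n_outer > 0:
        p_add = min(1.0, (m / 2.0) * n_inner / n_outer)
        add = outer & (rng.random(v.shape) < p_add)
        out |= add
    _require_nonempty(out, mask.name, f"surface_noise {m}")
    return mask.with_voxels(out)


@dataclass(frozen=True)
class StructureTemplate:
    """Blueprint for one phantom structure.

    ``size_mm`` is ``(radius,)`` for a sphere, ``(a, b, c)`` semi-axes for an
    ellipsoid, ``(radius, length)`` for a tube.  Placement is either an
    absolute ``center_mm`` or, relative to the anchor target, a unit
    ``direction`` plus ``gap_mm`` (nearest-surface gap between the anchor
    target and this structure along that direction).
    """

    name: str
    role: str
    shape: str  # sphere | ellipsoid | tube
    size_mm: tuple[float, ...]
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)  # tube only
    center_mm: tuple[float, float, float] | None = None
    direction: tuple[float, float, float] | None = None
    gap_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.shape not in ("sphere", "ellipsoid", "tube"):
            raise ValueError(f"unknown shape {self.shape!r}")
        expected = {"sphere": 1, "ellipsoid": 3, "tube": 2}[self.shape]
        if len(self.size_mm) != expected:
            raise ValueError(
                f"{self.shape} template {self.name!r} needs {expected} size parameters"
            )

    def support_mm(self, direction: np.ndarray) -> float:
        """Half-extent of the shape along a unit direction (support function)."""
        u = np.asarray(direction, dtype=float)
        if self.shape == "sphere":
            return float(self.size_mm[0])
        if self.shape == "ellipsoid":
            a = np.asarray(self.size_mm)
            return float(np.sqrt(np.sum((a * u) ** 2)))
        r, length = self.size_mm
        return float(abs(np.dot(u, np.asarray(self.axis))) * length / 2.0 + r)


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to generate a reproducible phantom cohort."""

    n_subjects: int
    grid: VoxelGrid
    templates: tuple[StructureTemplate, ...]
    perturbations: dict[str, PerturbationSpec] = field(default_factory=dict)
    seed: int = 0
    center_jitter_mm: float = 3.0
    size_jitter_frac: float = 0.05

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError(f"n_subjects must be >= 1, got {self.n_subjects}")
        object.__setattr__(self, "templates", tuple(self.templates))
        names = [t.name for t in self.templates]
        if len(set(names)) != len(names):
            raise ValueError("template names must be unique")
        unknown = set(self.perturbations) - set(names)
        if unknown:
            raise ValueError(
                f"perturbation keys name no template: {sorted(unknown)}"
            )

    @property
    def anchor(self) -> StructureTemplate:
        for t in self.templates:
            if t.role == "target":
                return t
        raise ValueError("cohort spec has no target template to anchor placement")


def _rasterize_template(grid: VoxelGrid, t: StructureTemplate, center, scale: float
                        ) -> StructureMask:
    size = tuple(s * scale for s in t.size_mm)
    if t.shape == "sphere":
        return rasterize_sphere(grid, center, size[0], t.name, t.role)
    if t.shape == "ellipsoid":
        return rasterize_ellipsoid(grid, center, size, t.name, t.role)
    return rasterize_tube(grid, t.axis, center, size[0], size[1], t.name, t.role)


def simulate_subject(spec: CohortSpec, subject_index: int
                     ) -> tuple[StructureSet, StructureSet]:
    """Generate one subject's paired (MS, AS) structure sets.

    Fully reproducible from ``(spec.seed, subject_index)``: the per-subject
    RNG is seeded with ``spec.seed + subject_index`` and consumed in template
    order.  The MS set carries the jittered template shapes; the AS set is
    the MS set with each configured perturbation applied.
    """
    if not 0 <= subject_index < spec.n_subjects:
        raise ValueError(
            f"subject_index {subject_index} out of range [0, {spec.n_subjects})"
        )
    rng = np.random.default_rng(spec.seed + subject_index)
    anchor = spec.anchor
    anchor_center = (np.asarray(anchor.center_mm, dtype=float)
                     if anchor.center_mm is not None else spec.grid.center_mm())

    ms_masks: dict[str, StructureMask] = {}
    centers: dict[str, np.ndarray] = {}
    scales: dict[str, float] = {}
    for t in spec.templates:
        jitter = rng.uniform(-spec.center_jitter_mm, spec.center_jitter_mm, size=3)
        scale = 1.0 + rng.uniform(-spec.size_jitter_frac, spec.size_jitter_frac)
        if t.center_mm is not None:
            center = np.asarray(t.center_mm, dtype=float) + jitter
        elif t.direction is not None:
            u = np.asarray(t.direction, dtype=float)
            u = u / np.linalg.norm(u)
            dist = anchor.support_mm(u) + t.gap_mm + t.support_mm(-u) * scale
            center = anchor_center + u * dist + jitter
        else:
            center = anchor_center + jitter
        try:
            ms_masks[t.name] = _rasterize_template(spec.grid, t, center, scale)
        except ValueError as e:
            raise type(e)(f"structure {t.name!r}: {e}") from e
        centers[t.name] = center
        scales[t.name] = scale

    as_masks: dict[str, StructureMask] = {}
    for i, t in enumerate(spec.templates):
        mask = ms_masks[t.name]
        pspec = spec.perturbations.get(t.name)
        if pspec is None:
            as_masks[t.name] = mask.with_voxels(mask.voxels.copy())
            continue
        if pspec.kind == "surface_noise":
            # Distinct, reproducible noise stream per (cohort, subject, structure).
            pspec = dataclasses.replace(
                pspec, seed=(spec.seed + 7919 * subject_index + 104729 * i) % (2 ** 31)
            )
        try:
            as_masks[t.name] = perturb(mask, pspec)
        except ValueError as e:
            raise type(e)(f"structure {t.name!r}: {e}") from e

    sid = f"subj{subject_index:03d}"
    return (StructureSet(sid, "MS", ms_masks), StructureSet(sid, "AS", as_masks))


def simulate_cohort(spec: CohortSpec) -> list[tuple[StructureSet, StructureSet]]:
    """Generate all ``spec.n_subjects`` paired structure sets."""
    return [simulate_subject(spec, i) for i in range(spec.n_subjects)]
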