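"""Parametric dose surrogate for contour-driven plan optimisation.

A clinical VMAT optimiser is a black box driven by institutional objectives;
what matters for this study is only that the dose distribution *depends on
the contours used to plan* and that its spatial gradient is controllable,
since the interplay of structure position with dose falloff is exactly what
decouples geometric from dosimetric agreement.  The surrogate is therefore a
closed-form prescription-conformal field:

    f_T(x) = Rx_T                      for x inside target T
    f_T(x) = Rx_T * 2^(−d(x,T)/h)      outside, d = distance to T in mm

with ``h`` the falloff half-distance (dose halves every ``h`` mm beyond the
target).  Multiple prescription levels (e.g. a 70/60/54 Gy simultaneously
integrated boost) combine by voxelwise maximum.  OAR sparing is a hard
in-mask multiplier ``(1 − w)`` applied outside all targets, so the plan's
dependence on each contour stays exactly interpretable.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import EmptyStructureError
from .grid import StructureSet, VoxelGrid

__all__ = [
    "DoseModelParams",
    "DoseGrid",
    "synthesize_dose",
    "plan_for",
    "prostate_params",
    "hn_sib_params",
]


@dataclass
class DoseGrid:
    """Per-voxel absorbed dose in Gy on a voxel grid."""

    grid: VoxelGrid
    dose: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        if self.dose.shape != self.grid.shape:
            raise ValueError(
                f"dose shape {self.dose.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.dose)) or np.any(self.dose < 0):
            raise ValueError("dose must be finite and non-negative everywhere")


@dataclass(frozen=True)
class DoseModelParams:
    """Tunable parameters of the dose surrogate.

    prescriptions : list of (target structure name, prescription dose Gy)
    falloff_half_distance_mm : distance outside a target at which its dose
        halves; small h = steep (SBRT-like) gradient, large h = shallow.
    oar_sparing : list of (structure name, sparing weight w in [0, 1));
        dose inside that structure (outside all targets) is scaled by 1 − w.
    background_floor_gy : minimum dose anywhere (scatter floor).
    """

    prescriptions: tuple[tuple[str, float], ...]
    falloff_half_distance_mm: float = 10.0
    oar_sparing: tuple[tuple[str, float], ...] = ()
    background_floor_gy: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "prescriptions", tuple(
            (str(n), float(rx)) for n, rx in self.prescriptions))
        object.__setattr__(self, "oar_sparing", tuple(
            (str(n), float(w)) for n, w in self.oar_sparing))
        if not self.prescriptions:
            raise ValueError("at least one prescription is required")
        if any(rx <= 0 for _, rx in self.prescriptions):
            raise ValueError("prescription doses must be > 0")
        if self.falloff_half_distance_mm <= 0:
            raise ValueError("falloff_half_distance_mm must be > 0")
        if any(not 0 <= w < 1 for _, w in self.oar_sparing):
            raise ValueError("sparing weights must be in [0, 1)")
        if self.background_floor_gy < 0:
            raise ValueError("background_floor_gy must be >= 0")


def prostate_params(rx_gy: float = 40.0, h_mm: float = 5.0,
                    oar_sparing: tuple[tuple[str, float], ...] = ()) -> DoseModelParams:
    """Single-target SBRT-style preset: 40 Gy with steep (h = 5 mm) falloff."""
    return DoseModelParams(prescriptions=(("CTV", rx_gy),),
                           falloff_half_distance_mm=h_mm, oar_sparing=oar_sparing)


def hn_sib_params(h_mm: float = 10.0,
                  oar_sparing: tuple[tuple[str, float], ...] = ()) -> DoseModelParams:
    """Simultaneously-integrated-boost preset: 70/60/54 Gy target levels with
    conventional (h = 10 mm) falloff."""
    return DoseModelParams(
        prescriptions=(("PTV70", 70.0), ("PTV60", 60.0), ("PTV54", 54.0)),
        falloff_half_distance_mm=h_mm, oar_sparing=oar_sparing)


def synthesize_dose(planning_set: StructureSet, params: DoseModelParams) -> DoseGrid:
    """Closed-form prescription-conformal dose for one structure set.

    Deterministic.  Distances are Euclidean from each voxel centre to the
    nearest occupied voxel centre of the target (exact distance transform
    with physical spacing), so dose is exactly Rx on the target plateau and
    halves every ``h`` mm outside it.
    """
    grid = planning_set.grid
    h = params.falloff_half_distance_mm
    dose = np.zeros(grid.shape, dtype=float)
    target_union = np.zeros(grid.shape, dtype=bool)
    for name, rx in params.prescriptions:
        if name not in planning_set:
            raise ValueError(f"prescription target {name!r} not in planning set")
        mask = planning_set[name]
        if mask.is_empty:
            raise EmptyStructureError(f"prescription target {name!r} is empty")
        d = ndimage.distance_transform_edt(~mask.voxels, sampling=grid.spacing)
        np.maximum(dose, rx * np.exp2(-d / h), out=dose)
        target_union |= mask.voxels
    for name, w in params.oar_sparing:
        if name not in planning_set:
            raise ValueError(f"sparing structure {name!r} not in planning set")
        spared = planning_set[name].voxels & ~target_union
        dose[spared] *= (1.0 - w)
    np.maximum(dose, params.background_floor_gy, out=dose)
    return DoseGrid(grid, dose, meta={
        "planning_source": planning_set.source,
        "subject_id": planning_set.subject_id,
        "falloff_half_distance_mm": h,
    })


def plan_for(subject_pair: tuple[StructureSet, StructureSet], mode_source: str,
             params: DoseModelParams, target_policy: str = "same_source") -> DoseGrid:
    """Build the planning structure set for one evaluation arm and synthesise
    its dose.

    ``mode_source`` picks which contour set drives the plan ("AS" or "MS").
    ``target_policy``:

    * ``same_source`` — targets and OARs both come from ``mode_source``
      (prostate-style planning, where the auto-segmented target is trusted).
    * ``always_MS_target`` — targets always come from the manual set, OARs
      from ``mode_source`` (head-and-neck-style planning, where targets are
      clinician-drawn and only OARs are auto-segmented).
    """
    if mode_source not in ("AS", "MS"):
        raise ValueError(f"mode_source must be 'AS' or 'MS', got {mode_source!r}")
    if target_policy not in ("same_source", "always_MS_target"):
        raise ValueError(f"unknown target_policy {target_policy!r}")
    ms_set, as_set = subject_pair
    if ms_set.source != "MS" or as_set.source != "AS":
        raise ValueError("subject_pair must be (MS set, AS set)")
    source_set = as_set if mode_source == "AS" else ms_set
    target_names = {n for n, _ in params.prescriptions}
    structures = {}
    for name in source_set.names:
        if target_policy == "always_MS_target" and name in target_names:
            structures[name] = ms_set[name]
        else:
            structures[name] = source_set[name]
    for name in target_names:
        if name not in structures:
            raise ValueError(
                f"target {name!r} missing from {mode_source} set of "
                f"{source_set.subject_id!r}"
            )
    planning_set = StructureSet(source_set.subject_id, source_set.source, structures)
    out = synthesize_dose(planning_set, params)
    out.meta["target_policy"] = target_policy
    out.meta["mode_source"] = mode_source
    return out
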