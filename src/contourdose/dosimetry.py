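"""Cumulative DVHs, dosimetric endpoints and clinical constraint evaluation.

Endpoints follow the conventions of treatment-planning systems:

* ``VxGy`` — percentage of a structure's volume receiving at least x Gy
  (closed superlevel set, dose >= x).
* ``Max`` — single hottest voxel in the structure, Gy.
* ``Mean`` — arithmetic mean voxel dose, Gy.

Constraints are parsed from the compact clinical notation used in planning
protocols (``V40Gy ≥ 95%``, ``Max <52Gy``, ``Mean <25Gy``); both ``<``/``≤``
and ASCII ``<=``/``>=`` spellings are accepted and strictness is preserved
as parsed.  Constraint evaluation is always bin-free (computed directly from
voxel doses), so DVH binning can never change a pass/fail outcome.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import ConstraintParseError, EmptyStructureError, IncompatibleGridsError
from .grid import StructureMask
from .planner import DoseGrid

__all__ = [
    "DVHCurve",
    "Constraint",
    "ConstraintResult",
    "cumulative_dvh",
    "volume_at_dose",
    "dose_max",
    "dose_mean",
    "parse_constraint",
    "evaluate_constraint",
    "load_constraint_table",
    "builtin_constraints",
]


def _in_mask_doses(dose: DoseGrid, mask: StructureMask) -> np.ndarray:
    if dose.grid != mask.grid:
        raise IncompatibleGridsError(
            f"dose grid and mask {mask.name!r} grid differ"
        )
    if mask.is_empty:
        raise EmptyStructureError(f"structure {mask.name!r} is empty")
    return dose.dose[mask.voxels]


@dataclass
class DVHCurve:
    """Cumulative dose-volume histogram: % of volume receiving >= each edge."""

    bin_edges: np.ndarray        # Gy, 0, w, 2w, ...
    cumulative_volume: np.ndarray  # %, starts at 100, non-increasing
    structure: str
    mode: str = ""

    def integral_gy(self) -> float:
        """Trapezoid integral of the curve / 100 — approximates the mean dose
        to within one bin width."""
        return float(np.trapezoid(self.cumulative_volume, self.bin_edges) / 100.0)


def cumulative_dvh(dose: DoseGrid, mask: StructureMask, bin_width: float = 0.1,
                   mode: str = "") -> DVHCurve:
    """Cumulative DVH by unweighted voxel counting.

    Edges run 0, w, 2w, ... up to the first edge strictly above the in-mask
    maximum dose, so the curve always starts at 100% and ends at 0%.
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be > 0, got {bin_width}")
    doses = _in_mask_doses(dose, mask)
    dmax = float(doses.max())
    n_edges = int(np.floor(dmax / bin_width)) + 2  # last edge > dmax
    edges = np.arange(n_edges) * bin_width
    # % of voxels with dose >= edge, for each edge.
    values = 100.0 * (doses[None, :] >= edges[:, None]).mean(axis=1)
    return DVHCurve(edges, values, mask.name, mode)


def volume_at_dose(dose: DoseGrid, mask: StructureMask, d: float) -> float:
    """Bin-free VxGy: % of occupied voxels with dose >= d."""
    doses = _in_mask_doses(dose, mask)
    return float(100.0 * (doses >= d).mean())


def dose_max(dose: DoseGrid, mask: StructureMask) -> float:
    """Hottest voxel dose in the structure, Gy."""
    return float(_in_mask_doses(dose, mask).max())


def dose_mean(dose: DoseGrid, mask: StructureMask) -> float:
    """Mean voxel dose in the structure, Gy (uniform voxel volume)."""
    return float(_in_mask_doses(dose, mask).mean())


_RELATIONS = {"<": "<", "<=": "≤", "≤": "≤", ">=": "≥", "≥": "≥"}
_V_RE = re.compile(
    r"^\s*V\s*(?P<dose>\d+(?:\.\d+)?)\s*Gy\s*(?P<rel><=|>=|<|≤|≥)\s*"
    r"(?P<limit>\d+(?:\.\d+)?)\s*%\s*$", re.IGNORECASE)
_MM_RE = re.compile(
    r"^\s*(?P<metric>Max|Mean)\s*(?P<rel><=|>=|<|≤|≥)\s*"
    r"(?P<limit>\d+(?:\.\d+)?)\s*Gy\s*$", re.IGNORECASE)


@dataclass(frozen=True)
class Constraint:
    """One parsed clinical dose limit for a structure."""

    structure: str
    metric: str              # "V_at_dose" | "max" | "mean"
    limit: float             # % for V_at_dose, Gy for max/mean
    relation: str            # "<", "≤" or "≥"
    dose_gy: float | None = None  # V_at_dose only
    source_text: str = ""

    def __post_init__(self) -> None:
        if self.metric not in ("V_at_dose", "max", "mean"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if (self.dose_gy is None) == (self.metric == "V_at_dose"):
            raise ValueError("dose_gy must be present iff metric is V_at_dose")
        if self.limit <= 0:
            raise ValueError(f"limit must be > 0, got {self.limit}")
        if self.relation not in ("<", "≤", "≥"):
            raise ValueError(f"unknown relation {self.relation!r}")
        if self.relation == "≥" and self.metric != "V_at_dose":
            raise ValueError(
                "'≥' is only valid for target-coverage (VxGy) constraints"
            )

    @property
    def unit(self) -> str:
        return "%" if self.metric == "V_at_dose" else "Gy"

    def render(self) -> str:
        """Canonical text form; parse(render(c)) reproduces the constraint."""
        if self.metric == "V_at_dose":
            return f"V{self.dose_gy:g}Gy {self.relation} {self.limit:g}%"
        return f"{self.metric.capitalize()} {self.relation} {self.limit:g}Gy"

    @property
    def key(self) -> str:
        """Stable identifier used in result tables."""
        return f"{self.structure} {self.render()}"


@dataclass(frozen=True)
class ConstraintResult:
    """Achieved endpoint value and pass/fail against one constraint."""

    constraint: Constraint
    achieved: float
    passed: bool
    margin: float  # signed distance to the limit; > 0 means room to spare


def parse_constraint(text: str, structure: str = "") -> Constraint:
    """Parse a constraint string like ``V40Gy ≥ 95%`` or ``Max <52Gy``.

    Tolerant of spacing and of ASCII ``<=``/``>=`` in place of ``≤``/``≥``;
    strictness (``<`` vs ``≤``) is preserved exactly as written.
    """
    m = _V_RE.match(text)
    if m:
        return Constraint(
            structure=structure, metric="V_at_dose",
            dose_gy=float(m.group("dose")), limit=float(m.group("limit")),
            relation=_RELATIONS[m.group("rel")], source_text=text,
        )
    m = _MM_RE.match(text)
    if m:
        return Constraint(
            structure=structure, metric=m.group("metric").lower(),
            limit=float(m.group("limit")),
            relation=_RELATIONS[m.group("rel")], source_text=text,
        )
    raise ConstraintParseError(
        f"cannot parse constraint {text!r}: expected 'V<d>Gy <rel> <p>%', "
        f"'Max <rel> <d>Gy' or 'Mean <rel> <d>Gy'"
    )


def evaluate_constraint(c: Constraint, dose: DoseGrid, mask: StructureMask
                        ) -> ConstraintResult:
    """Evaluate one constraint bin-free on voxel doses.

    Strict ``<`` is evaluated strictly: an achieved value exactly at the
    limit fails a ``<`` constraint but passes a ``≤`` one.
    """
    if c.metric == "V_at_dose":
        achieved = volume_at_dose(dose, mask, c.dose_gy)
    elif c.metric == "max":
        achieved = dose_max(dose, mask)
    else:
        achieved = dose_mean(dose, mask)
    if c.relation == "<":
        passed = achieved < c.limit
        margin = c.limit - achieved
    elif c.relation == "≤":
        passed = achieved <= c.limit
        margin = c.limit - achieved
    else:  # ≥ (coverage)
        passed = achieved >= c.limit
        margin = achieved - c.limit
    return ConstraintResult(c, achieved, passed, margin)


def load_constraint_table(path) -> list[Constraint]:
    """Load a constraint table CSV with columns ``structure, constraint_text``."""
    df = pd.read_csv(path)
    missing = {"structure", "constraint_text"} - set(df.columns)
    if missing:
        raise ValueError(f"constraint table lacks columns: {sorted(missing)}")
    return [parse_constraint(row.constraint_text, structure=row.structure)
            for row in df.itertuples()]


def builtin_constraints(site: str) -> list[Constraint]:
    """Built-in clinical constraint tables: ``"prostate"`` (9 rows, 40 Gy
    SBRT protocol) or ``"hn"`` (16 rows, 70/60/54 Gy SIB protocol)."""
    if site not in ("prostate", "hn"):
        raise ValueError(f"unknown site {site!r}; expected 'prostate' or 'hn'")
    ref = resources.files("contourdose.data") / f"{site}_constraints.csv"
    with resources.as_file(ref) as path:
        return load_constraint_table(path)
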