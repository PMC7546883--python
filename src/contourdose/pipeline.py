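"""Three-mode plan/contour cross-evaluation, paired statistics and the
geometric-vs-dosimetric discrepancy experiment.

The cross-evaluation design compares three sets of DVH endpoints per
subject:

* ``PlanMEvalM`` — plan optimised on manual (MS) contours, evaluated with
  MS contours: the clinical reference.
* ``PlanAEvalA`` — plan optimised on auto-segmented (AS) contours,
  evaluated with AS contours: the fully automatic workflow.
* ``PlanAEvalM`` — the AS-optimised plan evaluated with MS contours: the
  controlled observation of what the automatic plan actually delivers to
  the true anatomy.

The fourth combination (MS plan on AS contours) is intentionally never
produced — it answers no clinical question in this design.  Endpoints are
compared per constraint across subjects with paired t-tests at two-sided
α = 0.05, without multiple-testing correction.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .dosimetry import Constraint, builtin_constraints, dose_max, dose_mean, \
    evaluate_constraint, load_constraint_table
from .geometry import compare_structures, dice, hausdorff
from .grid import StructureSet, VoxelGrid
from .phantom import CohortSpec, PerturbationSpec, StructureTemplate, \
    simulate_cohort, simulate_subject
from .planner import DoseGrid, DoseModelParams, plan_for

__all__ = [
    "EvalMode",
    "CrossEvalRecord",
    "PairedTestResult",
    "cross_evaluate",
    "records_to_frame",
    "paired_t",
    "count_exceedances",
    "summarize_modes",
    "paired_tests_by_constraint",
    "SweepConfig",
    "discrepancy_experiment",
    "default_prostate_cohort",
    "StudyConfig",
    "run_study",
]

ALPHA = 0.05


class EvalMode(str, Enum):
    """(plan source, evaluation contour source) combinations."""

    PlanAEvalA = "PlanAEvalA"
    PlanMEvalM = "PlanMEvalM"
    PlanAEvalM = "PlanAEvalM"


@dataclass(frozen=True)
class CrossEvalRecord:
    """One achieved endpoint value for (subject, constraint, mode)."""

    subject_id: str
    structure: str
    constraint: str  # canonical "structure metric" key
    mode: EvalMode
    achieved: float
    passed: bool
    unit: str


def cross_evaluate(subject_pair: tuple[StructureSet, StructureSet],
                   constraints: list[Constraint], params: DoseModelParams,
                   target_policy: str = "same_source") -> list[CrossEvalRecord]:
    """Evaluate every constraint under the three plan/contour modes.

    Two plans are synthesised (one per contour source); each constraint is
    then scored on the AS contours for ``PlanAEvalA`` and on the MS contours
    for ``PlanMEvalM`` and ``PlanAEvalM``.
    """
    ms_set, as_set = subject_pair
    for c in constraints:
        for s, label in ((ms_set, "MS"), (as_set, "AS")):
            if c.structure not in s:
                raise ValueError(
                    f"constraint {c.key!r}: structure {c.structure!r} missing "
                    f"from {label} set of subject {s.subject_id!r}"
                )
    plan_a = plan_for(subject_pair, "AS", params, target_policy)
    plan_m = plan_for(subject_pair, "MS", params, target_policy)
    arms: list[tuple[EvalMode, DoseGrid, StructureSet]] = [
        (EvalMode.PlanAEvalA, plan_a, as_set),
        (EvalMode.PlanMEvalM, plan_m, ms_set),
        (EvalMode.PlanAEvalM, plan_a, ms_set),
    ]
    records = []
    for c in constraints:
        for mode, plan, eval_set in arms:
            try:
                res = evaluate_constraint(c, plan, eval_set[c.structure])
            except ValueError as e:
                raise type(e)(
                    f"subject {ms_set.subject_id!r}, structure {c.structure!r}: {e}"
                ) from e
            records.append(CrossEvalRecord(
                subject_id=ms_set.subject_id, structure=c.structure,
                constraint=c.key, mode=mode, achieved=res.achieved,
                passed=res.passed, unit=c.unit,
            ))
    return records


def records_to_frame(records: list[CrossEvalRecord]) -> pd.DataFrame:
    df = pd.DataFrame([{**asdict(r), "mode": r.mode.value} for r in records])
    return df[["subject_id", "structure", "constraint", "mode",
               "achieved", "passed", "unit"]]


@dataclass(frozen=True)
class PairedTestResult:
    """Paired t-test on per-subject endpoint differences."""

    n: int
    mean_diff: float
    sd_diff: float
    t_statistic: float  # NaN when degenerate
    p_value: float
    significant: bool
    degenerate: bool
    constraint: str = ""
    mode_pair: str = ""


def paired_t(values_x, values_y, constraint: str = "", mode_pair: str = ""
             ) -> PairedTestResult:
    """Two-sided paired t-test, subjects aligned by position.

    t = mean(d) / (sd(d)/√n) with sample sd (n−1 denominator) and p from the
    Student t distribution with n−1 degrees of freedom.  Zero-variance
    differences yield no finite t and are flagged degenerate: p = 1 when the
    common difference is 0, p = 0 when it is not.
    """
    x = np.asarray(values_x, dtype=float)
    y = np.asarray(values_y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired samples must be 1-D and equal length")
    n = len(x)
    if n < 2:
        raise ValueError(f"paired t-test needs n >= 2 subjects, got {n}")
    d = x - y
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    if sd_d == 0.0:
        p = 1.0 if mean_d == 0.0 else 0.0
        return PairedTestResult(n, mean_d, sd_d, float("nan"), p,
                                significant=p < ALPHA, degenerate=True,
                                constraint=constraint, mode_pair=mode_pair)
    t = mean_d / (sd_d / np.sqrt(n))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
    return PairedTestResult(n, mean_d, sd_d, float(t), p,
                            significant=p < ALPHA, degenerate=False,
                            constraint=constraint, mode_pair=mode_pair)


def _check_complete(df: pd.DataFrame) -> None:
    subjects = sorted(df["subject_id"].unique())
    counts = df.groupby(["constraint", "mode"])["subject_id"].agg(list)
    missing = []
    for (constraint, mode), subs in counts.items():
        if len(subs) != len(set(subs)):
            dup = sorted({s for s in subs if subs.count(s) > 1})
            raise ValueError(
                f"duplicate records for ({constraint!r}, {mode!r}): {dup}"
            )
        absent = sorted(set(subjects) - set(subs))
        if absent:
            missing.append((constraint, mode, absent))
    if missing:
        raise ValueError(f"incomplete record set; missing cells: {missing}")


def count_exceedances(records: list[CrossEvalRecord] | pd.DataFrame) -> pd.DataFrame:
    """Number of subjects failing each (constraint, mode) cell.

    Zero rows are included so all-pass results show explicitly; an
    incomplete or duplicated record set is an error.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    _check_complete(df)
    out = (df.assign(failed=~df["passed"])
             .groupby(["constraint", "mode"], sort=True)["failed"]
             .sum().astype(int).reset_index()
             .rename(columns={"failed": "n_exceeding"}))
    return out


def summarize_modes(records: list[CrossEvalRecord] | pd.DataFrame) -> pd.DataFrame:
    """Mean ± sample SD of achieved values per (constraint, mode).

    SD is reported as NaN (absent) for single-subject cells.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if df.empty:
        raise ValueError("no records to summarize")
    g = df.groupby(["constraint", "mode"], sort=True)["achieved"]
    out = g.agg(n="count", mean="mean", sd=lambda v: v.std(ddof=1)).reset_index()
    units = df.groupby(["constraint", "mode"], sort=True)["unit"].first().reset_index()
    return out.merge(units, on=["constraint", "mode"])


_MODE_PAIRS = (
    (EvalMode.PlanAEvalA, EvalMode.PlanMEvalM),
    (EvalMode.PlanAEvalA, EvalMode.PlanAEvalM),
)


def paired_tests_by_constraint(records: list[CrossEvalRecord] | pd.DataFrame
                               ) -> pd.DataFrame:
    """Per-constraint paired t-tests across subjects for the two comparisons
    of interest: fully-automatic vs clinical, and automatic-plan-on-true-
    anatomy vs automatic-plan-on-its-own-contours."""
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    _check_complete(df)
    rows = []
    for constraint, sub in df.groupby("constraint", sort=True):
        wide = sub.pivot(index="subject_id", columns="mode", values="achieved")
        for mx, my in _MODE_PAIRS:
            res = paired_t(wide[mx.value].to_numpy(), wide[my.value].to_numpy(),
                           constraint=constraint,
                           mode_pair=f"{mx.value} vs {my.value}")
            rows.append({
                "constraint": constraint, "mode_pair": res.mode_pair, "n": res.n,
                "mean_diff": res.mean_diff, "sd_diff": res.sd_diff,
                "t_statistic": res.t_statistic, "p_value": res.p_value,
                "significant": res.significant, "degenerate": res.degenerate,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

def default_prostate_cohort(n_subjects: int = 5, seed: int = 0,
                            grid: VoxelGrid | None = None,
                            perturbed: bool = True) -> CohortSpec:
    """Prostate-like phantom: a central spherical target with six OARs whose
    shapes, sizes and perturbations span the regimes that matter — large
    nearly-rigid structures (femoral heads), an elongated tube with
    superior-inferior truncation (rectum), and small structures with large
    relative error (seminal vesicle, penile bulb).

    ``perturbed=False`` gives the identity cohort (AS ≡ MS), the control
    condition for mode-identity checks.
    """
    if grid is None:
        grid = VoxelGrid((96, 96, 96), (2.0, 2.0, 2.0))
    templates = (
        StructureTemplate("CTV", "target", "sphere", (20.0,)),
        StructureTemplate("Bladder", "oar", "ellipsoid", (30.0, 25.0, 20.0),
                          direction=(0, 1, 0), gap_mm=5.0),
        StructureTemplate("Rectum", "oar", "tube", (10.0, 80.0), axis=(0, 0, 1),
                          direction=(0, -1, 0), gap_mm=5.0),
        StructureTemplate("Femur L", "oar", "sphere", (18.0,),
                          direction=(-1, 0, 0), gap_mm=17.0),
        StructureTemplate("Femur R", "oar", "sphere", (18.0,),
                          direction=(1, 0, 0), gap_mm=17.0),
        StructureTemplate("Penile bulb", "oar", "sphere", (8.0,),
                          direction=(0, 0, -1), gap_mm=15.0),
        StructureTemplate("Seminal vesicle", "oar", "ellipsoid", (12.0, 8.0, 8.0),
                          direction=(0, 0.6, 0.8), gap_mm=2.0),
    )
    perturbations = {
        "CTV": PerturbationSpec("translate", 2.0, axis=(1, 0, 0)),
        "Bladder": PerturbationSpec("dilate", 2.0),
        "Rectum": PerturbationSpec("truncate_axial", 8.0),
        "Femur L": PerturbationSpec("translate", 2.0, axis=(0, 0, 1)),
        "Femur R": PerturbationSpec("translate", 2.0, axis=(0, 0, -1)),
        "Penile bulb": PerturbationSpec("surface_noise", 0.4),
        "Seminal vesicle": PerturbationSpec("translate", 8.0,
                                            axis=(0.0, 0.7071067811865476,
                                                  0.7071067811865476)),
    } if perturbed else {}
    return CohortSpec(n_subjects=n_subjects, grid=grid, templates=templates,
                      perturbations=perturbations, seed=seed)


def default_prostate_params(h_mm: float = 5.0) -> DoseModelParams:
    """40 Gy single-target prescription with steep falloff and moderate
    bladder/rectum sparing."""
    return DoseModelParams(
        prescriptions=(("CTV", 40.0),), falloff_half_distance_mm=h_mm,
        oar_sparing=(("Bladder", 0.2), ("Rectum", 0.2)),
    )


# ---------------------------------------------------------------------------
# Discrepancy experiment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SweepConfig:
    """Sweep of OAR distance-to-target × perturbation magnitude at fixed
    dose falloff, isolating how the same geometric error translates to very
    different dosimetric error depending on where the structure sits in the
    dose gradient."""

    distances_mm: tuple[float, ...] = (10.0, 25.0, 40.0)
    magnitudes_mm: tuple[float, ...] = (2.0, 4.0, 8.0)
    falloff_mm: float = 5.0
    n_per_cell: int = 5
    seed: int = 0
    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    target_radius_mm: float = 20.0
    oar_radius_mm: float = 8.0
    rx_gy: float = 40.0
    sparing_weight: float = 0.3


def discrepancy_experiment(config: SweepConfig) -> pd.DataFrame:
    """Run the sweep; one row per (distance, magnitude, subject).

    Each cell simulates ``n_per_cell`` subjects with a spherical target and a
    single spherical OAR at surface gap ``distance_mm`` along +x, perturbed
    by a rigid +x translation of ``magnitude_mm``.  Geometric agreement
    (DSC, HD) and mean/max-dose endpoints under the three evaluation modes
    are recorded together so their (dis)agreement can be read off directly.
    """
    grid = VoxelGrid(config.grid_shape, config.spacing_mm)
    params = DoseModelParams(
        prescriptions=(("Target", config.rx_gy),),
        falloff_half_distance_mm=config.falloff_mm,
        oar_sparing=(("OAR", config.sparing_weight),),
    )
    rows = []
    cell = 0
    for dist in config.distances_mm:
        for mag in config.magnitudes_mm:
            templates = (
                StructureTemplate("Target", "target", "sphere",
                                  (config.target_radius_mm,)),
                StructureTemplate("OAR", "oar", "sphere", (config.oar_radius_mm,),
                                  direction=(1, 0, 0), gap_mm=float(dist)),
            )
            perturbations = {
                "OAR": PerturbationSpec("translate", float(mag), axis=(1, 0, 0)),
            } if mag > 0 else {}
            spec = CohortSpec(
                n_subjects=config.n_per_cell, grid=grid, templates=templates,
                perturbations=perturbations,
                seed=(config.seed + 9973 * cell) % (2 ** 31),
                center_jitter_mm=2.0,
            )
            for ms_set, as_set in simulate_cohort(spec):
                pair = (ms_set, as_set)
                plan_a = plan_for(pair, "AS", params)
                plan_m = plan_for(pair, "MS", params)
                oar_ms, oar_as = ms_set["OAR"], as_set["OAR"]
                mean_aa = dose_mean(plan_a, oar_as)
                mean_mm = dose_mean(plan_m, oar_ms)
                mean_am = dose_mean(plan_a, oar_ms)
                rows.append({
                    "distance_mm": dist, "magnitude_mm": mag,
                    "subject_id": ms_set.subject_id,
                    "dsc": dice(oar_ms, oar_as),
                    "hd_mm": hausdorff(oar_ms, oar_as),
                    "mean_dose_PlanAEvalA": mean_aa,
                    "mean_dose_PlanMEvalM": mean_mm,
                    "mean_dose_PlanAEvalM": mean_am,
                    "d_mean_plan_gy": mean_aa - mean_mm,
                    "d_mean_eval_gy": mean_aa - mean_am,
                    "max_dose_PlanAEvalA": dose_max(plan_a, oar_as),
                    "max_dose_PlanAEvalM": dose_max(plan_a, oar_ms),
                })
            cell += 1
    return pd.DataFrame(rows)


def sweep_cell_summary(sweep: pd.DataFrame) -> pd.DataFrame:
    """Per-cell means of |Δ mean dose| and DSC from a sweep frame."""
    g = sweep.groupby(["magnitude_mm", "distance_mm"], sort=True)
    out = g.agg(
        dsc_mean=("dsc", "mean"),
        abs_d_mean_eval_gy=("d_mean_eval_gy", lambda v: float(np.abs(v).mean())),
        abs_d_mean_plan_gy=("d_mean_plan_gy", lambda v: float(np.abs(v).mean())),
    ).reset_index()
    return out


# ---------------------------------------------------------------------------
# End-to-end study
# ---------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """Configuration for one end-to-end study run."""

    cohort: CohortSpec
    params: DoseModelParams
    constraints_path: str | None = None  # None -> built-in site table
    site: str = "prostate"
    target_policy: str = "same_source"
    out_dir: str = "results/study"
    sweep: SweepConfig | None = None


def run_study(config: StudyConfig) -> dict[str, pd.DataFrame]:
    """Simulate → geometric comparison → cross-evaluation → statistics →
    report.  Writes CSV tables plus a JSON manifest under
    ``config.out_dir``; identical config + seed reproduce the files byte for
    byte.  Returns the tables keyed by output name.
    """
    # Validate inputs before any simulation work.
    if config.constraints_path is not None:
        path = Path(config.constraints_path)
        if not path.exists():
            raise FileNotFoundError(f"constraints file not found: {path}")
        constraints = load_constraint_table(path)
    else:
        constraints = builtin_constraints(config.site)

    pairs = simulate_cohort(config.cohort)

    geom_rows = []
    for ms_set, as_set in pairs:
        for m in compare_structures(ms_set, as_set).metrics:
            geom_rows.append(asdict(m))
    geometry = pd.DataFrame(geom_rows)
    geo_summary = (geometry.groupby("structure", sort=True)
                   .agg(n=("dsc", "count"), dsc_mean=("dsc", "mean"),
                        dsc_sd=("dsc", lambda v: v.std(ddof=1)),
                        hd_mean_mm=("hd_mm", "mean"),
                        hd_sd_mm=("hd_mm", lambda v: v.std(ddof=1)))
                   .reset_index())

    records: list[CrossEvalRecord] = []
    for pair in pairs:
        records.extend(cross_evaluate(pair, constraints, config.params,
                                      config.target_policy))
    records_df = records_to_frame(records)

    bundle = {
        "geometry_metrics": geometry,
        "geometry_summary": geo_summary,
        "cross_eval_records": records_df,
        "mode_summary": summarize_modes(records_df),
        "exceedance_counts": count_exceedances(records_df),
        "paired_tests": paired_tests_by_constraint(records_df),
    }
    if config.sweep is not None:
        bundle["discrepancy_sweep"] = discrepancy_experiment(config.sweep)

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, df in bundle.items():
        df.to_csv(out_dir / f"{name}.csv", index=False)
    from . import __version__
    manifest = {
        "software_version": __version__,
        "seed": config.cohort.seed,
        "n_subjects": config.cohort.n_subjects,
        "site": config.site,
        "target_policy": config.target_policy,
        "grid_shape": list(config.cohort.grid.shape),
        "spacing_mm": list(config.cohort.grid.spacing),
        "structures": [t.name for t in config.cohort.templates],
        "perturbations": {k: {"kind": v.kind, "magnitude": v.magnitude}
                          for k, v in config.cohort.perturbations.items()},
        "prescriptions": [list(p) for p in config.params.prescriptions],
        "falloff_half_distance_mm": config.params.falloff_half_distance_mm,
        "oar_sparing": [list(s) for s in config.params.oar_sparing],
        "n_constraints": len(constraints),
        "outputs": sorted(f"{name}.csv" for name in bundle),
    }
    with open(out_dir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return bundle
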