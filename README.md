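# contourdose

Geometric and dosimetric evaluation of auto-segmented radiotherapy
contours, on synthetic phantom cohorts.

## The problem

Auto-segmentation (AS) tools are usually validated against manual
segmentation (MS) with geometric metrics — the Dice similarity coefficient

    DSC = 2 |V_AS ∩ V_MS| / (|V_AS| + |V_MS|)

and the symmetric Hausdorff distance

    HD = max{ dHD(A, B), dHD(B, A) },   dHD(A, B) = max_{a∈A} min_{b∈B} ‖a − b‖

over the contours' boundary point sets, in mm.  But what matters clinically
is the *dosimetric* consequence: if a treatment plan is optimised on AS
contours, does it still satisfy the clinical dose-volume constraints
(VxGy, Max, Mean limits) when judged against the true anatomy?  The two
views can disagree sharply — a structure with poor DSC far from the target
may be dosimetrically irrelevant, while a modest contour error in a steep
dose gradient can break a constraint.

This package makes that interplay computable end to end:

* **phantom** — seeded cohorts of paired MS ("truth") and AS (perturbed)
  structure sets on physically-spaced voxel grids, with controllable
  translation, dilation/erosion, superior axial truncation and boundary
  noise;
* **geometry** — DSC and symmetric HD (boundary-voxel centres, exact
  distances, anisotropic spacing honoured);
* **planner** — a closed-form dose surrogate: prescription dose inside each
  target, halving every *h* mm outside it (40 Gy single-target and
  70/60/54 Gy SIB presets), with hard OAR-sparing multipliers so the plan
  genuinely depends on the contours used;
* **dosimetry** — cumulative DVHs, bin-free VxGy/Max/Mean endpoints, and a
  parser/evaluator for clinical constraint tables (shipped for a prostate
  SBRT and a head-and-neck SIB protocol, 25 rows);
* **pipeline** — the three-mode cross-evaluation (PlanAEvalA, PlanMEvalM,
  PlanAEvalM = AS-optimised plan scored on MS contours), per-constraint
  paired t-tests, exceedance accounting, and the distance × perturbation
  discordance sweep.

## Worked example

```python
import contourdose as cd

cohort = cd.default_prostate_cohort(n_subjects=5, seed=7)
params = cd.default_prostate_params()          # 40 Gy, h = 5 mm falloff
constraints = cd.builtin_constraints("prostate")

pairs = cd.simulate_cohort(cohort)
ms, as_ = pairs[0]
for m in cd.compare_structures(ms, as_).metrics:
    print(f"{m.structure:16s} DSC {m.dsc:.3f}  HD {m.hd_mm:.1f} mm")
```

```
CTV              DSC 0.922  HD 2.0 mm
Bladder          DSC 0.904  HD 2.0 mm
Rectum           DSC 0.975  HD 8.0 mm
Femur L          DSC 0.917  HD 2.0 mm
Femur R          DSC 0.921  HD 2.0 mm
Penile bulb      DSC 0.885  HD 2.0 mm
Seminal vesicle  DSC 0.305  HD 8.5 mm
```

Large rigid structures track well; the small displaced seminal vesicle does
not (DSC 0.31), and the truncated rectum shows how HD punishes a localised
8 mm defect that barely moves its DSC (0.98).  The dosimetric side:

```python
records = []
for pair in pairs:
    records += cd.cross_evaluate(pair, constraints, params)
df = cd.records_to_frame(records)
print(cd.count_exceedances(df).query("n_exceeding > 0"))
```

```
     constraint        mode  n_exceeding
CTV V40Gy ≥ 95%  PlanAEvalM            5
```

Every OAR constraint passes in every mode despite the geometric errors —
but the AS-optimised plan, scored on the *true* target (PlanAEvalM), misses
coverage in all five subjects: the 2 mm target shift matters exactly where
the dose gradient is steep.  The `analysis/` scripts run this study in
sequence (`01_simulate_cohort.py` … `04_discrepancy_sweep.py`) and write
their tables under `results/`; script 04 quantifies the headline
discordance — cells of the sweep with |ΔDSC| < 0.02 whose mean-dose deltas
differ by ~70× depending on distance from the target.

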