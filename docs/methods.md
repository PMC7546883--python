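# Methods

## Spatial frame and occupancy

All masks and dose live on a regular axis-aligned voxel grid with physical
spacing in mm; voxel centre (i, j, k) sits at `origin + index·spacing`
(0-based).  Rasterisation uses the voxel-centre-in-shape rule — a voxel
belongs to a structure iff its centre lies inside the analytic shape — so
every rasterised volume is exactly testable by counting centres, and
converges to the analytic volume as resolution grows (within 5 % for
spheres with radius ≥ 5× spacing).  The default grid is 96×96×96 at 2 mm
isotropic spacing: desk-scale runtimes while keeping ≥ 10 voxels across
every default structure.

## Phantom cohorts

Real paired MS/AS structure sets are institutional data and not publicly
deposited, so the study runs on synthetic cohorts that emulate the error
*patterns* of atlas-based auto-segmentation, not organ anatomy.  Each
subject draws per-structure centre jitter (uniform, ±3 mm default) and size
jitter (±5 %) from an RNG seeded with `cohort_seed + subject_index`, making
every subject a pure function of (seed, index).  The AS set is the MS set
with one perturbation per structure:

| kind           | magnitude meaning            | emulates                         |
|----------------|------------------------------|----------------------------------|
| translate      | mm, rounded to whole voxels  | systematic offset of small organs|
| dilate / erode | ball radius, mm (physical)   | over-/under-segmentation         |
| truncate_axial | mm removed from superior end | superior–inferior extent variation of elongated organs (cord, esophagus, rectum) |
| surface_noise  | fraction of boundary voxels toggled, in [0, 1] | ragged boundaries |

Translation rounds to whole-voxel offsets per axis to keep masks binary
without resampling.  Surface noise interprets magnitude as an expected
boundary-toggle fraction (a mm magnitude is meaningless for it): with
inner boundary = occupied voxels 6-adjacent to an unoccupied voxel and
outer shell = unoccupied voxels 6-adjacent to the mask, each inner voxel is
removed with probability m/2 and each outer voxel added with probability
(m/2)·|inner|/|outer| (clipped at 1), giving an expected m·|inner| toggles.
Magnitude-0 perturbations of every kind are exact identities.

The default prostate-like cohort (5 subjects, matching the dosimetric
sub-study size) contains a 20 mm spherical target and six OARs spanning the
regimes that drive the metrics: large near-rigid spheres (femoral heads,
translate 2 mm → DSC ≈ 0.92), an ellipsoidal bladder (dilate 2 mm), an
80 mm rectal tube truncated superiorly by 8 mm (DSC ≈ 0.98 yet HD = 8 mm —
the localisation-blindness of DSC), a noisy penile bulb, and a small
seminal-vesicle ellipsoid translated 8 mm (DSC ≈ 0.3).  These values are
declared study conditions, not fits to any dataset.

## Geometric metrics

DSC is computed on occupied-voxel counts.  HD is computed in 3D on
boundary-voxel centres (occupied voxels with an unoccupied 6-neighbour; the
grid border counts as unoccupied), converting indices to mm before any
distance so anisotropic spacing is honoured.  Distances are exact: an
all-pairs distance matrix when |A|·|B| ≤ 4·10⁶ (bit-compatible with the
brute-force oracle used in the tests) and a KD-tree beyond that.  Surface
points rather than all occupied voxels are used because contour distance is
a boundary notion; this is a declared convention.  Conventions for
degenerate inputs: one empty mask → DSC = 0 by definition, HD undefined
(error); two empty masks → DSC undefined (error).  Note that identical
occupancy implies DSC = 1 and HD = 0, but HD = 0 does not imply identical
occupancy in every pathological case (a solid cube and the same cube with
its centre voxel removed share a boundary point set), so only the forward
implication is guaranteed.

## Dose surrogate

Inverse-optimised VMAT dose is irreproducible outside a commercial
treatment-planning system; the study only needs plans that (a) depend on
the contour set used to optimise and (b) have a controllable gradient,
since gradient × geometry is precisely the interaction under study.  The
surrogate is closed-form: per target T, `f_T(x) = Rx_T · 2^(−d(x,T)/h)`
with d the exact Euclidean distance (mm) to the nearest occupied target
voxel centre (d = 0 inside, so the plateau is exactly Rx), combined across
prescription levels by voxelwise maximum; sparing multiplies dose inside a
spared OAR (outside all targets) by (1 − w); finally a background floor is
applied.  The falloff half-distance h is the single gradient dial: presets
h = 5 mm (steep, SBRT-like) and h = 10 mm (conventional); floor defaults to
0 Gy.  Sparing is a hard in-mask multiplier with no feathering so the
dependence of dose on each contour stays exactly interpretable in tests.
Default prescriptions: 40 Gy single target (prostate-style), 70/60/54 Gy
simultaneous integrated boost (head-and-neck-style).

Plan policies mirror clinical practice: `same_source` plans targets and
OARs from one contour source; `always_MS_target` keeps clinician-drawn
targets and takes only OARs from the AS set.

## DVH and constraints

Cumulative DVHs use unweighted voxel counting with 0.1 Gy default bins;
edges run from 0 to just above the in-mask maximum, so curves start at
100 % and end at 0 %, and the trapezoid integral of the curve/100
reproduces the voxel mean dose within one bin width.  VxGy uses the closed
superlevel set (dose ≥ x), the standard TPS convention; Max is the single
hottest voxel (no volume-max refinement); volumes are relative (%).
Constraint evaluation is always bin-free so binning can never flip a
pass/fail.  The parser accepts `V<d>Gy <rel> <p>%`, `Max <rel> <d>Gy`,
`Mean <rel> <d>Gy` with rel ∈ {<, ≤, ≥} (ASCII `<=`/`>=` accepted);
strictness is preserved exactly and `≥` is restricted to coverage (VxGy)
rows.  Two clinical tables ship as CSV: a 9-row prostate SBRT protocol and
a 16-row head-and-neck SIB protocol.

## Cross-evaluation and statistics

Three mode combinations are produced per subject and constraint:
PlanAEvalA (automatic workflow), PlanMEvalM (clinical reference), and
PlanAEvalM (AS-optimised plan scored on true anatomy — the controlled
observation).  The fourth combination (MS plan on AS contours) answers no
clinical question and is deliberately never generated.  Per constraint,
paired t-tests compare PlanAEvalA vs PlanMEvalM and PlanAEvalA vs
PlanAEvalM across subjects: t = mean(d)/(sd(d)/√n) with sample sd, two-
sided p from Student t with n−1 df, significance at α = 0.05 with no
multiple-testing correction.  Zero-variance differences (which the
zero-perturbation control hits by construction) are flagged degenerate:
p = 1 when the common difference is 0, p = 0 otherwise, with no finite t.
Exceedance tables count subjects failing each (constraint, mode) cell,
including explicit zero rows, and reject incomplete or duplicated records.

## Discrepancy experiment

The sweep isolates the geometry/dose discordance: a spherical OAR (8 mm
radius) at surface gap d ∈ {10, 25, 40} mm from a 20 mm target, rigidly
translated by m ∈ {2, 4, 8} mm, h = 5 mm, 5 subjects per cell on the
default grid.  Because translation changes DSC but (to first order) not
with distance, while the local dose scale decays as 2^(−d/h), cells at
equal magnitude have near-identical DSC but mean-dose deltas that fall
roughly 8× per 15 mm of distance — the quantitative form of "geometric
metrics do not rank dosimetric impact".  All magnitudes are non-zero so the
monotone-decrease property can be asserted strictly; the magnitude-0
identity (all deltas exactly zero) is covered by unit tests.

## What the phantoms do and do not show

Passing tests demonstrate the correctness of the metrics, the DVH/
constraint machinery, the statistics, and the qualitative discordance
mechanism.  They do not validate any specific auto-segmentation product,
reproduce patient-specific dose distributions (the surrogate is explicitly
not a model of VMAT delivery — no fluence, beams or optimisation), or
calibrate constraint pass rates for real anatomy, whose shapes, densities
and inter-structure correlations the geometric phantoms do not attempt.

## Numerical and reproducibility choices

Exact (not approximate) nearest distances everywhere; all randomness flows
from explicit integer seeds through `numpy.random.default_rng`; per-subject
seeds are `cohort_seed + subject_index`, per-cell sweep seeds
`seed + 9973·cell`, and surface-noise streams are derived per (cohort,
subject, structure).  Study outputs are written with fixed column order and
no timestamps, so identical configs reproduce CSVs byte for byte.  Problem
sizes used throughout the test suite and acceptance script (96³ sweep, 64³
determinism study, ≤ 500-point Hausdorff oracles) were chosen as the
smallest sizes at which every asserted property is scale-stable.
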