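#!/usr/bin/env python
"""Geometric-vs-dosimetric discordance experiment.

Sweeps a single spherical OAR over distance-to-target × perturbation
magnitude at steep dose falloff (h = 5 mm).  The same geometric error
produces dose-endpoint errors that shrink exponentially with distance from
the target, so two structures with near-identical DSC can differ many-fold
in dosimetric impact.  Writes results/discrepancy_sweep.csv and the per-cell
summary results/discrepancy_cells.csv.
"""
from pathlib import Path

from contourdose import discrepancy_experiment
from contourdose.pipeline import sweep_cell_summary
from study_conditions import sweep

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cfg = sweep()
    df = discrepancy_experiment(cfg)
    cells = sweep_cell_summary(df)

    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    df.to_csv(out / "discrepancy_sweep.csv", index=False)
    cells.round(4).to_csv(out / "discrepancy_cells.csv", index=False)

    print(f"Sweep: distances {cfg.distances_mm} mm x magnitudes "
          f"{cfg.magnitudes_mm} mm, h = {cfg.falloff_mm} mm, "
          f"n = {cfg.n_per_cell}/cell\n")
    print("Per-cell mean DSC and mean |Δ mean dose| (PlanAEvalA − PlanAEvalM):")
    print(cells.round(3).to_string(index=False))

    # Discordance exhibit: nearly equal DSC, very different dose deltas.
    best = None
    for i in range(len(cells)):
        for j in range(len(cells)):
            a, b = cells.iloc[i], cells.iloc[j]
            if i != j and abs(a.dsc_mean - b.dsc_mean) < 0.05 \
                    and b.abs_d_mean_eval_gy > 0:
                ratio = a.abs_d_mean_eval_gy / b.abs_d_mean_eval_gy
                if best is None or ratio > best[0]:
                    best = (ratio, a, b)
    if best:
        ratio, a, b = best
        print(f"\nDiscordance exhibit: cells (d={a.distance_mm} mm, "
              f"m={a.magnitude_mm} mm) and (d={b.distance_mm} mm, "
              f"m={b.magnitude_mm} mm) have |ΔDSC| = "
              f"{abs(a.dsc_mean - b.dsc_mean):.3f} "
              f"but a {ratio:.0f}x difference in mean-dose delta —\n"
              "geometric agreement does not rank dosimetric impact.")


if __name__ == "__main__":
    main()
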