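#!/usr/bin/env python
"""Ground-truth recovery studies that validate the whole pipeline.

Runs (a) the simulation grid — cadence {44, 60, 68, 76} cycles/min ×
coordination offset {0, 15, 36, 60}° × marker noise {0, 1, 3} mm × 3 seeds
— recovering cadence, time lag, mean phase angle and signal correlation;
and (b) the association-stage study — 200 simulated cohorts of 15 at true
population R² 0.2 and 0.5. Tables go to results/.
"""

import sys
from pathlib import Path

import pandas as pd

from armcycle.studies import r2_recovery, recovery_grid

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
RESULTS = Path("results")


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    grid = recovery_grid(seed=SEED)
    grid.to_csv(RESULTS / "recovery_grid.tsv", sep="\t", index=False,
                float_format="%.6g")
    print(f"recovery grid ({len(grid)} runs):")
    print(f"  max |cadence error|   = {grid.cadence_error_cpm.abs().max():.3f} cycles/min")
    print(f"  max |time-lag error|  = {grid.time_lag_error_s.abs().max():.4f} s")
    print(f"  max |phase error|     = {grid.phase_error_deg.abs().max():.2f} deg")
    clean = grid[(grid.true_offset_deg == 0) & (grid.noise_sd_mm == 0)]
    print(f"  min correlation (zero offset, noiseless) = "
          f"{clean.signal_correlation.min():.4f}")

    rows = []
    for true_r2 in (0.2, 0.5):
        df = r2_recovery(true_r2, n_seeds=200, seed=SEED)
        rows.append({"true_r2": true_r2, "mean_estimate": df.r2.mean(),
                     "sd_estimate": df.r2.std(), "n_seeds": len(df)})
        print(f"association recovery: true R² {true_r2} -> "
              f"mean estimate {df.r2.mean():.3f} (SD {df.r2.std():.3f}, n=200)")
    pd.DataFrame(rows).to_csv(RESULTS / "r2_recovery.tsv", sep="\t",
                              index=False, float_format="%.4f")
    print(f"tables -> {RESULTS}/")


if __name__ == "__main__":
    main()
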