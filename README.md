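# armcycle

Movement-profile analysis for table-top arm cycling, built for upper-limb
rehabilitation research in neuromuscular disease (e.g. facioscapulohumeral
dystrophy, FSHD), where arm cranking is a candidate exercise mode and the
question is whether exercise intensity compromises movement quality.

The pipeline goes from five-marker sagittal motion-capture trajectories
(fifth metacarpal head, ulnar styloid, lateral humeral epicondyle,
acromion, lateral hip; 100 Hz) to:

* **joint angles** — shoulder flexion/extension measured from the trunk
  line (hip→acromion), arm alongside the body = 0°, flexion positive,
  extension negative; elbow flexion with full extension = 0° and full
  flexion → 180°;
* **inter-joint coordination** — time lag between elbow- and shoulder-angle
  peaks (positive = elbow leads), mean continuous relative phase
  φ(t) = φ_elbow − φ_shoulder from the analytic signal of per-cycle
  normalised series, and the lag-maximised normalised cross-correlation
  r = max_τ corr(θ_sh(t), θ_el(t+τ));
* **cycle metrics** — cadence from inter-peak spans, per-joint min/max/range
  of motion, maximum angular velocities, angle-angle (θ_sh vs θ_el) exports;
* **cohort statistics** — median (IQR) summaries, ordinary-least-squares R²
  for the function–strength–exertion associations, and a pairwise-complete
  Pearson matrix of the strength battery.

Because motion-capture data of this kind is rarely shareable, the package
includes a synthetic generator: a planar two-link arm (elbow-down inverse
kinematics) turning a crank, with configurable cadence profile,
elbow–shoulder phase offset, Gaussian marker noise and Poisson marker
drop-out gaps — every downstream stage is validated by recovering the
generator's known ground truth.

## Worked example

```python
from armcycle import (SimulationConfig, simulate_crank_cycling,
                      compute_joint_angles, fill_gaps, lowpass_filter,
                      angular_velocity, build_movement_profile)

cfg = SimulationConfig(cadence_profile=60.0, duration=30.0,
                       elbow_shoulder_phase_offset=36.0)
traj = simulate_crank_cycling(cfg)          # 3000 frames, 5 markers
angles = lowpass_filter(fill_gaps(compute_joint_angles(traj)))
profile = build_movement_profile(angles, angular_velocity(angles))
print(f"cadence {profile.cadence_cpm:.1f} cycles/min, "
      f"time lag {profile.time_lag_s:+.3f} s, "
      f"phase {profile.mean_phase_angle_deg:.1f} deg, "
      f"r = {profile.signal_correlation:.3f}")
```

prints

```
cadence 60.0 cycles/min, time lag +0.101 s, phase 35.7 deg, r = 0.988
```

i.e. the configured 36° elbow lead is recovered as a +0.101 s time lag
(36/360 of the 1 s cycle; positive = elbow peaks precede shoulder peaks)
and a 35.7° mean relative phase, with strongly correlated joint waveforms.

## Command line and analysis scripts

`armcycle full --out-dir run --seed 1` simulates a 15-participant demo
cohort (five 2-minute efforts, 30 s rests; three participants with heavy
marker drop-out), analyses 25 s windows of efforts one and five, and writes
feature tables, median (IQR) summaries, association fits and a run
manifest. `simulate` / `analyze` / `summarize` run the stages separately on
the same on-disk artifacts.

The numbered scripts under `analysis/` tell the same story stepwise:

1. `01_simulate_cohort.py` — generate the demo cohort (data under
   `scratch/`, ground-truth table under `results/`);
2. `02_movement_profiles.py` — joint angles → windows → feature table
   (the three heavy-drop-out recordings are skipped: 12 of 15 profiled);
3. `03_cohort_statistics.py` — median (IQR) tables, R² associations,
   strength correlation matrix;
4. `04_parameter_recovery.py` — the validation grids (cadence/offset/noise
   recovery and R² recovery at cohort size 15).

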