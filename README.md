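# nucleotrack

Mobility analysis of nucleosome trajectories from high-speed atomic force
microscopy (HS-AFM) videos.

HS-AFM can film individual nucleosomes — the DNA–histone particles that
package chromatin — moving on a mica surface at about one frame per second.
After particle detection and linking (done upstream, e.g. in ImageJ/MATLAB
trackers), the result is a table of per-frame particle coordinates. This
package turns those coordinate tables into defensible mobility statistics
for researchers studying chromatin dynamics in vitro:

- **QC filtering**: keep 10–60-point tracks (20–120 s at the effective 2 s
  frame interval), reject tracks with any single step above 24 nm (likely
  linking errors), and split off near-immobile "stuck" tracks (average
  R-step < 1 nm and spatial range < 8 nm) as a surface-adhesion control.
- **Per-video drift correction** from the mean inter-frame displacement of
  co-visible particles (no fiducials required).
- **MSD and diffusion constants**: time-averaged MSD per trajectory and the
  two-point estimator D = (MSD(2Δt) − MSD(Δt)) / (2·dim·Δt), whose mean
  across trajectories equals the estimate from the averaged MSD curve
  exactly.
- **Two-state decomposition**: pooled per-axis step displacements fit with
  one- and two-component zero-mean Gaussian mixtures by EM; component
  widths map to diffusion constants via D = σ²/(2Δt), separating a slow
  (paused, D₁) from a fast (mobile, D₂) population, with BIC model
  selection and an F-test comparing the slow component against the stuck
  population.
- **Tip-artifact diagnostics**: chi-square uniformity of turning angles,
  paired t-test of x- vs y-axis diffusion (fast- vs slow-scan axis), and a
  step-size-over-time regression — the symmetry checks that rule out the
  scanning tip dragging particles.
- **A seeded synthetic generator** (two-state switching diffusion,
  confinement, shared drift, localization noise, stuck particles) with
  ground truth, so every stage is testable without any recordings.

See `docs/methods.md` for the model, estimator conventions, and
limitations.

## Worked example

Simulate a condition with known ground truth (slow state D₁ = 0.2 nm²/s at
occupancy 0.4, fast state D₂ = 4.0 nm²/s, 10% stuck particles), then run
each stage:

```sh
nucleotrack simulate --out traj.csv --n-videos 3 --n-particles 60 \
    --seed 7 --stuck-fraction 0.1 --condition demo
# wrote 180 trajectories to traj.csv

nucleotrack qc traj.csv --out qc.csv
# 175/180 trajectories accepted; report: qc.csv

nucleotrack metrics traj.csv --out-prefix demo --condition demo
# n=175 trajectories, D = 2.23 ± 0.098 nm²/s

nucleotrack mixture traj.csv --out mix.csv --seed 7
# x-axis: chosen k=2 (ΔBIC=916.5)
# y-axis: chosen k=2 (ΔBIC=923.0)

nucleotrack diagnose traj.csv --out diag.csv
# angle_uniformity: p=8e-08 [BIAS]
# axis_bias: p=0.913 [ok]
# stepsize_vs_time: p=0.00568 [BIAS]
```

What the numbers mean:

- The condition-average diffusion constant 2.23 ± 0.10 nm²/s sits between
  the two true state constants, weighted by occupancy (0.4·0.2 + 0.6·4.0 =
  2.48 nm²/s before sampling and QC effects): a single D hides the two
  states.
- The mixture stage recovers them: on the x axis the selected
  two-component fit has weight₁ = 0.45 with D₁ = 0.33 and D₂ = 3.9 nm²/s.
  D₁ exceeds the true 0.2 by the localization-noise floor σ_loc²/Δt =
  0.5²/2 ≈ 0.13 nm²/s, as expected; the huge ΔBIC ≈ 920 firmly rejects a
  single Gaussian.
- Diagnostics: the axis test is clean (p = 0.91, no tip-direction bias).
  The angle test flags the backward-turning bias that localization noise
  genuinely induces, and the step-vs-time test picks up the small selection
  slope from pooling QC-filtered tracks of unequal length — both are real
  properties of this dataset, not tip artifacts; see `docs/methods.md`.

The same stages run end to end from a YAML config (`nucleotrack run
config.yaml`), producing per-trajectory metrics, a per-condition summary
table, MSD curves, mixture fits, stuck-population F-tests, diagnostics, and
a run log with the seed and every threshold. Real data enters through
`files` mode: a manifest lists coordinate CSVs (any column naming, any
coordinate unit) with their condition labels. `nucleotrack compare`
concatenates condition summaries for dose–response-style tables.

Library use mirrors the CLI:

```python
import nucleotrack as nt

params = nt.MotionParams(d1=0.2, d2=4.0, stuck_fraction=0.1)
video, truth = nt.simulate_video(params, n_particles=60, seed=7)
video = nt.apply_drift_correction(video, nt.estimate_drift(video))
qc = nt.qc_filter(video)
summary = nt.condition_summary(qc.accepted, condition="demo")
```

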