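# Methods

`nucleotrack` quantifies the lateral mobility of nucleosomes adsorbed on a
mica surface and imaged by high-speed atomic force microscopy (HS-AFM).
The raw observable is a set of tracked particle trajectories — per-frame
(x, y) positions in nanometers at an effective 2 s frame interval — and the
pipeline turns them into mobility statistics: step-size distributions, MSD
curves, diffusion constants, a two-state decomposition of step
displacements, and tip-artifact diagnostics.

## Motion model

A tracked nucleosome is modeled as a two-state diffusing particle. In state
s ∈ {1, 2} each per-axis single-frame displacement is zero-mean Gaussian
with variance 2·D_s·Δt, with D_1 ≤ D_2 by convention (state 1 = slow or
paused, state 2 = mobile). Switching between states is a two-rate Markov
chain with rates k₁₂ and k₂₁ (s⁻¹), giving stationary slow-state occupancy
k₂₁/(k₁₂+k₂₁). The observed position adds three layers on top of the
intrinsic path:

1. **Confinement** (optional): the intrinsic path is reflected at a
   circular boundary of radius R centered on the trajectory start. The
   stationary law of reflected Brownian motion in a disc is uniform, so the
   time-averaged MSD plateaus at E|p−q|² = R² for independent uniform
   points. Reflection is applied radially (distance d maps to 2R−d), which
   approximates true specular reflection when single-frame steps are small
   relative to R; simulations meant to probe the plateau quantitatively
   should keep √(4DΔt) ≲ R/3.
2. **Drift**: a linear stage drift (v_x, v_y) nm/s shared by every particle
   of a video, added cumulatively per frame.
3. **Localization noise**: isotropic white Gaussian noise (sd
   `loc_noise_sd`, per axis per frame). No noise model is implied by the
   imaging physics here; white isotropic noise is the standard SPT default.

A configurable fraction of particles is "stuck": their intrinsic motion is
zero and only localization noise remains. State switching is evaluated once
per frame with probability 1−exp(−k·Δt); sub-frame switching is
unidentifiable at a 2 s interval and is not modeled.

### Generator defaults

| parameter | default | why |
|---|---|---|
| `d1`, `d2` | 0.2, 4.0 nm²/s | slow/fast states of a mobile nucleosome-array population, ~20× contrast |
| `k12`, `k21` | 0.15, 0.10 s⁻¹ | stationary slow-state occupancy 0.4, switching resolvable at 2 s frames |
| `frame_interval` | 2.0 s | effective rate after every-other-frame decimation of a 1 Hz scan |
| `n_frames_range` | (10, 60) | the retained trajectory-duration window (20–120 s) |
| `loc_noise_sd` | 0.5 nm | sub-nanometer localization, well below typical step sizes |
| `confinement_radius` | none | confinement is opt-in; the plateau study uses R = 15 nm |
| `stuck_fraction` | 0.0 | stuck particles are opt-in for QC/stuck-analysis studies |

## Preprocessing

**Decimation.** The raster tip alternates top-to-bottom and bottom-to-top
scans, so consecutive raw frames sample the surface at unequal phase;
analysis keeps every other frame (configurable parity), renumbers frames
from 0, and doubles the frame interval. Decimation is not idempotent and
must run exactly once, on data at the raw scan rate.

**Drift correction.** Per video, the drift increment between consecutive
observed frames is the mean displacement of all particles present in both
frames; intrinsic Brownian displacements average toward zero across
particles while the shared drift survives. The cumulative sum (anchored at
zero on the first frame) is subtracted from every coordinate. Frame pairs
sharing no particle contribute a zero increment. The estimator's error on
the cumulative drift vector scales as √((2DΔt + 2σ_loc²)·n_frames /
n_particles): drift recovery is a dense-video regime, and the validation
study uses 200 particles accordingly. Re-estimating drift on a corrected
video returns zero by construction (the same particle sets enter both
estimates), so residual drift checks the plumbing, not a statistical claim.

**Trajectory QC.** Applied per trajectory in a fixed order so results are
reproducible: (a) fewer than 10 points → rejected as too short (20 s
minimum at 2 s/frame); (b) more than 60 points → truncated to the first 60
(120 s analysis window) and retained — truncation rather than exclusion
avoids biasing against slow, long-lived tracks; (c) any single planar step
above 24 nm (twice the nucleosome width) → rejected as a likely linking
error; (d) average R-step below 1 nm AND spatial extent below 8 nm →
"stuck", kept as a separate surface-adhesion control population. The two
stuck conditions combine with AND by default (OR is a config option).
"Spatial extent" is the maximum pairwise distance between positions within
the (possibly truncated) trajectory. All thresholds are configurable.

## Mobility statistics

The **R-step** is the planar single-frame displacement √(Δx²+Δy²).
**Turning angles** are the signed angle from one step vector to the next,
in (−180°, 180°]. The **MSD** is time-averaged over all overlapping pairs,
MSD(kΔt) = meanᵢ |r_{i+k} − r_i|²; overlapping averaging maximizes pairs at
the small lags the estimator uses. The **diffusion constant** is the
two-point slope of the first two MSD points,

    D = (MSD(2Δt) − MSD(Δt)) / (2·dim·Δt),

not a regression: the two-point form cancels the constant MSD offset
produced by static localization noise, and it is linear in the MSD values,
so the mean of per-trajectory estimates equals the estimate from the
averaged MSD curve exactly (asserted to 1e-9 relative tolerance in the
tests). Per-trajectory estimates can be negative on noisy tracks and are
retained unclipped in condition averages; clipping would bias the mean
upward. Per-axis D uses the same estimator on one coordinate with dim = 1.
Condition summaries report mean ± SE across trajectories (SE undefined at
n = 1); whether an across-video SE would be preferable is a design choice —
across-trajectory SE is what is implemented and labeled.

Because the rejection rule is phrased in nm while step variability is also
of interest in nm², the per-trajectory table reports both the spatial
extent (nm, max pairwise distance) and the R-step variance (nm², ddof 1);
neither is collapsed into the other.

## Two-state mixture decomposition

Pooled per-axis step displacements of a drift-corrected condition are fit
by maximum likelihood with k = 1 and k = 2 zero-mean Gaussian components;
x and y are fit separately. Component means are fixed at zero: symmetric
displacement histograms cannot identify free means, and zero means make the
width-to-mobility map exact, D_i = σ_i²/(2Δt). With zero means the EM
updates reduce to responsibility-weighted second moments. EM runs from 10
seeded initializations (quantile splits of |x| at randomized split points;
the first split is the median), keeps the best likelihood, and stops when
the log-likelihood gain falls below 1e-8 or at 500 iterations. A component
collapsing below σ = 0.05 nm triggers a flagged refit with that floor.

Model selection prefers two components only when ΔBIC = BIC₁ − BIC₂ > 10,
a deliberately conservative threshold (BIC uses 2k−1 free parameters);
ties go to one component, and raw likelihoods are always reported so any
other criterion can be applied downstream. Note the implied D of a fitted
component includes the localization-noise contribution σ_loc²/Δt — on
synthetic data with noise, D̂₁ recovers D₁ + σ_loc²/Δt, which matters when
D₁ is small.

The stuck population gets the same treatment with k = 1 per axis per
video; for pure localization noise, differencing doubles the variance, so
the expected effective constant is σ_loc²/Δt. A two-sided variance-ratio
F-test compares the stuck width against the σ₁² of the selected
two-component fit, with larger-over-smaller F and (n−1, n−1) degrees of
freedom; since a mixture component has no integer count, the slow
component's df uses the rounded effective count weight₁ × n (a convention,
stated as such).

A descriptive per-step state flagger labels each step by maximum posterior
under the selected two-component fit (both axis displacements scored
against isotropic components; exact ties go to state 1) and counts label
changes per trajectory. No temporal smoothing is applied — this mirrors a
visual switching check, and raw posterior labels overstate true switching
when the components overlap, so the counts are a screening aid, not rate
estimates.

## Tip-artifact diagnostics

A raster tip that drags particles would break statistical symmetries. Three
formal tests make the checks machine-decidable while the underlying tables
are emitted for visual confirmation:

- **Angle uniformity**: chi-square goodness of fit of turning angles binned
  into 24 × 15° bins against uniformity, with the circular mean resultant
  length as effect size. Caveat: localization noise anticorrelates
  successive measured steps and genuinely enriches angles near ±180° — the
  test then correctly rejects uniformity for a reason other than tip bias.
  Null calibration therefore uses noise-free Brownian ensembles; on real
  data a backward-peaked (rather than scan-axis-aligned) angle histogram
  points to noise, not the tip.
- **Axis bias**: paired two-sided t-test of per-trajectory D_x − D_y
  (fast-scan vs slow-scan axis). Identical axes report p = 1 rather than an
  error.
- **Step size vs time**: pooled least-squares regression of R-step on time
  since video start; a nonzero slope indicates mobility change during
  imaging (progressive adhesion, tip wear). Pooling across tracks of
  unequal length after max-step QC can induce a small selection slope
  (long surviving tracks are slower); calibration uses fixed-length
  ensembles without QC.

All three are calibrated by simulation: at nominal α = 0.05 the null
rejection rates over 500 replicates fall in [0.02, 0.08], and each test
detects its designed alternative (uncorrected 1.5 nm/s drift; D_x = 2·D_y;
step scale halving over the video) with power above 0.8 (100 replicates).
The thresholds for declaring bias are pipeline conventions; the underlying
decision in the field is usually visual.

## What the generator does and does not emulate

It reproduces the statistical structure the analysis assumes: two-state
Gaussian steps, stochastic switching, shared linear drift, circular
confinement, white localization noise, stuck particles, and the retained
duration range at a 2 s interval. It does not emulate particle detection or
linking errors (mislinks, gaps, identity swaps), nonlinear or rotational
drift, anisotropic or correlated noise, particle interactions or crowding,
nucleosomes leaving the surface, or any image-domain effect. Passing the
validation studies therefore shows the estimators are correct under the
model's assumptions, not that the assumptions hold for any particular
recording; the diagnostics module exists to probe the latter.

## Numerical conventions and degenerate inputs

- Frames are 0-based; times derive as frame × Δt when absent. Coordinates
  are nm; a per-file unit factor converts other units on ingest.
- MSD(0) = 0 by definition and is not stored; curves start at lag Δt.
- Angles at exactly −180° map to +180°.
- Duplicate (trajectory, frame) rows, non-finite coordinates, and
  non-uniform frame gaps are hard errors, not warnings, because every
  downstream statistic assumes a uniform grid.
- Zero-variance inputs: stationary trajectories give MSD ≡ 0; constant step
  sizes give slope 0 with p = 1; a zero-width stuck population is flagged
  as degenerate rather than raising.
- Validation studies use 100–500 trajectories (or 2×10⁴ pooled steps, 500
  test replicates); these sizes put Monte-Carlo error comfortably below the
  asserted tolerances while keeping a full run around one to two minutes.

## Known limitations

- The drift estimator assumes many co-visible particles; with few mobile
  particles it absorbs real motion into "drift". It is undefined for videos
  where no particle spans consecutive frames.
- The mixture model assumes isotropic, stationary states; it cannot
  distinguish a continuum of mobilities from two discrete states (a
  continuum also yields a better two-component than one-component fit).
- The radial reflection scheme biases the confined stationary law inward
  when steps are comparable to R (about 5% at √(4DΔt) ≈ R/2).
- Truncating >60-point tracks keeps slow particles in the sample but
  discards late-time information; the alternative (exclusion) is not
  offered because it couples acceptance to mobility.
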