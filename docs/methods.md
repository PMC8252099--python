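# Methods

## The acquisition being modeled

One image per heartbeat is read out with a single-shot spoiled
multi-gradient-echo train (36 excitations, flip 20°, TR 10.3 ms, 5 echoes
per excitation at TE 1.0–8.5 ms, centric k-space order). Seven contrast
preparations are chained in a fixed order:

| # | preparation | TS (ms) | T2p (ms) | rest before |
|---|-------------|---------|----------|-------------|
| 1 | none        | ∞       | 0        | 4 s         |
| 2 | T2-prep     | ∞       | 25       | 4 s         |
| 3 | T2-prep     | ∞       | 50       | 4 s         |
| 4 | saturation  | TSmin = 7 | 0      | —           |
| 5 | saturation  | TSmax   | 0        | —           |
| 6 | saturation  | TSmin = 7 | 0      | —           |
| 7 | saturation  | TSmax   | 0        | —           |

TSmax defaults to `RR − 400 ms` (600 ms at 60 bpm): the saturation pulse of
the long-delay images plays at the start of systole and the readout sits in
end-diastole. TS is measured from the saturation pulse to the k-space-center
excitation, which under centric ordering is the first excitation of the
train. The rest periods allow (approximate) full longitudinal recovery
before the unprepared and T2-prepared images, which is what lets a single
amplitude `A` serve all seven contrasts in the fit.

Echo times default to 5 linear steps over [1.0, 8.5] ms; the spacing is
configurable since only the range is prescribed by the sequence parameters.

## Bloch engine

RF pulses are instantaneous rotation matrices at 100 % efficiency; between
pulse events the magnetization follows the exact closed-form relaxation
solution (`Mz → Mz e^{−dt/T1} + 1 − e^{−dt/T1}`, `Mxy → Mxy e^{−dt/T2}`).
Because the pulses are instantaneous, the closed form is the exact limit of
arbitrarily fine time stepping — no integration error enters.

* **Saturation** is a WET composite modeled as ideal Mz destruction with a
  configurable efficiency (fraction of Mz destroyed; transverse crushed).
* **T2 preparation** is 90° flip-down, 4 evenly spaced ideal 180° refocusing
  pulses with MLEV phase cycling (y, y, −y, −y), and a 270° flip-up,
  followed by a crusher. With ideal pulses the module stores
  `Mz e^{−d/T2}` to within the small T1 recovery over the interval
  (< 0.5 % for d ≤ 60 ms, T2 ≥ 20 ms). The *efficiency* knob scales the 90°
  flip-down and the 90° component of the 270° (= 180° + 90°) flip-up —
  a B1-like shortfall of the tip pulses while the composite refocusing train
  stays calibrated. This is the only scaling convention we found that
  reproduces the characteristic *monotone underestimation* of fitted T2
  (growing with true T2) over efficiencies 1.0 → 0.7; scaling the full 270°
  literally folds the stored magnetization through zero at low efficiency
  (the magnitude fit then inverts the error), and scaling the flip-up as an
  effective −90° produces overestimation instead.
* **Readout**: each excitation tips `sin(20°)·Mz` into the transverse plane
  and is spoiled within its TR; the reported magnitudes come from the
  k-space-center excitation as `|sin(flip)·Mz| · e^{−TE/T2*}`. The whole
  36-excitation train is simulated so the post-readout longitudinal state is
  correct for subsequent contrasts. Off-resonance is not modeled; T2\*
  enters only through the analytic echo-decay factor, exactly as the signal
  model treats it.
* **Scan state**: `simulate_acquisition` plays one unrecorded conditioning
  cycle of the protocol before recording (`n_dummy_cycles=1`). A running
  examination never starts from cold thermal equilibrium (scouts, shimming
  and navigator training precede the mapping scan), and the periodic state
  makes the incomplete-recovery deviations well-defined independent of scan
  history. A cold start would give the first, unprepared contrast full
  recovery while the T2-prepared contrasts are under-recovered,
  inflating the apparent T2 error several-fold. Set `n_dummy_cycles=0` to
  start from an explicit initial state.

## Joint 5-parameter fit

The model is `S = [A(1 − e^{−TS/T1}) e^{−T2p/T2} + B] e^{−TE/T2*}` with
`TS = ∞` evaluated symbolically as a recovery factor of exactly 1. `B`
absorbs the residual signal at short saturation delays. Magnitude data are
fitted without Rician bias correction; instead, trailing echoes whose
magnitude falls below `k·σ` (default k = 2) are discarded per contrast
(suffix-only rule, never below 3 retained echoes).

Fitting is bounded trust-region least squares (scipy `least_squares`,
analytic Jacobian, ftol = xtol = 1e−12) with bounds T1 ∈ [100, 5000],
T2 ∈ [5, 300], T2\* ∈ [1, 300] ms. Initialization is a chain of closed-form
sub-fits: log-linear T2\* from the unprepared echoes, per-contrast TE = 0
amplitudes, `B` from the shortest-TS contrasts, two-point T2 from the
T2-weighted amplitudes, saturation-recovery T1 from the longest TS. Up to 5
jittered restarts (seeded log-normal perturbations, reproducible) run on
non-convergence; degenerate (empty/constant) series raise instead of
returning a fit.

## Precision (SD) maps

The per-voxel covariance is `σ²(JᵀJ)⁻¹` with the Jacobian at the optimum;
σ² is the dof-corrected residual variance (`dof = N − 5`) unless an external
noise SD is supplied, which then takes precedence. Each parameter's SD is
the square root of *its own* diagonal entry — summing the diagonal would mix
units (ms² with squared amplitudes) and is not meaningful. Validation
compares the mean Hessian SD across noisy fits with the Monte-Carlo scatter
of the fitted parameters (1000 Rician replicates at SNR 20): agreement is
within 15 % for T1, T2, and T2\*. The comparison deliberately uses the
Hessian SDs *of the noisy fits* (that is what an SD map contains in
practice); the noise-free-fit CRLB understates the scatter because the
Rician floor biases the fits, most visibly T1.

## Digital phantoms and noise

The tube phantom places circular tubes on a grid with log-uniformly sampled
relaxation times (defaults cover T1 1200–1700, T2 20–70, T2\* 5–60 ms); the
ring phantom is an annular myocardium (defaults at reported in vivo 3 T
values: 1573 / 33.2 / 25.3 ms) around a blood pool, with a recorded
RV-insertion angle for AHA segmentation. Signals are simulated once per
compartment and broadcast to voxels (valid because the signal depends only
on the tissue parameters), so a full 35-volume dataset costs 2–3 Bloch runs.

Rician noise is `|(S + n₁) + i n₂|` with independent zero-mean Gaussians of
SD `σ = reference / SNR`, the reference being the unprepared contrast's
first-echo signal. What the generator does *not* emulate: partial-volume
mixing, coil-sensitivity or reconstruction (GRAPPA) noise correlations,
susceptibility-induced T2\* artifacts, through-plane motion, or fat signal.
Passing tests therefore demonstrate correctness of the models and fits under
ideal magnitude imaging, not robustness to those in vivo effects.

## Confounder study

`run_confounder_study` sweeps one factor while holding the rest at baseline
(rest 10 s, noise-free, 60 bpm, efficiency 1.0 — the baseline row is
bit-identical to the accuracy sweep):

* **rest period** 1–10 s: only T2 is visibly affected; at 4 s the relative
  T2 deviation is 0.26 % for T2 = 100 ms (T1 = 1600 ms) and < 0.2 % within
  the in vivo range.
* **noise** SNR 5–30, Monte Carlo (default 1000 replicates): reports bias,
  SD and RMSE per parameter; T2\* degrades fastest at low SNR.
* **heart rate** 50–140 bpm (TSmax auto-adjusted): noise-free deviations
  change by < 0.1 %.
* **T2-prep efficiency** 1.0–0.7: strong monotone T2 underestimation,
  larger for longer true T2. Note that for short T2 (≲ 20 ms) at
  efficiency ≤ 0.7 the fitted T2 saturates at the search bound, so relative
  errors no longer order by tissue there.

The default tissue set varies one parameter at a time around
(1450, 45, 32.5) ms, mirroring the per-parameter panels of the simulation
study; sweep grids and tissues are arguments.

## Registration

Rigid (dx, dy, θ) alignment maximizes 32-bin joint-histogram mutual
information inside the region of interest: exhaustive coarse search
(1 px / 1°), then per-axis golden-section refinement bracketed to one coarse
step. Both images are Gaussian-smoothed (σ = 1 px) for scoring only: on
near-piecewise-constant phantom images, raw-image MI — with either intensity
or partial-volume interpolation — has spurious extrema pinned to the integer
pixel grid (we verified the true subpixel optimum can be a local *minimum*
of the raw-MI profile), while the smoothed profile is unimodal at the true
alignment. Recovery on the test phantoms is ≤ 0.05 px / 0.01° for
corruptions up to ±5 px / ±5°, and ≤ 1 px at SNR 20. Free bounded Powell
refinement was rejected: on the rugged raw surface it can walk away from the
coarse optimum.

Note the degenerate case: a rotationally symmetric phantom (the plain ring)
cannot identify rotation at all; registration tests use the tube grid.

## Regional statistics

AHA mid-ventricular segmentation divides the myocardial mask into six 60°
wedges starting at the anterior RV-insertion angle, ordered anterior →
anteroseptal → inferoseptal → inferior → inferolateral → anterolateral.
`segment_stats` reports within-segment mean and SD of each parameter map and
the mean of the corresponding SD map. `bland_altman` returns the bias, the
95 % limits of agreement (bias ± 1.96 SD of differences), and a two-sided
paired t-test p-value Bonferroni-corrected across the three parameters.

## Navigator gating model

`simulate_gating` implements the accept–reject scheme: unprepared and
saturation-prepared images are re-attempted on the next beat after a
rejection; the T2 preparation is only played on an accepted navigator, so
rejections before a T2-prepared image extend its *effective* rest period
rather than repeating it (the extended rest can be fed back into the Bloch
simulation through `rest_override`). At 100 % acceptance the scan time is
the closed-form minimum (3 rest periods + 7 beats = 19 s at 60 bpm, 4 s
rest). The RR interval is fixed — no arrhythmia or ECG waveform modeling.

## Known limitations

* The reference bSSFP readouts of the single-parameter methods are not
  separately modeled; the reference *fits* operate on coordinate/signal
  arrays from any source.
* Saturation-recovery T1 mapping has an intrinsically small dynamic range;
  at clinically realistic SNR the Rician floor biases the joint T1 estimate
  upward by several percent (visible in the Monte-Carlo sweeps).
* With the clinical 4 s rest the joint fit's full-recovery assumption reads
  T1 a few percent low in the periodic state; the simulation baseline uses
  10 s rest to isolate other confounders.
* The motion generator is 2-D rigid with linear interpolation; non-rigid
  deformation is out of scope.
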