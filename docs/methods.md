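# Methods

## The model

`csflow` simulates the time-of-flight (inflow) signal of a multislice
spoiled gradient-echo acquisition from a prescribed, time-varying fluid
velocity, and inverts measured inflow signals back to velocity with a
network trained purely on those simulations.

### Spin signal

Fluid is represented by point spin ensembles. An ensemble that has received
`n` RF pulses with inter-pulse intervals Δt₁..Δt₍ₙ₋₁₎ carries longitudinal
magnetization given by the spoiled-GRE recursion

    Mz ← Mz·cosθ·e^(−Δt/T1) + M_eq·(1 − e^(−Δt/T1)),   Mz(0) = M_eq,

and emits a transverse signal `Mz·sinθ·e^(−TE/T2)` at each pulse. The
closed-form expansion of this recursion (a sum of recovery increments, each
attenuated by the subsequent flips and relaxation decays) is implemented in
`mr_signal.transverse_signal`; the recursion itself is retained as the
per-spin incremental update used by the simulator (O(1) per pulse per spin)
and, independently re-implemented, as the oracle in the test suite. Perfect
spoiling is assumed: TE enters only as the constant factor e^(−TE/T2), and
no transverse coherence survives between pulses. For constant spacing Δt the
recursion has the familiar fixed point

    M_ss = M_eq·sinθ·e^(−TE/T2)·(1 − E)/(1 − E·cosθ),  E = e^(−Δt/T1),

which with Δt = TR is the stationary-tissue baseline; the **inflow
contrast** reported by the simulator is the transverse signal minus this
baseline. Spins present at t = 0 start at equilibrium; the resulting
initial transient is handled by discarding the first 40 TR samples wherever
simulated signals are compared with anything (matching the trim applied to
measured fMRI series).

Defaults are the validation protocol: TR 0.504 s, TE 30 ms, flip angle 45°,
slice thickness W = 0.25 cm, 21 slices, multiband factor 3, and CSF-like
relaxation T1 = 4 s, T2 = 1.5 s.

### Excitation schedule

The `n_slices/MB` excitation events of each TR are spread uniformly over the
TR; event *j* excites the multiband group `{k, k+n/MB, k+2n/MB, …}`
(arithmetic-stride SMS convention). The within-TR group order is
configurable (`sequential`, `interleaved` = even groups then odd, or an
explicit permutation; default `interleaved`) because vendors differ and the
order is rarely reported; the bottom three slices fall in different groups,
so simulations should record the order used. Excitation is instantaneous
and its spatial profile is a step spanning exactly one slice: a spin at
position x receives the pulse iff `kW ≤ x < (k+1)W` for an excited slice k
(half-open, so boundary positions are never double-counted).

### Kinematics

Motion is 1D plug flow along the slice normal. The entrance velocity V(t)
(cm/s, positive into the volume, defined at the bottom of slice 1, x = 0)
is rescaled along the compartment by incompressibility:

    dx/dt = F(x)·V(t),   F(x) = A_slc1 / A(x),

with A(x) the cross-sectional area–depth curve and A_slc1 = A(0). Outside
the tabulated extent of A (and wherever A falls below it) the area is
clamped to a floor of 0.05 cm² so F is defined everywhere spins travel.

The ODE is separable: in the fluid-volume coordinate
G(x) = ∫₀ˣ A_clamped/A_slc1 dx′ every trajectory satisfies
G(x(t)) = G(x0) + ∫₀ᵗ V dτ. The simulator exploits this: it tabulates G
once (trapezoid on a 0.005 cm grid including the curve's breakpoints, exact
linear extension outside the tabulated span), after which propagating all
spins to an event time costs one interpolation, and slice occupancy reduces
to binary searches over the sorted seed coordinates. This path is exact (up
to the G tabulation) and is what makes large training sets computable; a
generic `solve_ivp` route (RK45, rtol 1e−6, atol 1e−8, dense output) is
kept for arbitrary trajectory queries and is cross-checked against the
exact propagator and closed-form solutions in the tests.

Seeding is uniform in G by default — each ensemble represents an equal
fluid volume, which makes the unweighted within-slice average correct when
the compartment is non-uniform; for a straight tube this is ordinary
uniform spacing. Default spacing is W/100 (API), with coarser module-level
defaults where noted below; margins are computed exactly from the extrema
of ∫V dτ plus one slice width, so no spin can be missing from a slice.

### Per-slice signals

At each slice's own excitation instant, the sample for that TR is the mean
inflow contrast over the ensembles inside the slice, including the pulse
just received — one sample per TR per slice, with slices mutually offset
within the TR by the schedule (`resampled_to_common_grid` interpolates to a
common time base when needed). Spins above the reported slices keep
receiving pulses from whatever slice interval they occupy; beyond the top
of the volume they receive none, which is what produces the outflow-memory
effect (fluid recovering below slice 1 during outflow raises subsequent
inflow peaks).

## Simulation experiments

* **Decay rate.** For steady plug flow the per-slice mean amplitudes decay
  roughly exponentially with slice index; `decay_rate` fits
  `S(k) = e^(−Dk)` by log-domain least squares anchored at the normalized
  first slice. `run_sweep` tabulates D and first-slice amplitude over (V,
  TR, W) grids. D decreases strictly with V/V_crit (V_crit = W/TR) on the
  subcritical branch of every (TR, W) series; above V_crit the slices
  saturate in sequence (slice k at k·V_crit) and D plateaus near zero with
  small non-monotone wiggles, so monotonicity is only asserted below
  V_crit. The sweep reports the first-slice amplitude both as raw inflow
  contrast and relative to the stationary steady-state signal of the TR;
  the relative (percent-signal-change) measure is the one that decreases
  monotonically with TR — the absolute contrast at fixed V peaks at
  intermediate TR because the saturated baseline collapses faster than the
  inflowing spins' signal at short TR.
* **Frequency attenuation.** A sum of equal-amplitude sinusoids (0.2–1.2 Hz,
  0.2 cm/s each, zero offset) is simulated and Welch PSDs of input and
  first-slice signal are compared. Because the slice signal is sampled once
  per TR, this experiment defaults to a TR 0.25 s variant of the protocol so
  that all six frequencies lie below the slice-sampling Nyquist rate
  1/(2·TR); signal peaks fall monotonically with frequency while input
  peaks are flat.
* **Demo waveforms.** `unidirectional`, `bidirectional`, `damped`, `chirp`
  generators with configurable amplitude/frequency.

## Synthetic training data

`training_sampler` draws velocities as sums of 100 sinusoids on the fixed
0.01–1.00 Hz grid with amplitudes uniform between bound curves
B_L = 0.6·g, B_U = 1.4·g + 0.01 (cm/s), where g is the sum of three
Gaussian bumps mimicking measured CSF spectra: slow (α ≤ 0.1 cm/s,
μ ∈ [0.035, 0.065] Hz, σ 0.015), respiratory (α ≤ 1.0, μ ∈ [0.1, 0.3],
σ 0.002, harmonics at 2μ and 3μ with weights 1/3 and 1/6), cardiac
(α ≤ 0.2, μ ∈ [0.8, 1.0], σ 0.0075). Offsets v0 ~ U(−0.1, 0.1) cm/s; time
shifts uniform within each period. 25% of samples are **phantom mode**: a
single bump (σ 0.006, μ ∈ {0.05, 0.1, 0.2} Hz, α ≤ 1.2), v0 = 0, and a
straight tube — pump-driven oscillatory flow. Within human-mode samples a
further 25% pin the breathing frequency to 0.167 Hz (the paced-breathing
rate); the two 25% draws are nested (the pinning applies after the
phantom/human split) since their order is otherwise unspecified.

Human-mode anatomy comes from a library of synthetic ventricle-like curves
(Gaussian bump, A_min ∈ [0.1, 0.4] cm², A_peak ∈ [0.8, 2.0] cm²,
σ ∈ [0.5, 1.5] cm over an 8 cm span) standing in for participant-extracted
fourth-ventricle curves, which are not published as data; each sample
shifts the slice-1 origin within ±1 cm of the widest point and scales areas
by U(0.8, 1.2) (the scale cancels in F but changes the network's area
channel). Phantom-mode anatomy is a straight 0.5 cm² tube.

Each sample simulates 240 TRs at W/25 seeding (≈25 ensembles per slice-1
width — the added measurement noise dominates the residual discretization
ripple well before this density), drops the 40-TR transient, rescales the
three-slice set to maximum amplitude 1 (human) or 0.25 (phantom) —
interpreted as rescaling the pre-noise signals, mirroring how measured
inputs are normalized — adds Gaussian noise with σ ~ U(0.01, 0.1), demeans
each inflow channel, and resamples the input velocity to 1,000 points over
the kept 200-TR (~100.8 s) window. Inputs are 5×200 (three inflow slices,
areas, positions); targets are the 1,000-point velocity. Generation is
bit-reproducible from (master seed, n).

What the generator does **not** emulate: scanner noise coloration and
drift, BOLD contamination, motion, partial-volume mixing, non-plug
(secondary/turbulent) flow, and real ventricle geometry beyond the
unimodal-bump family. Passing the recovery tests therefore shows the
inversion works under the model's own physics with realistic spectral
content, not that it is validated on real scanners.

## Inverse model

A 1D convolutional encoder–decoder maps the 5×200 inputs to the 1,000-point
velocity: three conv stages (channels 5→16→32→64) and three transposed-conv
stages (64→32→16→8), all kernel 3, stride 1, padding 1, each followed by
batch norm and ReLU; then flatten (1600) and two fully connected layers
(1600→768→1000). Exact widths are an open design choice — any setting
meeting the shape contract is valid and they live in `NetworkConfig`; the
768-wide hidden layer is generous relative to the ≤1 Hz band-limit of the
targets (~200 effective degrees of freedom over 100 s). With stride 1 the
length change to 1,000 happens entirely in the FC head. The network,
batchnorm, and Adam are implemented in NumPy (float32, im2col convolutions)
with manual backpropagation, verified against finite differences; training
uses MSE loss, Adam at lr 1e−3, batch 16, and a seeded 10% held-out split.
Reference configuration: 45,000 samples / 120 epochs; the test suite and
acceptance script run scaled-down configurations (4,200/30 and 3,000/20)
sized to a single-CPU session.

Prediction demeans the inflow channels internally (making it invariant to
constant channel offsets) and resamples the area curve to the 200-point
anatomy channels. `evaluate_prediction` low-passes both series below 0.5 Hz
(zero-phase Butterworth, order 5), aligns them by maximum cross-correlation
(±5 s search window; removes the phase offset of separately acquired runs),
and reports the mean absolute difference; it rejects constant series, for
which the alignment is undefined. `relative_bandpower` is the 0.14–0.19 Hz
(paced-breathing band) fraction of total periodogram power.

## Measured-data preprocessing

* Partial-volume scaling m = T1W_voxel·(T1W_tiss/T1W_csf − 1)/(T1W_tiss −
  T1W_csf) ≥ 1, equal to 1 for pure-CSF voxels.
* fMRI ROI series: drop 40 samples, subtract the mean of the lowest decile
  of signed values (the "amplitude" wording is ambiguous; the signed lowest
  decile is used), zero-phase Butterworth low-pass (order 5) below 0.5 Hz —
  skippable for network input, which is only demeaned.
* Phase-contrast: v = VENC·(φ_flow − φ_stationary)/π, the standard
  convention under which a phase of π maps to VENC; the convention is
  isolated in one function in case a scanner encodes 2π differently.
* Cycle averaging: ×4 linear upsampling, peak detection with minimum
  separation (expected period − 1 s) and prominence 0.1, inter-peak
  segments resampled to round(period/dt) points and averaged.
* Area-from-labels: per anatomical slice, labeled voxels contribute their
  in-plane area scaled by (slice-minimum T1w)/(voxel T1w), summed slicewise.

## Numerical choices and degenerate inputs

ODE tolerances (rtol 1e−6 / atol 1e−8) and seeding density are exposed as
configuration, since neither is prescribed by the physics; the G-coordinate
tabulation step is 0.005 cm. Slice intervals are half-open; ties at event
instants resolve by the exact position at the event time. Empty slices at
an excitation raise (seeding bug); zero slice-1 normalizers, constant
series in alignment, non-positive amplitudes in the decay fit, and
sub-40-sample fMRI series all raise rather than warn. The simulator is
deterministic: identical configuration gives bit-identical signals; all
stochastic steps take explicit NumPy generators.

## Known limitations

Plug flow only (no radial profile, diffusion, or 3D trajectories); step
slice-selection profile (no through-slice flip-angle variation); single T2
with perfect spoiling; the network is protocol-specific (train anew for
other TR/W/θ); phantom-tube area fixed at 0.5 cm²; the synthetic ventricle
family is unimodal. The supercritical decay-rate regime carries little
velocity information by construction (slice saturation), which is a
property of the measurement, not of the implementation.
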