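# Methods

This note records the models, conventions and design choices behind `ptxh`,
in the spirit of a methods appendix: what is computed, under which
assumptions, and what the synthetic phantom does and does not establish.

## Conventions and constants

* Gyromagnetic ratio: gamma-bar = 42.577478461 MHz/T; Larmor frequency at
  9.4 T: f0 = 400.2 MHz (configurable on every `FieldMap`), so
  ppm = Hz / f0 · 1e6.
* Excitation k-space uses the cycles convention, phase = 2π k·r, with k in
  m⁻¹.  The ±6.33 m⁻¹ kT-point radius is approximately the inverse RF
  wavelength in tissue at 400 MHz (lambda ≈ 0.158 m).
* All volumes carry a 4×4 RAS affine (voxel indices → mm); complex volumes
  are stored on disk as paired real/imaginary NIfTI files.
* B1+ sensitivities are in µT per volt of channel drive; RF waveforms in
  volts; gradients in T/m; SAR matrices in W/kg per V² at 100 % duty.

## B0 mapping

The phase-difference field map uses `angle(e2·conj(e1))/(2π dTE)` so any
echo-independent receiver phase cancels; values alias outside
±1/(2 dTE) = ±226.2 Hz at the default dTE = 2.21 ms.  Unwrapping converts
the field back to phase, runs a 3D spatial unwrapper restricted to the
mask, and re-converts, which guarantees per-voxel congruence modulo
1/dTE; the global branch is pinned at the voxel nearest the mask
centroid.  The unwrapping step is delegated to scikit-image's masked 3D
phase unwrapper (a quality-sorted region-growing algorithm of the
Herraez family), which is the class of method this step calls for.

Masking thresholds the magnitude at a fraction (default 0.5) of its
99.9th percentile, applies morphological closing and keeps the largest
connected component — a deliberately simple stand-in for a brain
extraction tool, adequate for the phantom's binary-magnitude geometry.

Field statistics: sample standard deviation; the 90th-percentile range as
the 95th-minus-5th percentile (a symmetric interval covering 90 % of
voxels); and a histogram full-width-at-half-maximum with Freedman–Diaconis
bins and linearly interpolated half-maximum crossings.  Both the standard
deviation and the histogram FWHM are always reported side by side: for a
Gaussian field they differ by the fixed factor 2.3548, and summaries of
in-vivo linewidths are sometimes quoted in terms of either, so neither is
privileged.

## Spherical-harmonic shimming

The basis is real (tesseral) solid harmonics r^l·Y_lm through order 4,
each normalised to unit peak on a 100 mm reference sphere, so that a coil
coefficient reads directly as "Hz at the reference radius per unit
current".  Coil calibrations are least-squares decompositions of measured
(here: generated) per-unit-current fields; fitting through order 4 while
driving only the physically available coils lets higher-order terms absorb
coil imperfection without pretending 4th-order hardware exists.

Shim currents minimise the in-mask sum of squares of the shimmed field
subject to per-coil box limits — a convex quadratic programme solved to
optimality by a bounded linear least-squares routine (`scipy.optimize.lsq_linear`,
tolerance 1e-12).  Any convex solver reaches the same optimum; a dense
grid-search oracle on ≤3-coil problems confirms agreement to better than
1e-3 of the limit range.  Because enlarging the coil subset only enlarges
the feasible set, the predicted residual is monotone non-increasing in the
coil set; the default comparison (1st+2nd order versus adding Z3, Z2X,
Z2Y, ZX2Y2) demonstrates that on every input.  Fits are unweighted over
in-mask voxels; a magnitude-weighted variant is a one-line extension and
deliberately not the default, to keep the oracle comparisons exact.

The post-shim field used downstream is by default the optimiser's
*predicted* map (b0 + Σ c_i·field_i); a re-simulation mode re-acquires a
noisy dual-echo map under the applied currents instead, mimicking the
optional second calibration scan.

## B1+ mapping

DREAM is modelled at the signal-equation level: per encode step the
channels are driven with one row of an encoding matrix (default: DFT rows,
32 steps for 16 channels), the preparation angle is proportional to the
combined |B1+|, and the simulated magnitudes satisfy STE/FID =
tan²(alpha)/2 with the transmit phase carried on the STE.  Decoding
inverts the ratio, converts angle to µT through the preparation scale, and
solves `encoding @ s = fields` per voxel (pinv; the condition number is
reported).  Relaxation compensation of the real sequence is not simulated
— inputs are taken as ideal STE/FID magnitudes; this is exactly the
assumption the decode makes, so round trips are exact to machine precision
and the noise-free recovery tolerance of 1e-6 is meaningful.

Channel phases are re-referenced to channel 1 at the mask centroid, since
only relative transmit phases matter to the designer.  Preparation angles
must stay below 90° for the arctan inversion to be single-valued; the
default preparation scale (55.5° at the nominal CP-mode efficiency of
0.1253 µT/V) keeps the phantom well inside that range.

## kT-points design

The trajectory is centre → ±x, ±y, ±z at 6.33 m⁻¹ → centre: eight 210 µs
rectangular sub-pulses, each followed by a 70 µs blip slot, 2.24 ms total.
Placing a (possibly zero-area) blip slot after *every* sub-pulse — the
final slot refocusing to the k-space centre — is what makes the printed
total 8 × 280 µs; seven interleaved blips would give 2.17 ms instead.
Each blip is a symmetric trapezoid of fixed 70 µs duration whose area
realises Δk/gamma-bar exactly (the minimal-amplitude full-duration
trapezoid; amplitude and slew checked against the 80 mT/m and 333 T/m/s
limits, with an error naming the offending transition).  Sampled blips are
rescaled so the discrete area matches the analytic area, which keeps the
simulated and designed k-space positions identical.

The STA operator references off-resonance phase to the pulse end
(t_j − T), the standard spatial-domain convention.  The element
360·gamma-bar·s_c(r)·tau·exp(2πi k_j·r)·exp(2πi df(r)(t_j − T)) gives
flip in degrees per volt; with 1 µT/V and tau = 210 µs that is 3.22 °/V.

Magnitude least squares is solved by variable exchange: the target phase
is repeatedly replaced by the phase of the current profile and the inner
regularised least-squares problem (A^H A + λ_g I + λ_l I⊗S_active) b =
A^H z is solved by conjugate gradients warm-started from the previous
iterate.  S_active is the currently maximal VOP, re-selected each outer
iteration.  Because the exchange step with an approximate inner solve is
not guaranteed monotone, each update is damped by bisection whenever the
full step would increase the total objective; iteration stops at relative
objective change < 1e-6 or 50 outer iterations (a budget stop sets a
warning flag on the result).  Initialisation is a CP-like drive on the
centre kT-point — equal magnitudes, phases aligned at the
strongest-sensitivity voxel — scaled to the target in the least-squares
sense.

Region growing addresses the known failure mode of MLS phase freedom
(localised flip drop-outs): the design starts on the top-10 %
combined-|B1+| seed region, the target region is repeatedly dilated
(2 voxels per step) inside the mask, and each enlarged problem adopts the
previous solution's achieved phase as its phase target.  The final result
records the minimum in-mask flip fraction and warns below 0.5.

Axis-point order (+x, −x, +y, −y, +z, −z) is fixed but configurable; it
is a labelling choice with no effect on the attainable optimum.

## Bloch simulation

Hard-pulse integration with one exact Rodrigues rotation per raster step
(default 5 µs, hard ceiling 10 µs): unconditionally norm-preserving, so
|M| = 1 to ~1e-14 for any pulse.  The per-step effective field in Hz is
(gb·Re B1eff, gb·Im B1eff, df + gb·G·r) with B1eff = Σ_c s_c(r)·V_c(t);
frequency modulation is folded into the RF phase by cumulative summation,
which is exact in the Larmor rotating frame.  Relaxation is omitted
(pulse durations are far below tissue T1/T2); the flag is reserved.

Adiabatic pulses: the hyperbolic secant uses AM = peak·sech(βt'),
FM = −(μβ/2π)·tanh(βt') with β = 2070 s⁻¹ (sech truncated at ~1 % of peak
over 5.12 ms) and μ = 4.9.  The FOCI-style pulse multiplies both AM and FM
by the shape factor A(t) = min(a_max, cosh(βt')) — flat-topped AM, sweep
steepened at the edges — with β = 815 s⁻¹ over 13 ms and a_max = 5.  These
are documented representative parameterisations, not any vendor's exact
waveforms; the property that matters (and is asserted) is behavioural: at
matched peak B1 the FOCI-style pulse inverts a strictly larger fraction of
a low-B1 fixture than the hyperbolic secant, i.e. it has the lower
adiabatic threshold.  A plain-text AM/FM loader accepts externally sampled
waveforms, resampled by linear interpolation with peak rescaling.

## SAR monitoring

Per-TR local SAR is (1/TR)·Σ_samples dt·b^H S_v b maximised over VOPs; the
safety factor (default 2) is applied at report time, not inside the design
regulariser, keeping design-time regularisation and monitor margins
separate.  The steady-repetition look-ahead projects the 10 s and 6 min
windows (equal to the per-TR average under constant rate, scaled by duty)
and flags the 20 and 10 W/kg IEC 60601-2-33 limits.  VOP compression is
greedy dominance clustering: matrix Q is dropped when a retained P
satisfies P + ε·λ_max·I ⪰ Q; every retained matrix is emitted with the
ε-pad added, so the compressed maximum provably upper-bounds every
original quadratic form for every drive.  SAR matrices from
electromagnetic simulation are out of scope; the fixture generator
produces random PSD matrices with controllable spectra plus a worst-case
channel-pair structure so the regulariser and the monitor have a sharp
target.

## The synthetic phantom

The phantom emulates the *structure* the algorithms assume, not anatomy:

* **Mask**: an ellipsoid (semi-axes 70 × 85 × 62 mm) on the 50×50×44 grid
  of 4 mm voxels used for field mapping.
* **B0**: solid-harmonic terms through order 4 plus local Gaussian bumps
  (a deep frontal-like −235 Hz bump and a +145 Hz lateral bump),
  calibrated once so the in-mask standard deviation (~57 Hz) sits in the
  40–80 Hz pre-higher-order-shim regime.
* **B1+**: 16 loop-like channels on two rings (radius 110 mm, rows at
  ±35 mm), magnitude decaying as a Lorentzian of the distance to the
  element, phase advancing as a travelling wave exp(−2πi d/λ) with
  λ = 0.158 m, plus a small seeded smooth perturbation that breaks the
  exact ring symmetry.  The overall scale pins the CP-mode combination to
  0.1253 µT/V at the mask centroid (10 µT at 79.8 V).  The CP mode then
  shows the centre-bright pattern with ~50 % NRMSE against a uniform
  target and voxels below half the mean — the ultra-high-field
  phenomenology the design exists to fix.
* **Noise**: complex Gaussian, SNR defined on the in-mask mean magnitude
  (default 50).
* Every generator is a pure function of (spec, seed).

What passing tests on this phantom establish: the algorithms are correct
against their own closed forms and oracles, and the chain homogenises a
field/flip problem with realistic spatial statistics.  What they do not
establish: performance on real coils and heads — the phantom's B1+ is far
smoother than an EM-simulated field, its mask has no neck or subcutaneous
tissue, and its noise is white; in-vivo residuals (tens of Hz, ~9 % NRMSE)
are therefore not reproduced, and the much lower phantom design residual
(<1 % NRMSE) reflects the phantom's smoothness, not algorithmic
superiority.

## Problem sizes and numerical tolerances

Default problem sizes (50×50×44 grid, ~24 000 mask voxels, 16 channels,
8 kT-points, 5 µs raster) were chosen so a full workflow runs in tens of
seconds on one core.  Key tolerances: inner CG residual 1e-12 (relative),
variable-exchange stop 1e-6, shim QP tolerance 1e-12, Hermitian/PSD
validation 1e-12 relative, blip-area realisation exact by construction.
Degenerate inputs are errors, not warnings: empty masks, rank-deficient
encodings at decode time, non-positive echo times, infeasible blips and
peak-voltage violations all raise with a specific message (rank-deficient
encodings at *simulation* time are recorded in provenance instead, since
the raw signals are still well defined).

## Known limitations

* Small-tip designs only; large-tip/optimal-control design and
  slice-selective spokes or SPINS trajectories are out of scope.
* No relaxation in the Bloch model; no EM simulation anywhere.
* The DREAM model omits sequence-level timing (echo formation, relaxation
  compensation); it is a signal-equation emulation sufficient to test the
  decode chain.
* Single static shim over one region; no dynamic or slice-wise shimming.
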