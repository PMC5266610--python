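# Methods

`sweiproc` implements the data-processing side of multiple-track-location
shear wave elasticity imaging (MTL-SWEI): an acoustic radiation force
impulse (ARFI) push displaces tissue axially, the induced transverse
(shear) wave propagates laterally, repeated tracking transmits sample the
motion at kilohertz rates, and the group shear wave speed (SWS) is
estimated from the wave's time of flight across known lateral offsets. In
a linear, elastic, isotropic medium the speed ties directly to stiffness,
v = √(μ/ρ), so with ρ ≈ 1000 kg/m³ the speed in m/s is the square root of
the shear modulus in kPa.

## Sequence-parameter derivations

`sequence_params` collects the closed-form quantities a sequence designer
needs: push duration T = cycles/f, PRF = 1/PRI, F-number F = z/D,
wavelength λ = c/f, axial depth of field 8F²λ, excitation beamwidth Fλ,
the beamformed-IQ axial sampling interval (a fraction of λ, 0.25 on the
reference scanner), the radiation force density f = 2αI/c and the
mechanical impulse f·T. All functions are pure, SI-in/SI-out, and
deterministic. Two conventions worth noting:

* the half-wavelength lateral interval at 3.1 MHz evaluates to 248.4 µm
  from the formula (some scanner documentation rounds it to 246 µm); the
  package always follows the formula;
* `max_trackable_sws` = span/(2·PRI) is a package convention — the speed
  at which a wavefront crosses the tracking span in two frames — offered
  as a Nyquist-style heuristic because no standard closed form exists.

## Synthetic acquisition model

The simulator provides ground truth for every downstream stage.

**Motion.** The displacement pulse is a temporal Gaussian travelling
laterally at speed v from the push origin x₀:
u(x,t) = A·(x_ref/|x−x₀|)^p·exp(−(t−t₀−|x−x₀|/v)²/2σ²), with geometric
decay normalised at x_ref = 1 mm. Peak-displacement arrival times
(t₀ + |x−x₀|/v) and peak-velocity arrivals (exactly σ earlier, the
extremum of the Gaussian derivative) are analytic, so parameter-recovery
tests assert against closed forms. Defaults mirror a typical elastic
phantom acquisition: 1.1 m/s, σ = 1 ms (≈ 200 Hz band), 5 µm peak
displacement, 4 reference + 3 push + 25 track frames at PRI 0.2 ms,
track positions 0.5–5 mm.

**Artifacts.** Push/reverberation corruption is modelled
phenomenologically as spatially rough noise of ≥ 5× pulse amplitude on
the push frames and a configurable number of following frames (the
physical cause — clutter from the long push pulse ringing in the field —
is not modelled acoustically). Background biological/transducer motion is
a lateral-uniform low-frequency sinusoid (default 5 Hz). Boundary
reflections are mirrored pulses launched from the interface with a
coefficient in [0,1] and path-length decay. The corrupted field is
exactly clean + artifact, so superposition is testable bit-for-bit.

**IQ rendering.** One band-limited complex speckle column is drawn per
lateral position (FFT brick mask, so realisations are exactly periodic
and band-limited); frame i is the reference column rotated by
exp(+i·4π·fc·u/c). Sign contract, package-wide: displacement *away* from
the transducer is positive and advances the IQ phase; the trackers use
the matching inverse, and the round-trip test enforces the pairing. The
pure-phase model preserves per-sample magnitude exactly and gives exact
estimator oracles; it deliberately omits speckle decorrelation, shearing
within the point spread function, and diffraction, so passing round-trip
tests bound only algorithmic error, not the physical estimator bias a
scanner would see. An optional resample mode
(`render_shifted_rf_ensemble`) instead shifts an upsampled RF speckle
realisation by the echo delay 2u/c, producing the interpolation error and
decorrelation that correlation-based tracking must tolerate. A residual
carrier (RF centre frequency ≠ fc) can be injected as a fast-time phase
ramp to exercise frequency-tracking estimators.

## Motion estimation

**1-D autocorrelator (Kasai).** For each axial kernel of M samples the
lag autocorrelation R = Σ_m x*(m,ref)·x(m,i) is formed and
u = c/(4π·fc)·arg R with the four-quadrant phase in (−π, π]. Fixed
referencing (reference frame = last reference-labelled frame before the
push, overridable) yields absolute displacement; progressive referencing
yields per-frame differential displacement; a Doppler-style ensemble mode
sums N−1 adjacent-frame products into a single average. The textbook
flattening of these expressions as products of kernel sums (and a stray
sign in the progressive denominator) is replaced by the standard
sum-of-conjugate-products form, which is what the oracle tests pin down.
The phase bound confines estimates to |u| ≤ c/(4·fc) = λ/4 (half the
two-way-path wavelength); larger displacements wrap, which the suite
asserts on constructed input. Kernels slide with stride M/2 (min 1); the
output axial coordinate is the kernel centre.

**2-D autocorrelator (Loupas).** Extends Kasai by estimating the mean RF
frequency per kernel from the fast-time lag-one autocorrelation phase
(f̂ = fc + arg R_ax/(2π·Δt_fast), Δt_fast = 2Δz/c) and normalising the
slow-time phase by f̂ instead of fc. When the data's RF centre frequency
equals fc the correction is zero and the two estimators coincide; under a
deliberate 10 % carrier mismatch the per-kernel frequency estimate is
noisy but unbiased, and the Loupas RMS error is measurably below the
Kasai bias (asserted with kernel M = 16 on the simulator).

**IQ→RF remodulation and NXcorr.** IQ is FFT-resampled to the requested
RF rate and mixed up on a carrier; the carrier is snapped to the nearest
frequency with an integer cycle count over the record (exact λ/4
sampling makes the snap a no-op) so demodulation reproduces the input
band to ~1e−14 instead of suffering percent-level spectral leakage.
Normalized cross-correlation then tracks each axial kernel against the
reference frame over a ± search window, with cubic-spline upsampling
(default ×10) and 3-point parabolic refinement of the correlation peak;
displacement = lag·c/(2·fs·upsample). A peak correlation within 1e−9 of
1 skips refinement (a perfect match needs none, and refining it only
adds interpolant noise). Peak correlation is kept as a per-sample
quality weight; flat kernels are masked NaN.

**Conversions.** Velocity from displacement uses central differences
(one-sided at the ends) to keep peak-velocity timing unbiased;
differential displacement divides by Δt; accumulation is a cumulative
sum (×Δt from velocity) anchored at zero. The discrete Fourier relation
ℱ[v] = iω·ℱ[u] holds to < 2 % L2 for a 200 Hz-band pulse at 10 kHz
sampling, the regime the pipeline operates in.

## Conditioning

All slow-time filters are zero-phase (forward–backward 4th-order
Butterworth, edge-value padding) because the speed estimate lives
entirely in the time axis; the effective magnitude specs — DC gain 1,
≥ 40 dB at twice the low-pass cutoff, ≥ 20 dB suppression of 5 Hz
background at the 20 Hz high-pass cutoff with ≥ 90 % retention of a
200 Hz-band pulse — are contracts verified by the suite, not tied to the
filter family. The high-pass additionally subtracts the residual
per-trace mean so DC rejection holds exactly on short records (still
linear, still zero-phase). The default 20 Hz high-pass cutoff sits
between sub-10 Hz biological motion and the > 50 Hz shear-wave band.

**Reverberation-frame repair** replaces flagged frames per (axial,
lateral) sample with cubic-spline interpolation along slow time,
preserving uniform sampling; trailing frames without two good support
frames are dropped instead (logged). Auto-detection — all push-labelled
frames plus the contiguous run of following frames whose spatial standard
deviation exceeds 3× the median spatial std of the last quarter of frames
— is an explicit package heuristic; explicit index lists are the primary
interface. Spline reconstruction across a 5-frame gap straddling the
pulse peak is accurate to < 2 % of peak when σ ≥ 5 frame intervals (the
reference acquisition: σ = 1 ms at PRI 0.2 ms); narrower pulses degrade
(≈ 4 % at σ = 4, ≈ 12 % at σ = 3 frame intervals).

**Directional filtering** separates travelling-wave directions in
(kx, ω) space. With the FFT sign convention used, a wave moving toward +x
occupies the quadrants where kx·ω < 0 — fixed by a simulator property
test rather than asserted abstractly. The rejected quadrants are zeroed
with an odd raised-cosine taper (default width 5 % of each Nyquist band)
near the axes; the kx = 0 and ω = 0 lines carry weight 0.5 so the
rightward and leftward masks sum to one and the two outputs partition the
input exactly. Energy contracts (≥ 95 % same-direction retention, ≤ 1 %
opposite leakage) are met for waves whose spectral ridge is resolved by
the grid — in practice ≥ 8 lateral positions and ≥ 16 frames, and
mean-free (velocity-like or high-passed) data, since a strong DC bin is
necessarily split between the two directions.

## Speed estimation

3-D motion is projected to (lateral × time) by an unweighted mean over
the push depth of field (focal depth ± 4F²λ) and the lateral window
[x_min, x_max]. The near-field bound is strict: track locations at or
inside the excitation beamwidth Fλ sit in the shear-wave near field,
where diffraction makes arrivals early; including them biases the
regression speed downward (the suite asserts the sign of this bias).

* **Regression** — arrival per position from the time of peak
  displacement, peak particle velocity, or accumulated adjacent-trace
  cross-correlation lags (all spline-upsampled ×10 in time with 3-point
  parabolic refinement; peak ties break to the earliest time); speed is
  the inverse slope of OLS of arrival time on position, with R² and a
  95 % CI propagated to first order from the slope standard error. A
  non-positive slope returns a flagged failure, not an exception; fewer
  than 6 positions warns (outlier sensitivity).
* **RANSAC** — 2-point minimal sets, consensus = |residual| ≤ threshold
  (default one frame interval), best consensus by count then RMS, OLS
  refit on the consensus, inlier fraction reported; 2000 iterations by
  default (success probability 1−(1−w²)^k ≈ 1 at 30 % outliers);
  bit-deterministic for a fixed seed.
* **Radon sum** — candidate straight space–time trajectories between a
  fixed start and end position with start/end times on the ×10
  time-upsampled lattice, feasibility limited to a speed range; the
  (rectified, so displacement and velocity both give positive ridges)
  signal is linearly interpolated and summed along each trajectory; the
  peak sum wins, ties to the slowest speed. A flat surface
  (peak/median < 1.5) returns a failure result. The vectorised search is
  pinned to an explicit brute-force enumerator on small grids.

A fractional timing error ε in the PRI rescales every estimator's output
by exactly 1/(1+ε) (the time axis is the only clock in the problem);
the suite asserts this at ε = ±5 % to 0.1 %.

## Beam-position calibration

Lateral PSF profiles are extracted from point-target envelope images by
axial maximum projection, spline-upsampled to ≤ 0.1 mm, and
cross-correlated with parabolic peak refinement; a peak correlation below
0.5 raises a low-confidence error. The percent position error
100·|prescribed − measured|/prescribed equals the percent pitch error for
linear/phased arrays at any depth; curvilinear arrays need repeats at
several depths to separate radius-of-curvature from sector-angle errors.
Stage precision enters once per positioning event, two events per pair,
giving uncertainty 100·2·precision/prescribed (a 0.001 mm stage on a
6.0 mm move → 0.033 %); the single-reading figure would be half that, and
both conventions are stated here because published practice is ambiguous.
The speed of sound used for imaging is the user's responsibility and is
only recorded in provenance.

## Container and provenance

The HDF5 layout (schema version 1) stores `/iq` (native complex,
frame-major) and/or `/motion` with coordinate vectors, frame labels and
an append-only JSON provenance chain under `/meta`; every pipeline stage
appends exactly one record (operation + full configuration), so a result
file replays its own history. Round trips are bit-exact; validation
errors list all missing fields at once; 0-based frame indices and
signed lateral distances from the push origin are used throughout.

## Problem sizes and limitations

Tests and the acceptance script run on desk-scale synthetic problems —
ensembles of ≈ 64–96 axial samples × ≤ 12 lateral positions × ≤ 200
frames, 128×256 grids for the directional filter — sizes at which every
oracle is exact or analytic. Known limitations: no acoustic field
simulation (beam diffraction, nonlinearity), no viscoelastic dispersion
in the simulator (so displacement- and velocity-feature speeds agree by
construction; dispersive media would split them), no 3-D/4-D directional
filtering for out-of-plane interfaces, no direct inversion of the wave
equation (second derivatives of noisy displacement data are not robust),
and no reading of native scanner export formats.
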