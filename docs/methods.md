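# Methods

`protobeam` simulates and reconstructs 3D protoacoustic (ionoacoustic) images
of the proton Bragg peak as acquired by a planar 16×16 matrix ultrasound
array, and quantifies how well the reconstruction localizes the peak — the
quantity that matters for range verification in proton therapy.

## Physical model

**Dose.** A pencil-beam spot is modelled analytically: the depth–dose curve is
the characteristic `1/sqrt(R − z)` rise toward the Bragg peak, convolved with
a Gaussian range-straggling kernel, with the power-law range–energy relation

    R = α·E^p,   α = 0.0022 cm/MeV^p, p = 1.77   (water; scaled by 1/ρ)

and straggling width `σ_R = 0.012·R^0.935` (cm). The singular integrand is
integrated analytically per depth bin, so the discretization is exact up to
the Gaussian blur. Laterally the spot is a 2D Gaussian (default σ = 3 mm at
entry, constant with depth; optional linear-in-depth broadening). This
analytic model replaces a Monte Carlo dose engine: it has the correct
range–energy law, a single global peak, a realistic peak-to-entrance ratio
and a distal falloff below 1% of peak within a few mm — the features the
acoustic chain actually probes. It omits nuclear-interaction buildup, beam
momentum spread and heterogeneous stopping power.

**Thermoacoustics.** One proton pulse of duration τ_p (machine-adjustable
4–20 µs) deposits dose `D_p(r)`, giving the initial pressure

    p0(r) = Γ·η_th·ρ·D_p(r),      Γ = β·K_T/(C_v·ρ),

with Γ the Grüneisen parameter and η_th the heat efficiency. The pressure at
a point receiver is the retarded-time spherical-spreading integral

    p(r, t) = 1/(4π v_s²) ∫ dr′ p0(r′)/|r − r′| · ∂_t s(t′)/τ_p,
              t′ = t − |r − r′|/v_s,

under the standard separability assumption `D(r′, t) = D_p(r′)·s(t)/τ_p`
(`∫ s dt = τ_p`). Discretely, every source voxel deposits its amplitude at
its time of flight (linearly split between bracketing samples); the deposit
train is convolved with `ds/dt` and with the transducer's band-pass impulse
response (Gaussian amplitude spectrum, −6 dB fractional bandwidth as
configured; zero-phase, so the receive filter adds no arrival-time bias).
Γ·η_th·ρ is applied exactly once, in `initial_pressure`; all amplitudes are
relative, as they are in practice for protoacoustic images.

Elements are ideal points at their centers. The default array is 16×16
elements of 3 mm with a 0.2 mm kerf — 3.2 mm center-to-center pitch and a
~51 mm square aperture (a literal 0.2 mm center spacing would contradict
3 mm elements). Sampling is 20 MS/s over a 75 µs record; 1 MHz center
frequency with 60% fractional bandwidth gives the upper −6 dB edge
f_max = 1.3 MHz.

**Noise and averaging.** Acquisition noise is additive white Gaussian,
identical σ on every channel, parameterized by the *single-frame peak SNR*
(max |signal| / σ). Frame averaging takes the literal mean of n independent
noisy realizations, so residual noise falls as σ/√n.

## Reconstruction

Back-projection accumulates, for every voxel, each element's trace at the
voxel's acoustic time of flight (linear interpolation in time). Two variants:

* **das** (default): plain delay-and-sum of the band-passed traces.
* **ubp**: the filtered term `p(t) − t·∂p/∂t` with solid-angle apodization —
  the classical universal-back-projection weighting for spherical geometry.

`ubp` assumes effectively instantaneous deposition. With a 4–20 µs proton
pulse and no pulse deconvolution (none is performed, matching experimental
practice), its derivative term displaces an extended source's maximum by
roughly the pulse length — we measured ~5 mm on the 87 MeV scene versus
0.15 mm for `das`. Delay-and-sum is therefore the default; `ubp` remains
available and matches `das` argmax within one voxel for point-like sources.

Known artifacts, stated so users can design fields of view around them:

* **Limited view.** A planar array sees the scene from one side only: the
  axis along the array normal (the range axis, when the array faces the
  beam) is reliable; in-plane blobs elongate. Localization metrics therefore
  use peak position, never shape fidelity, in the lateral plane.
* **Trailing-edge ghost.** `ds/dt` of a finite pulse has a negative lobe at
  t ≈ τ_p; after band-pass filtering its ringing creates a ghost lobe
  displaced ~`v_s·τ_p` (≈6 mm at 4 µs) beyond the true peak along the array
  normal. Reconstruction windows for range verification should stop short of
  that zone (the default scene's window does).
* **Pulse-edge bias.** The leading-edge lobe of `ds/dt` is centered half a
  rise time after pulse onset, biasing `das` peaks distally by
  `v_s·rise/2` (≈0.3 mm at the default 10% rise of a 4 µs trapezoid). This
  is the noiseless localization floor.

## Denoising

Per channel: multilevel DWT (sym8, 5 levels, symmetric extension), soft
thresholding of all detail bands at the universal threshold
`σ̂·sqrt(2 ln n)` with `σ̂ = MAD(finest band)/0.6745`, inverse DWT, then an
optional zero-phase 4th-order Butterworth low-pass. The low-pass cutoff
default is 0.12 MHz. Caveat: a 0.12 MHz low-pass suppresses nearly the whole
1 MHz transducer band, so applying the default cutoff removes the signal
along with the noise; it is kept as the configurable default for fidelity to
the processing description this chain models, but pipelines that feed
reconstruction should set `cutoff_mhz=None` (or a cutoff above the band).
The shrinkage stage alone preserves a clean band-limited pulse with ≥0.95
waveform correlation while removing ≥80% of white-noise variance.

## Metrics

* **Bandwidth-limited resolution** `R = 0.88·v_s/f_max` (≈1.02 mm for
  1500 m/s and 1.3 MHz). The measured axial FWHM of a reconstructed point
  source is larger, because the µs-scale pulse smears the axial response by
  ~`v_s·τ_p`; the line-spread operation reports both numbers rather than
  forcing agreement.
* **Localization**: `argmax` (global maximum, 3-point parabolic sub-voxel
  refinement per axis — default), `centroid` (intensity-weighted mean above
  50% of max), `distal80` (distal 80%-of-peak crossing along the beam axis,
  the conventional range definition). Ground truth is the analytic
  depth-dose maximum.
* **Gamma index** (dose difference ΔD_M % of the global reference maximum /
  distance-to-agreement Δd_M mm, low-dose threshold % of the measured
  maximum): exhaustive search over a ball of radius 2·Δd_M on a 1/5-voxel
  lattice with trilinear interpolation of the reference, visiting offsets in
  order of increasing distance with an early exit once the distance term
  alone exceeds every running minimum. This is the defensible reference
  implementation; it is checked against an independent brute-force search.
* **Averaging sweep**: deviation of the localized peak from the analytic
  truth versus the number of averaged frames, over seeds; reports 3D
  Euclidean and per-axis deviations.

## Default study conditions

The default scene (`protobeam.experiments.default_scene`) is an 87 MeV beam
(range ≈ 60 mm) entering the water at z = 75 mm and travelling toward the
array in the z = 0 plane, so the Bragg peak sits ~16 mm in front of the
array and range changes move it along the reliable axis. Dose raster
0.4 mm voxels; reconstruction window 20×20×26 mm around the expected peak
(0.4 mm voxels), inside the 75 µs record everywhere and short of the
trailing-edge ghost zone. Scan patterns step the spot laterally (±10 mm or
±5 mm around the array axis for three-spot plans) so all spots stay well
inside the aperture's view.

**SNR calibration.** The single-frame peak SNR of the default noisy scene is
a property of a detector/beam combination that the simulation cannot derive
from first principles, so it is calibrated once against the averaging
behaviour this chain is designed to reproduce: the value stored in
`protobeam.config.DEFAULT_SNR_SINGLE_FRAME` (= 2.0) was chosen so that
50-frame averaging localizes the default Bragg peak to within 2 mm across
seeds, and was then held fixed; the ~1000-average sub-millimeter behaviour is
a prediction of that calibration, not a separate fit. The calibration makes
explicit which number is fitted and which is predicted. At this SNR a single
frame localizes to only ~3-4 mm (median), so the averaging dependence remains
the object of study. Argmax localization of the laterally-elongated blob is
the noise-sensitive step: its deviation is dominated by in-plane jitter, not
range error.

## Numerical choices

* Units: mm, µs, MHz internally; sound speed converted once (m/s → mm/µs).
* Voxel rasters use the voxel-center convention (world = origin +
  index·spacing), 0-based indices, right-handed mm frame.
* Delta deposits and back-projection both use linear interpolation in time;
  sampling must exceed 4·f_max when a band-pass response is requested.
* `acquire_frames` draws frames in bounded chunks so 1000-frame averages do
  not hold all realizations in memory; fixed seeds make every output
  bit-reproducible.
* Sources below 10⁻⁴ of the maximum initial pressure may be dropped in the
  forward projection of large volumes (`source_threshold`); the default
  scenes use that threshold, which changes traces by <0.1% in L2.
* Degenerate inputs raise typed errors: truncated dose grids, too-short
  records (naming the farthest voxel), sub-Nyquist sampling, all-zero
  volumes, raster mismatches in the gamma comparison.

## What the synthetic generator does not emulate

Heterogeneous or refracting media (a single uniform medium per run; the
1400 m/s torso-phantom preset is a scalar, not a map), shear waves, element
directivity and cross-talk, amplifier electronics, trigger jitter, beam
momentum spread and nuclear buildup in the dose model, and motion. Passing
tests therefore demonstrate the correctness and noise behaviour of the
imaging chain itself, not performance in heterogeneous anatomy.

## Problem sizes

The shipped experiments run on one CPU: the default scene uses ~600k dose
voxels, 256 channels × 1500 samples, ~220k reconstruction voxels;
averaging sweeps use 3–5 seeds and up to 1000 frames per average. These
sizes were chosen to exercise the full chain at the full experimental geometry
while keeping a complete run in minutes.
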