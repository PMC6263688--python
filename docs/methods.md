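# Methods

This note documents the models and procedures implemented in
`thermowelfare`, the parameter defaults and why they were chosen, what the
synthetic scenes do and do not emulate, and the numerical decisions that a
user extending the package should know about.

## Respiratory-rate estimation

### Model

The measurement model is purely mechanical: breathing displaces the chest
wall quasi-periodically, and that displacement is visible as sub-pixel to
few-pixel motion of the fur texture in a thermal video. The estimator makes
no use of temperature calibration — all preprocessing operates on intensity
rank order, so radiometric (°C per pixel) and plain grayscale input follow
one code path.

The processing chain per video:

1. **Segmentation** (`preprocess`). Multilevel Otsu with 3 classes by
   default: background, the intermediate-temperature halo that the thermal
   point-spread function creates at the body edge, and the body core. The
   foreground mask (warmest class) restricts feature detection; it is not
   used afterwards. Contrast stretching maps the 1st–99th intensity
   percentiles linearly to 0–255; percentile clipping keeps hot spots
   (urine, feces) from compressing the body contrast.
2. **Feature tracking** (`respiration`). Up to 100 Shi-Tomasi corners are
   detected once, in the first frame, by greedy ranked selection on the
   minimum-eigenvalue response with a 3-px minimum mutual distance. They are
   then tracked with an in-package pyramidal Lucas-Kanade implementation
   (15-px windows, 2 pyramid levels, iterative refinement with bilinear
   sub-pixel sampling). A point whose window leaves the frame or whose
   normal matrix degenerates is invalid from that frame on.
3. **Band-pass filtering.** Equiripple (Parks-McClellan) FIR with passband
   [0.6, 3.3] Hz for rats and [1, 4.6] Hz for mice, 0.2 Hz transitions,
   ≥ 40 dB stopband. The design ripple is 0.4 dB because the filter is
   applied forward–backward (zero net delay), which squares the magnitude
   response; the applied response is therefore within ~1 dB. The filter is
   applied once to the full-length trajectories rather than per window: at
   30 fps the filter needs ~250 taps, so a 10-s window (300 samples) is too
   short to filter on its own, while the full trace comfortably satisfies
   the length requirement. Positions of points lost mid-video are held at
   their last tracked value before filtering so they add no spurious band
   power.
4. **Per-window estimation.** Sliding windows of 10 s, hopped every 1 s.
   Within each window: the 25 % most erratic trajectories (largest mean
   inter-frame displacement) are discarded — with ties broken by point
   index, keeping exactly ⌈0.75 n⌉ — the axis (x or y) with the larger
   summed variance is selected (ties → y), the filtered signals are
   decomposed by PCA, and the first 6 component score series are scored for
   periodicity. Per-window failures (e.g. too few surviving points) yield
   gap rows flagged invalid rather than aborting the trace.
5. **Periodicity score.** Each component is Hamming-windowed and zero-padded
   to a power of two giving ≤ 0.01 Hz resolution. f₀ is the power argmax
   inside the passband; the score is the power within ±0.05 Hz of f₀ plus
   the power within ±0.05 Hz of the first harmonic 2f₀, divided by the
   total power over (0, fs/2]. DC is excluded (components are mean
   centered). Note the absolute score is window-length dependent: the
   Hamming main lobe has half-width 2/T Hz, so a pure tone scores ≈ 0.6 at
   T = 10 s and > 0.9 only for T ≳ 40 s. Component *selection* only needs
   the relative comparison, which is insensitive to this.
6. **Output.** RR = 60·f₀ of the best-scoring component (ties → lower
   index); `rr_bpm_median` is the median of the estimates in the trailing
   5 s, which suppresses single-window outliers at the cost of a few
   seconds of delay.

### Agreement metrics

`evaluate_against_reference` pairs estimate and reference traces by nearest
timestamp (within half a hop by default) and reports RMSE, mean relative
error ε̄, the 90th percentile ε₉₀, Pearson r, and Bland–Altman bias with
95 % limits of agreement (bias ± 1.96 · SD of the differences, SD with one
delta degree of freedom).

### Window-length trade-off

The 10-s window (1-s hop) is a compromise: it spans ≥ 6 breathing cycles at
the slowest anesthetized-rat rates (~40 breaths/min) while leaving enough
windows in a 2-min recording for the trailing 5-s median to act. Longer
windows sharpen the spectral peak (the per-window quantization of the RR
estimate is one FFT bin, ~0.44 breaths/min at 10 s / 30 fps) but respond
more slowly to rate changes.

## Open Field tracking

### Model

The tracker is a particle filter whose observation model is sparse
reconstruction. State is (cx, cy, log sx, log sy) — no rotation, because a
rodent seen top-down is a warm blob whose appearance at template scale is
nearly rotation invariant, and the smaller state keeps the particle count
moderate (300 by default). Transitions add Gaussian noise (σ = 3 px in
position, 0.01 in log scale per frame).

Each candidate window is resampled to a 16×16 patch, zero-meaned and
unit-normed, and reconstructed over the template dictionary [T, I, −I]
(10 target templates — the initial ROI patch and one/two-pixel-shifted
copies — plus positive and negative identity templates) by non-negative
ℓ1-regularized least squares (λ = 0.01). The candidate minimizing the
target-only reconstruction error ‖y − T c_T‖² wins. Particle weights are
multiplied by exp(−50 · error) and systematically resampled when the
effective sample size drops below half the particle count. Template update:
if the winner's cosine similarity to every template is below τ = 0.7, it
replaces the least important template; otherwise the best-matching
template's importance grows. Frames whose best error exceeds 5× the running
median are flagged low-confidence.

### Numerical solver

The ℓ1 problem is solved by block coordinate descent exploiting the
structure of the trivial templates: given the target coefficients, the
trivial part has the closed-form soft-threshold solution; given the trivial
part, the target coefficients (only 10 of them) are updated by coordinate
descent in Gram space. Both block updates decrease the objective, so
convergence is monitored on the per-candidate objective decrease
(tolerance 10⁻⁵, at most 2000 iterations, candidates frozen as they
converge). With the deliberately near-collinear shifted-template set the
*coefficients* converge slowly but the objective — and hence the error used
for ranking — converges fast; a tighter 10⁻⁶ stopping costs several times
the iterations while moving the objective by < 4·10⁻³.

### Localization precision

The shifted-template dictionary makes the reconstruction error flat over a
±1 px basin by construction (that is its robustness mechanism), and the
reported center is the argmin candidate, so the track carries ~1.3 px of
frame-to-frame sampling jitter around an unbiased mean. Velocity and zone
metrics therefore smooth the velocity components over 0.5 s before taking
magnitudes. Cumulative path length of a perfectly stationary animal is
dominated by this jitter; it is negligible relative to body size only when
the animal spans ≳ 70 px in the frame, which matches close-up arena views.

### Activity metrics

The arena is calibrated by its physical size (mm) and pixel rectangle;
conversion may be anisotropic. Occupancy maps accumulate 1/fps seconds per
frame into a 32×32 grid (positions outside the arena are clipped into the
border cells with a warning, so the grid mass always equals the track
duration). The logarithmic variant is ln(1 + seconds) — order preserving,
zeros stay zero — which reveals rarely visited paths that a linear map
hides. The center zone is the concentric rectangle with 50 % of the arena's
linear dimensions (25 % of its area), the common Open Field convention; the
center fraction, the immobility speed threshold (5 mm/s) and the minimum
immobility duration (1 s) are all configuration. Per-step distances are
assigned to the zone of the segment midpoint, which makes the center/
periphery split invariant under time reversal.

## Synthetic scenes

### What they emulate

* A warm body (35 °C) on a cool background (22 °C) — the contrast that
  makes thermal segmentation of rodents easy.
* A frozen random texture (Gaussian field smoothed to ~3 px correlation,
  1 °C std) riding on the body, because corner detection and optical flow
  need gradients that a flat blob does not have. Fur and skin of real
  animals show comparable thermal micro-structure.
* A Gaussian-blurred body edge (σ = 1.5 px) emulating the thermal
  point-spread halo; this is what makes the 3-class segmentation the right
  default.
* Breathing as rigid vertical translation of a chest sub-rectangle by
  a·sin(2π∫f(t)dt) with a = 1.5 px, rendered with bilinear sub-pixel
  shifting so sub-pixel amplitudes remain detectable. The commanded profile
  f(t) (constant, ramp, step, or arbitrary) is the ground truth.
* Open Field locomotion as a correlated random walk (Ornstein–Uhlenbeck
  speed, heading diffusion) reflected at the walls, with an optional
  heading bias toward the nearest wall that reproduces thigmotaxis.
* Per-frame i.i.d. Gaussian sensor noise (default σ = 0.3 °C, versus the
  ~13 °C body-background contrast).

### What they do not emulate

Real deformable bodies (the chest moves rigidly here), respiratory-derived
temperature modulation at the nostrils, camera drift and fixed-pattern
noise, fur parting, other animals, or occlusion. Passing tests on these
scenes therefore demonstrates the correctness of the signal chain — from
pixels to breaths/min under known ground truth — not robustness to every
artifact of live recordings. The chest rectangle translates wholesale, so
texture near its boundary mixes moving and static content; tracked points
there understate the amplitude, which is irrelevant to the frequency
readout the pipeline uses.

## Problem sizes used in validation

The published error statistics this package checks itself against were
measured on 2-minute recordings at 640×480 px / 60 fps. The validation
scenes keep the 2-minute duration and the acquisition geometry scaled to
320×240 px at 30 fps, which preserves every frequency relationship (all
passbands sit far below either Nyquist rate). The acceptance script runs 5
scenes × 2 noise realizations per species regime (rat: constant RR drawn
uniformly from 44–62 breaths/min; mouse: 70–140 breaths/min) plus 2
realizations of the 50→60 breaths/min ramp; the test suite likewise uses 2
realizations per scene. The tracking fidelity check runs one 30-s Open
Field scene at the same geometry. These realization counts are the
package's choice of validation size; the per-scene protocol (duration,
noise, amplitude, bands) is fixed.

## Known limitations

* The thorax ROI is selected manually (or taken from the generator); there
  is no automatic thorax detection.
* RR estimation assumes a quasi-stationary animal (anesthesia); it is not
  validated for freely moving animals, where the tracker and the RR chain
  would need to be combined.
* The RR estimate is quantized to one FFT bin per window; with the default
  10-s window that is ~0.44 breaths/min, an error floor visible in the
  reported RMSE.
* The tracker handles a single animal and has no occlusion reasoning or
  re-identification.
* Reading 8/16-bit grayscale *video containers* requires an imageio plugin
  with the corresponding codec; multipage TIFF stacks are the first-class
  format and the only one exercised by the tests.
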