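# thermowelfare

Contactless welfare monitoring of laboratory rodents from long-wave
thermal-infrared video. The package implements two pipelines used in
severity assessment of animal experiments:

1. **Respiratory rate (RR) from chest motion.** In anesthetized rodents the
   chest wall moves periodically with each breath. The pipeline tracks that
   motion in a manually selected thorax region and reads the breathing
   frequency off its spectrum — no sensors attached to the animal.
2. **Open Field activity tracking.** A sparse-representation particle-filter
   tracker follows the animal (the warmest object in the thermogram) through
   an Open Field test and derives velocity, occupancy heat maps and
   center/periphery zone metrics — the classic anxiety and activity readouts.

Because no public thermal recordings of rodents accompany these methods, the
package ships a ground-truthed synthetic scene generator (warm textured body
on a cool background, commanded breathing displacement or a commanded random
walk) so that every stage is verifiable end to end.

## The methods in brief

**RR estimation.** For a thorax ROI in the first frame:

1. Segment the animal by multilevel Otsu thresholding (warmest class) and
   contrast-stretch each frame to 8 bits.
2. Detect up to *N* = 100 Shi-Tomasi corners in the ROI (first frame only)
   and track them with pyramidal Lucas-Kanade optical flow.
3. Per 10-s sliding window (1-s hop): discard the 25 % most erratic
   trajectories (mean inter-frame displacement), keep the axis (x or y) with
   the larger motion variance.
4. Band-pass the trajectories with an equiripple FIR tuned to the species —
   rats [0.6, 3.3] Hz, mice [1, 4.6] Hz — applied forward–backward.
5. Decompose the windowed signals with PCA (first 6 components) and score
   each component's periodicity by the **peak-to-total ratio**: the fraction
   of spectral power within ±0.05 Hz of the dominant frequency f₀ and of its
   first harmonic 2f₀ (Hamming window, zero-padded FFT).
6. RR = 60 · f₀ of the most periodic component; a trailing 5-s median
   suppresses outliers.

Agreement with a reference trace is quantified by RMSE, mean relative error
ε̄, its 90th percentile ε₉₀, Pearson correlation and Bland–Altman bias with
95 % limits of agreement.

**Tracking.** Each candidate window *y* (a particle) is scored by
non-negative ℓ1-regularized reconstruction over target templates *T* plus
trivial (identity) templates:

    min ‖y − [T, I, −I] c‖² + λ‖c‖₁,  c ≥ 0

The candidate with the smallest target-template reconstruction error
‖y − T c_T‖² is the track result; templates adapt when the appearance
changes. State is (cx, cy, log sx, log sy) with Gaussian transitions and
systematic resampling.

## Worked example

```python
from thermowelfare import preset, rr_trace, evaluate_against_reference
from thermowelfare.synthetic import BreathSceneConfig, make_breathing_video

cfg = BreathSceneConfig(frame_shape=(240, 320), fps=30.0, duration_s=120.0,
                        rr_profile=47.3, noise_sigma_c=0.3, seed=2)
video, truth = make_breathing_video(cfg)          # ground-truthed scene
trace = rr_trace(video, cfg.chest_roi, preset("rat"))
print(trace.head(3)[["time_s", "rr_bpm", "rr_bpm_median", "periodicity"]])
m = evaluate_against_reference(trace, truth)
print(f"eps_bar {m.mean_rel_err_pct:.4f}%  rmse {m.rmse_bpm:.4f} bpm")
```

prints

```
   time_s     rr_bpm  rr_bpm_median  periodicity
0    10.0  47.460938      47.460938     0.623845
1    11.0  47.460938      47.460938     0.621544
2    12.0  47.460938      47.460938     0.624100
eps_bar 0.3537%  rmse 0.1694 bpm
```

i.e. the commanded 47.3 breaths/min is recovered to within the spectral
resolution (~0.45 bpm per FFT bin at a 10-s window), for a mean relative
error of 0.35 % — inside the 0.50 % cohort mean reported for rats with this
approach. The same generator drives the Open Field pipeline:

```bash
thermowelfare synth oft --out oft.tif --truth truth.csv --seed 7
thermowelfare track-oft --input oft.tif --roi 140,100,180,130 \
    --arena-mm 720,720 --out-prefix run1
```

which writes `run1_track.csv`, occupancy heat maps (`run1_heatmap.csv/.png`,
linear and logarithmic) and `run1_summary.csv` with total distance, zone
times, and immobility time.

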