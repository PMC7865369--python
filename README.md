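# facepulse

Imaging photoplethysmography (iPPG) from facial video: contactless
measurement of the blood-volume pulse from the tiny periodic changes in
skin reflectance that each cardiac cycle produces, resolved *regionally*
across the face.

`facepulse` is aimed at researchers studying facial hemodynamics — pulse
amplitude and pulse *arrival-time* differences between facial regions — and
at anyone building or validating camera-based vital-sign pipelines. It
implements the full chain from a frame sequence to statistics and images:

1. **Region geometry** — an 81-point facial landmark set (from the shipped
   canonical template or any detector adapter) is triangulated into 98
   non-overlapping, mirror-symmetric triangular regions; an 80×80 px ROI is
   centred on each triangle centroid, and a first-frame ROI mask is reused
   for all frames.
2. **Signals** — per-ROI raw signal `x(i)` = green-channel spatial mean;
   sliding 1 s mean-centralization; zero-phase 5th-order Butterworth bands
   at 0.5–4 Hz (pulse, `f(i)`) and 0.2–0.5 Hz (breathing).
3. **Quality** — per region:
   `SNR = 10·log₁₀(Σf(i)² / Σ(f(i)−x(i))²)` (dB); per-cycle AC
   `= (Σs(i)²/N)^½` (RMS over one cardiac cycle); `STD = std(AC)` across
   cycles; `Q = mean(SNRₙ − STDₙ)` over recordings. Regions are ranked by Q
   and the top 50 retained.
4. **Time lags** — cardiac peaks with sub-frame parabolic refinement are
   matched cycle-by-cycle to the mid-forehead reference region (region 20),
   giving `Tᵢ = (1/K)·Σₖ(P_{i,k} − P_{ref,k})/fps` in milliseconds.
5. **Statistics** — mean-of-difference effect sizes with bias-corrected and
   accelerated (BCa) bootstrap 95% CIs (5000 resamples), Wilcoxon
   signed-rank tests, and one-/two-way ANOVA over the 19-meta-region-pair ×
   2-side × 18-recording design.
6. **Maps** — spectral goodness
   `G = ∫_{PR−b}^{PR+b} Y df / (∫_{B1}^{B2} Y df − ∫_{PR−b}^{PR+b} Y df)`
   with exclusion below G = 0.5; goodness-weighted AC (`G·AC`) and time-lag
   heatmaps over the face geometry.
7. **EVM** — Eulerian video magnification (Gaussian pyramid + ideal temporal
   bandpass, `output = input + α·band`) to make the pulse visible and verify
   peak ordering.

A first-class **synthetic video generator** renders a face-shaped scene in
which every triangle pulses as
`DC + A_r·w(2π·f_hr·(t−τ_r)) + B·sin(2π·f_br·t) + noise`, so heart rate,
breathing rate, per-region amplitudes `A_r` and arrival lags `τ_r` are
exactly known ground truth for validating every stage.

## Worked example

```python
import facepulse as fp

params = fp.default_params(duration_s=22.0, seed=7, noise_sd=0.5)
frames, truth = fp.generate_video(params, frame_size=(256, 256))

regions = fp.build_triangulation(truth.landmark_set)
rects = fp.build_roi_rects(regions, size=10, frame_size=frames.frame_size)
for rid in (20, 45, 90):     # forehead reference, mid cheek, chin
    raw = fp.extract_raw_signal(frames, rects[rid])
    sig = fp.RegionSignal.from_raw(rid, raw, frames.fps)
    train = fp.detect_peaks(sig.pulse, frames.fps, rid)
    q = fp.QualityMetrics.from_signal(sig, train.troughs)
    print(f"region {rid:2d}: SNR {q.snr_db:6.2f} dB  AC {q.ac_mean:.2f} counts  "
          f"Q {q.q:6.2f}  HR {q.heart_rate_bpm:.1f} bpm  "
          f"breath {q.breath_rate_bpm:.1f} bpm")
```

prints

```
region 20: SNR  12.44 dB  AC 1.62 counts  Q  12.37  HR 72.0 bpm  breath 17.8 bpm
region 45: SNR  12.50 dB  AC 1.62 counts  Q  12.43  HR 72.0 bpm  breath 17.8 bpm
region 90: SNR  11.47 dB  AC 0.81 counts  Q  11.44  HR 72.0 bpm  breath 17.9 bpm
```

The forehead (20) and mid-cheek (45) regions carry the generator's strong
3-count amplitude and rank above the chin (90, 1.5 counts); the estimated
heart and breathing rates match the imposed 72 bpm / 18 breaths per minute.
Running the full `fp.analyze_recording(...)` on the same clip recovers the
imposed −12 ms cheek-vs-forehead arrival lag to a fraction of a millisecond
(`examples/04_time_lags_and_stats.py` prints −11.84 ms) even though one
frame at 40 fps spans 25 ms — sub-frame peak refinement averaged over ~25
cardiac cycles resolves the difference.

The `examples/` directory holds one short script per capability
(simulation, geometry, signals/quality, lags/statistics, maps, EVM); each
prints the numbers it computes and what they mean. A thin CLI exposes the
same stages (`facepulse simulate | rois | extract | timelag | stats | maps
| evm | run`).

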