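# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of `facepulse`. It is the design record; every empirical
number quoted here is computed by the test suite or `scripts/acceptance.py`.

## The measurement model

Skin reflectance under green light carries a quasi-constant (DC) component
set by tissue and illumination and a small pulsatile (AC) component from the
changing arterial blood volume of each cardiac cycle. Regional iPPG treats
each facial region as its own sensor: differences in AC amplitude map
vascular density and perfusion, and differences in pulse *arrival time*
(millisecond-scale transit delays) map the propagation of the pressure
pulse across the facial vasculature. The analysis chain is therefore built
around two quantities per region: a quality-weighted AC intensity, and a
time lag against a mid-forehead reference region.

## Face geometry

The face is covered by 98 non-overlapping triangles whose vertices are
facial landmarks. Landmark *detection* is out of scope: the package ships a
hand-authored canonical template of 81 points and accepts detector output
through an adapter (`facepulse.landmarks`). The template's 61 structural
points form seven symmetric rows (hairline, mid-forehead, brow, eye line,
cheek line, mouth line, chin); strip triangulation between adjacent rows
with a shorter-diagonal sweep yields exactly 14+14+16+20+20+14 = 98
triangles that tile the landmark hull, are non-degenerate, and map onto
themselves under left-right mirroring. The remaining 20 landmarks mark eye
and mouth detail and sit strictly inside mesh triangles. A point-count
argument fixes this split: a triangulation using all 81 points as vertices
and covering their hull has 160 − h triangles (h = hull points), so 98
triangles with a plausible face outline is only reachable when some
landmarks are interior detail rather than mesh vertices.

Region ids run top-to-bottom, left-to-right within each row strip. Region
20 is the left-of-midline triangle between the mid-forehead and brow rows
("middle of the forehead"); it is the timing reference. The meta-region
table groups 19 mirror pairs (38 regions) into six anatomical areas per
side — forehead (4 pairs), nose bridge (2), mid cheek (4), nasolabial fold
(3), upper peri-oral (3), chin (3). Geometry, pairing tables, and the
meta-region table are shipped as an editable JSON data file
(`facepulse/data/face_mesh.json`), regenerable from
`facepulse.template.build_canonical_mesh()`; a test pins the file to the
builder. If the original connectivity of the published figures ever
surfaces, the data file can be replaced without code changes.

Each region is sampled by a fixed-size square ROI centred on its centroid
(top-left = round(centroid) − size/2; 80 px default at full acquisition
resolution, proportionally smaller in the synthetic test scenes).
Rectangles that leave the frame are flagged and excluded from ranking
rather than silently shrunk, so partial averages never masquerade as
regional signals. ROIs of neighbouring regions may overlap; each region's
mean is always taken over its full rectangle.

## Signal chain

* **Raw signal**: green-channel spatial mean over the ROI, one value per
  frame. Spatial averaging over thousands of pixels suppresses
  uncorrelated sensor noise and 8-bit quantization error.
* **Mean-centralization**: subtraction of a sliding-window mean, 1 s
  window. Centered windows are rounded up to odd length (41 taps at
  40 fps) so that interior samples of a linear trend map exactly to zero;
  edges use truncated windows. A trailing-window variant is available.
* **Band separation**: 5th-order Butterworth, 0.5–4 Hz for the pulse band
  and 0.2–0.5 Hz for breathing, applied forward-backward
  (`sosfiltfilt`). Zero-phase filtering is essential: the quantity of
  interest is millisecond peak timing, and a causal filter's group delay
  would bias it. The effective magnitude response is the square of one
  pass; band edges are configurable.
* **SNR** (dB): `10·log₁₀(Σf² / Σ(f−x)²)` with `f` the pulse-band signal
  and `x` the *centralized* raw signal. Using the DC-laden raw series in
  the denominator would reduce the statistic to a DC measure.
* **Per-cycle AC**: RMS of the pulse signal between consecutive troughs;
  leading/trailing partial cycles are dropped, cycles shorter than 3
  samples skipped. The peak-to-trough span per cycle is also reported as a
  diagnostic. **STD** is the standard deviation of per-cycle AC — an AC
  volatility penalty, not the sample standard deviation of the waveform.
* **Q** = mean over recordings of (SNR − STD); single recording: SNR − STD.
  Regions are ranked by Q and the top 50 analysed further.
* **Rate estimation**: Hann-windowed periodogram of the full series
  (zero-padded 8×) with log-parabolic interpolation of the in-band peak.
  At 20–30 s record lengths a single full-length segment beats Welch
  averaging on resolution, which is what a ±0.5 bpm target requires; the
  low-confidence flag instead comes from a separately computed
  segment-averaged Welch spectrum (peak < 4× median in-band power), which
  is far less noisy than the fine grid for that purpose.

## Peak timing and lags

Cardiac peaks are local maxima of the pulse-band signal with minimum
separation fps/4 (the 4 Hz band edge) and prominence ≥ 0.3× the median
candidate prominence; troughs come from the negated signal. Peaks are
refined to fractional frame indices with 3-point parabolic interpolation.
Sub-frame refinement is on by default and is not optional in spirit: at
40 fps one frame is 25 ms, while inter-region lags are ~0.2–7 ms, so
integer-frame peaks cannot resolve the scale of interest. Averaging the
refined differences over ~25–35 cycles (and over the ROI's spatial mean)
is what brings recovery error below a millisecond on synthetic data.

Matching pairs each reference peak with the nearest region peak within
half the reference's median inter-peak interval, each region peak used at
most once; K matched cycles below 3 flags the lag as low-confidence. The
lag is the *mean* matched difference, `Tᵢ = (1/K)·Σ(P_{i,k}−P_{ref,k})/fps`,
reported in ms, positive when the region trails the reference; the raw sum
is available for audit (`time_lag_sum`).

## Statistics

The statistical layer operates on per-recording regional lag samples (the
reference design: 19 meta-region pairs × 2 sides × 18 recordings).

* **Mean of difference** is the effect size for paired comparisons:
  mean(a) − mean(b).
* **BCa bootstrap** (default 5000 resamples, 95%): bias correction z₀ from
  the proportion of bootstrap statistics below the point estimate
  (clamped to [1/B, 1−1/B] to avoid infinite z₀), acceleration a from
  jackknife skewness, endpoints at the adjusted percentiles. With z₀ = a =
  0 the interval reduces to the percentile interval. All-equal samples
  yield a zero-width interval with a warning. Implemented in-package and
  cross-checked against an independent BCa implementation in the tests;
  measured coverage for the mean of 30 standard-normal samples is ~93–95%
  over 500 replications.
* **Wilcoxon signed-rank**, two-sided, zeros dropped, ties mid-ranked;
  exact null distribution up to 25 tie-free non-zero differences,
  continuity-corrected normal approximation beyond. The exact branch is
  pinned to full sign enumeration in the tests.
* **ANOVA**: one-way per face side over the 19 meta-regions (DF 18, 323 in
  the reference design) and balanced two-way side × region with
  interaction (DF 1, 18, 18 against error DF 646). Sums of squares use the
  standard balanced decomposition, computed directly and pinned to
  loop-based oracles and to an independent linear-model ANOVA in the
  tests; SSF + SSE reproduces the total sum of squares to 10⁻⁸ relative.
  Unbalanced designs are rejected rather than approximated.

## Facial maps

Goodness `G` is the ratio of PSD power within ±b of the pulse-rate
frequency PR to the remaining power in [B1, B2]. The recording-level
analysis fixes PR globally from the best-Q region (per-region argmax is unstable on
background tiles); b defaults to 0.1 Hz — wide enough to cover normal
beat-to-beat variability — and [B1, B2] to the 0.5–4 Hz pulse band, all
configurable. Integration is trapezoidal on the Welch grid (Hann, ~8 s
segments, 50% overlap) with edge interpolation and window clipping at the
band edges; a pure tone (zero out-of-window power) returns +inf. A uniform
in-band spectrum gives G = 0.2/3.3 ≈ 0.0606 at the defaults. Regions with
G < 0.5 are excluded from intensity analysis; retained regions are
weighted G·AC (using the whole-recording mean of per-cycle AC — the
per-cycle/whole-recording choice is not fixed by the underlying
definition, and the mean is the stabler of the two). The lag map inherits
the goodness exclusion mask. A grid mode computes G over a dense
fixed-size tiling of the whole frame, reproducing the face/background
contrast (synthetic scenes show median face G more than 3× background).

## Eulerian video magnification

The colour-amplification variant: per-frame Gaussian pyramid, ideal
FFT-domain temporal bandpass at the coarsest level, upsample, and
`output = input + α·band`, clipped to [0, 255] with the clipped fraction
reported (warning above 1%). A Gaussian (not Laplacian) pyramid at one
coarse level is the appropriate choice for amplifying spatially smooth
colour changes; the ideal filter is the simplest faithful temporal
selector and has exactly zero phase, so ROI-mean peak times are preserved
(< 1 frame shift measured), which is what makes the magnified video usable
to verify inter-region peak order. α = 0 is the exact identity. The
(1+α) ROI-mean gain law holds where the in-band signal is spatially
uniform at the chosen pyramid level; signal structure much smaller than
the downsampling factor is partially blurred away, which is a property of
the method, not an implementation artefact. Defaults (levels 3, band
PR ± ~0.6 Hz, α configurable) are package choices, documented rather than
inherited from any reference recording.

## Synthetic data: what it does and does not emulate

The generator renders, per pixel inside triangle r,
`DC + A_r·w(2π f_hr (t − τ_r)) + B·sin(2π f_br t) + N(0, σ²)`, background
pixels DC + noise only; frames are rendered in float, range-checked
against [0, 255] (deterministic clipping raises; noise-tail clipping is
counted and warned), then quantized to 8 bits. The default waveform is the
harmonic sum `w(θ) = 0.6·cosθ + 0.3·cos2θ + 0.1·cos3θ` — unit-bounded,
zero-mean, with a sharp systolic peak so that bandpass fidelity and peak
interpolation are genuinely exercised (at 72 bpm all three harmonics lie
inside the 0.5–4 Hz band); a raised-cosine bump is available as an
alternative. Defaults: 72 bpm, 18 breaths/min, DC 120 counts, AC
amplitudes 1.5–3 counts by area (strong forehead/cheeks, weak jaw), lags 0
to −12 ms (cheeks leading), breathing amplitude 1 count, noise 0.5
counts, 40 fps, 30 s. The AC/DC ratio of real facial skin is not well
pinned by published numbers; the chosen amplitudes give SNRs around
11–13 dB, in the range a good green-light recording achieves.

Not emulated: head motion, specular reflection, melanin/absorption
physics, illumination drift, detector jitter. Passing tests therefore
demonstrate correctness of the *analysis* under a known signal model, not
robustness to motion artefacts — the static-face assumption baked into the
first-frame ROI mask is shared by the generator and by the analysis.

For the statistical layer, generating 18 full recordings per check would
dominate runtime without adding information; `simulate_lag_samples` draws
per-recording regional lags directly around per-area means (between-
recording sd 10 ms, matching the ~10 ms spreads reported for such
designs), preserving the exact 19 × 2 × 18 design shape. Recovery of lags
from full video is validated separately on single recordings.

## Problem sizes and numerical choices

Validation scenes are scaled to what the checks need: 30 s at 40 fps and
512×512 px (ROI 20 px) for rate/lag recovery; 22 s at 256×256 for the
shared quality/map fixtures; 10 s at 128×128 for EVM. Lag-recovery
assertions evaluate regions whose rectangle lies ≥ 80% on pixels sharing
the region's own imposed lag, so rectangle spill-over across an imposed
lag boundary (a property of the synthetic piecewise-constant lag pattern,
not of the method) does not contaminate the check; 97 of 98 regions
qualify at the default geometry. Tie-breaks: quality ranking breaks ties
toward the lower region id; rasterization assigns shared triangle edges to
the lower region id; peak refinement falls back to the integer index when
the parabola degenerates. Degenerate inputs (constant series, all-zero
differences, all-equal bootstrap samples, pure-tone spectra) return
documented sentinels or warnings rather than NaNs.

## Known limitations

* Static, frontal faces only; no tracking or motion compensation.
* The canonical template is stylized; real detector output will produce
  different triangle shapes (the pipeline is geometry-agnostic, but the
  shipped meta-region anatomy labels assume roughly frontal proportions).
* Lags are relative to one reference region; no absolute pulse transit
  time (no ECG channel).
* The Wilcoxon exact/approximate switch at n = 25 and the goodness
  parameters (b, B1, B2, 0.5 threshold) are conventions, configurable but
  not data-derived.
* Breathing-rate estimation needs ≥ 20 s of signal (four periods at the
  0.2 Hz band edge).
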