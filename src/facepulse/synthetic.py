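"""Synthetic facial video with known hemodynamic ground truth.

Every pixel inside facial triangle ``r`` follows

    I(t) = DC + A_r * w(2*pi*f_hr*(t - tau_r)) + B * sin(2*pi*f_br*t) + N(0, sd^2)

where ``w`` is a periodic unit-bounded pulse waveform peaking at phase 0,
``A_r`` the per-region pulsatile (AC) amplitude in 8-bit counts, ``tau_r``
the per-region pulse arrival lag relative to the mid-forehead reference,
``B`` a respiratory intensity modulation shared by the whole face, and the
noise term white per-pixel sensor noise.  Pixels outside the face carry
``DC + noise`` only, so quality maps show a face/background contrast.
Frames are rendered in float, checked against the 8-bit range, and then
quantised to uint8 like the recorded data they emulate.

Heart rate, breathing rate, per-region amplitudes and lags are therefore
exactly recoverable ground truth for the analysis pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from skimage.draw import polygon as _sk_polygon

from .landmarks import LandmarkSet, generate_landmark_template
from .rois import MetaRegionTable, N_REGIONS, build_triangulation
from .video import FrameSequence


class ParamError(ValueError):
    """Invalid synthetic-model parameters."""


class ClippingError(RuntimeError):
    """The deterministic intensity model leaves the 8-bit range."""


def harmonic_sum(theta: np.ndarray) -> np.ndarray:
    """Default pulse waveform: 0.6 cos(t) + 0.3 cos(2t) + 0.1 cos(3t).

    Unit-bounded with a sharp systolic peak at phase 0 and zero mean, so the
    imposed ``A_r`` is exactly the peak AC excursion.
    """
    return 0.6 * np.cos(theta) + 0.3 * np.cos(2 * theta) + 0.1 * np.cos(3 * theta)


def raised_cosine(theta: np.ndarray) -> np.ndarray:
    """Alternative waveform: a raised-cosine systolic bump, ((1+cos t)/2)^2."""
    return ((1.0 + np.cos(theta)) / 2.0) ** 2


WAVEFORMS = {"harmonic": harmonic_sum, "raised_cosine": raised_cosine}


@dataclass(frozen=True)
class PulseModelParams:
    """Parameters of the synthetic intensity model.

    Defaults describe a resting adult under the acquisition settings the
    pipeline targets: 72 bpm pulse, 18 breaths/min, 40 fps, 30 s recording,
    baseline 120 counts with region AC amplitudes of a few counts.
    """

    heart_rate_hz: float = 1.2
    breath_rate_hz: float = 0.3
    dc_level: float = 120.0
    region_amplitudes: dict[int, float] = field(default_factory=dict)
    region_lags_s: dict[int, float] = field(default_factory=dict)
    breath_amplitude: float = 1.0
    noise_sd: float = 0.5
    fps: float = 40.0
    duration_s: float = 30.0
    seed: int = 0
    waveform: str = "harmonic"
    channels: str = "green"      # "green" (monochrome) or "rgb"
    reference_region: int = 20

    def validate(self) -> None:
        errs = []
        if not 0.5 <= self.heart_rate_hz <= 4.0:
            errs.append("heart_rate_hz must lie in the pulse band [0.5, 4] Hz")
        if not 0.2 <= self.breath_rate_hz <= 0.5:
            errs.append("breath_rate_hz must lie in the breathing band [0.2, 0.5] Hz")
        if self.fps <= 8.0:
            errs.append("fps must exceed 8 (Nyquist for the 4 Hz pulse-band edge)")
        if self.duration_s <= 0:
            errs.append("duration_s must be positive")
        if self.noise_sd < 0:
            errs.append("noise_sd must be non-negative")
        if self.waveform not in WAVEFORMS:
            errs.append(f"unknown waveform {self.waveform!r}; options: {sorted(WAVEFORMS)}")
        if self.channels not in ("green", "rgb"):
            errs.append(f"unknown channels {self.channels!r}")
        bad_ids = [r for r in (*self.region_amplitudes, *self.region_lags_s)
                   if not 0 <= r < N_REGIONS]
        if bad_ids:
            errs.append(f"region ids outside 0-{N_REGIONS - 1}: {sorted(set(bad_ids))}")
        if abs(self.region_lags_s.get(self.reference_region, 0.0)) > 1e-12:
            errs.append(f"reference region {self.reference_region} must have zero lag")
        max_a = max(self.region_amplitudes.values(), default=0.0)
        span = max_a + abs(self.breath_amplitude) + 5 * self.noise_sd
        if self.dc_level - span < 0 or self.dc_level + span > 255:
            errs.append("dc_level +/- (max amplitude + breathing + 5*noise_sd) "
                        "leaves the 8-bit range [0, 255]")
        if errs:
            raise ParamError("; ".join(errs))


def default_region_profile() -> tuple[dict[int, float], dict[int, float]]:
    """A realistic facial amplitude/lag pattern for all 98 regions.

    Amplitudes (counts): strong forehead and cheeks, weaker jaw; lags (s):
    cheeks lead the forehead by ~12 ms, intermediate areas in between —
    mirroring the perfusion pattern the pipeline is designed to resolve.
    """
    # per row-strip baseline (strip ranges 0-13, 14-27, 28-43, 44-63, 64-83, 84-97)
    strip_edges = [0, 14, 28, 44, 64, 84, 98]
    strip_amp = [3.0, 3.0, 2.5, 3.0, 2.0, 1.5]
    strip_lag_ms = [0.0, 0.0, -5.0, -10.0, -6.0, -2.0]
    amplitudes, lags = {}, {}
    for k in range(6):
        for rid in range(strip_edges[k], strip_edges[k + 1]):
            amplitudes[rid] = strip_amp[k]
            lags[rid] = strip_lag_ms[k] / 1000.0
    area_amp = {"forehead": 3.0, "nose_bridge": 2.5, "mid_cheek": 3.0,
                "nasolabial_fold": 2.0, "upper_perioral": 2.0, "chin": 1.5}
    area_lag_ms = {"forehead": 0.0, "nose_bridge": -5.0, "mid_cheek": -12.0,
                   "nasolabial_fold": -8.0, "upper_perioral": -4.5, "chin": -1.5}
    table = MetaRegionTable.canonical()
    for area, pairs in table.pairs_by_area.items():
        for pair in pairs:
            for rid in pair:
                amplitudes[rid] = area_amp[area]
                lags[rid] = area_lag_ms[area] / 1000.0
    lags[table.reference_region] = 0.0
    return amplitudes, lags


def default_params(**overrides) -> PulseModelParams:
    """Model parameters with the full-face default amplitude/lag profile."""
    amplitudes, lags = default_region_profile()
    params = PulseModelParams(region_amplitudes=amplitudes, region_lags_s=lags)
    return replace(params, **overrides)


@dataclass
class SyntheticGroundTruth:
    """What the generator actually imposed, for recovery checks."""

    params: PulseModelParams
    landmark_set: LandmarkSet
    region_amplitudes: dict[int, float]
    region_lags_s: dict[int, float]
    peak_times_s: dict[int, np.ndarray]     # per region, seconds
    peak_frames: dict[int, np.ndarray]      # per region, fractional frame index
    label_image: np.ndarray                 # (H, W) int16, -1 = background
    n_noise_clipped: int = 0

    def lag_vs_reference_ms(self, region_id: int) -> float:
        ref = self.region_lags_s.get(self.params.reference_region, 0.0)
        return (self.region_lags_s.get(region_id, 0.0) - ref) * 1000.0


def rasterize_regions(landmarks: LandmarkSet,
                      frame_size: tuple[int, int]) -> np.ndarray:
    """Label image assigning each pixel its triangle id (-1 = background).

    Shared triangle edges are resolved deterministically in region-id order.
    """
    w, h = frame_size
    label = np.full((h, w), -1, dtype=np.int16)
    for region in build_triangulation(landmarks):
        rr, cc = _sk_polygon(region.vertices[:, 1], region.vertices[:, 0], shape=(h, w))
        keep = label[rr, cc] == -1
        label[rr[keep], cc[keep]] = region.region_id
    return label


def generate_video(params: PulseModelParams,
                   landmarks: LandmarkSet | None = None,
                   frame_size: tuple[int, int] = (512, 512),
                   ) -> tuple[FrameSequence, SyntheticGroundTruth]:
    """Render a synthetic recording and its ground truth.

    If ``landmarks`` is omitted, the canonical template is placed to fill
    ~70% of the frame.  Bit-reproducible for a fixed seed.
    """
    params.validate()
    if landmarks is None:
        w, h = frame_size
        landmarks = generate_landmark_template(
            scale=0.62 * min(w, h), offset=(w / 2, h / 2), frame_size=frame_size)
    elif landmarks.frame_size is None:
        landmarks = LandmarkSet(landmarks.points, frame_size)

    label = rasterize_regions(landmarks, frame_size)
    n_frames = int(round(params.fps * params.duration_s))
    t = np.arange(n_frames) / params.fps
    w_fun = WAVEFORMS[params.waveform]

    # per-region deterministic signal; lookup row 0 is the background
    signals = np.zeros((n_frames, N_REGIONS + 1))
    breath = params.breath_amplitude * np.sin(2 * np.pi * params.breath_rate_hz * t)
    for rid in range(N_REGIONS):
        a = params.region_amplitudes.get(rid, 0.0)
        tau = params.region_lags_s.get(rid, 0.0)
        signals[:, rid + 1] = a * w_fun(2 * np.pi * params.heart_rate_hz * (t - tau)) + breath

    lo = params.dc_level + signals.min()
    hi = params.dc_level + signals.max()
    if lo < 0 or hi > 255:
        raise ClippingError(
            f"deterministic intensity range [{lo:.2f}, {hi:.2f}] leaves [0, 255]; "
            "reduce amplitudes or recentre dc_level")

    rng = np.random.default_rng(params.seed)
    h_px, w_px = label.shape
    lut_index = label + 1
    mono = np.empty((n_frames, h_px, w_px), dtype=np.uint8)
    n_clipped = 0
    for i in range(n_frames):
        frame = params.dc_level + signals[i][lut_index]
        if params.noise_sd > 0:
            frame = frame + rng.normal(0.0, params.noise_sd, size=frame.shape)
        n_clipped += int(np.count_nonzero((frame < 0) | (frame > 255)))
        mono[i] = np.clip(np.round(frame), 0, 255).astype(np.uint8)
    if n_clipped:
        warnings.warn(f"{n_clipped} pixel samples clipped by noise tails")

    if params.channels == "rgb":
        data = np.empty((n_frames, h_px, w_px, 3), dtype=np.uint8)
        data[..., 1] = mono
        for ch in (0, 2):   # red/blue carry baseline + independent noise only
            for i in range(n_frames):
                fr = params.dc_level + rng.normal(0.0, params.noise_sd, size=(h_px, w_px))
                data[i, ..., ch] = np.clip(np.round(fr), 0, 255).astype(np.uint8)
        frames = FrameSequence(data, fps=params.fps, channel_layout="rgb")
    else:
        frames = FrameSequence(mono, fps=params.fps, channel_layout="green")

    period = 1.0 / params.heart_rate_hz
    peak_times, peak_frames = {}, {}
    for rid in range(N_REGIONS):
        tau = params.region_lags_s.get(rid, 0.0)
        k0 = int(np.ceil(-tau / period))
        ks = np.arange(k0, k0 + int(params.duration_s / period) + 2)
        times = tau + ks * period
        times = times[(times >= 0) & (times < params.duration_s)]
        peak_times[rid] = times
        peak_frames[rid] = times * params.fps

    truth = SyntheticGroundTruth(
        params=params, landmark_set=landmarks,
        region_amplitudes={r: params.region_amplitudes.get(r, 0.0) for r in range(N_REGIONS)},
        region_lags_s={r: params.region_lags_s.get(r, 0.0) for r in range(N_REGIONS)},
        peak_times_s=peak_times, peak_frames=peak_frames,
        label_image=label, n_noise_clipped=n_clipped)
    return frames, truth


def simulate_lag_samples(area_lag_ms: dict[tuple[str, str], float],
                         n_recordings: int = 18,
                         between_sd_ms: float = 10.0,
                         seed: int = 0):
    """Per-recording regional lag samples mirroring a repeated-measures design.

    ``area_lag_ms`` maps (area, side) to the true mean lag; each meta-region
    in that area draws ``n_recordings`` independent samples around it with
    between-recording standard deviation ``between_sd_ms`` (the spread seen
    across repeated recordings).  Returns a tidy DataFrame with columns
    recording, region_id, area, side, lag_ms.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    table = MetaRegionTable.canonical()
    rows = []
    for area, pairs in table.pairs_by_area.items():
        for left, right in pairs:
            for rid, side in ((left, "left"), (right, "right")):
                mu = area_lag_ms[(area, side)]
                draws = rng.normal(mu, between_sd_ms, size=n_recordings)
                for rec, v in enumerate(draws):
                    rows.append((rec, rid, area, side, float(v)))
    return pd.DataFrame(rows, columns=["recording", "region_id", "area", "side", "lag_ms"])
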