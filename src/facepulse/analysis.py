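"""End-to-end analysis of one recording: geometry -> signals -> quality ->
time lags -> facial maps.

This is the library-level orchestration used by the command-line pipeline;
each step is also callable on its own from the underlying modules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import maps as fmaps
from . import rois, signals as fsig, timing
from .landmarks import LandmarkSet
from .video import FrameSequence


@dataclass
class AnalysisConfig:
    roi_size: int = 80
    pulse_band: tuple[float, float] = fsig.PULSE_BAND
    breath_band: tuple[float, float] = fsig.BREATH_BAND
    window_s: float = 1.0
    reference_region: int = 20
    top_n: int = 50
    goodness_b: float = 0.1
    goodness_band: tuple[float, float] = (0.5, 4.0)
    goodness_threshold: float = 0.5
    subframe_refine: bool = True


@dataclass
class RecordingAnalysis:
    """All per-recording artefacts of the regional pulse analysis."""

    config: AnalysisConfig
    regions: list[rois.TriangleRegion]
    rects: list[rois.RectROI]
    signals: dict[int, fsig.RegionSignal]
    quality: dict[int, fsig.QualityMetrics]
    top_regions: list[int]
    peak_trains: dict[int, timing.PeakTrain] = field(default_factory=dict)
    lags_ms: dict[int, float] = field(default_factory=dict)
    matched_cycles: dict[int, int] = field(default_factory=dict)
    goodness_values: dict[int, float] = field(default_factory=dict)
    pr_hz: float | None = None

    def signals_frame(self) -> pd.DataFrame:
        """Tidy per-frame table: frame, time_s, region_id, raw/centralized/
        pulse/breathing."""
        parts = []
        for rid, sig in sorted(self.signals.items()):
            n = sig.raw.size
            parts.append(pd.DataFrame({
                "frame": np.arange(n), "time_s": np.arange(n) / sig.fps,
                "region_id": rid, "raw": sig.raw, "centralized": sig.centralized,
                "pulse": sig.pulse, "breathing": sig.breathing}))
        return pd.concat(parts, ignore_index=True)

    def quality_frame(self) -> pd.DataFrame:
        rows = [(q.region_id, q.snr_db, q.ac_mean, q.std_ac, q.q,
                 q.heart_rate_bpm, q.breath_rate_bpm)
                for q in sorted(self.quality.values(), key=lambda q: q.region_id)]
        return pd.DataFrame(rows, columns=["region_id", "snr_db", "ac_mean",
                                           "std_ac", "q", "heart_rate_bpm",
                                           "breath_rate_bpm"])

    def lag_frame(self) -> pd.DataFrame:
        rows = [(rid, self.lags_ms[rid], self.matched_cycles.get(rid, 0))
                for rid in sorted(self.lags_ms)]
        return pd.DataFrame(rows, columns=["region_id", "lag_ms", "matched_cycles"])


def analyze_recording(frames: FrameSequence, landmarks: LandmarkSet,
                      config: AnalysisConfig | None = None) -> RecordingAnalysis:
    """Run the full regional analysis on one recording.

    Clipped ROIs (rectangles leaving the frame) are excluded from quality
    ranking and lag analysis.  Time lags are computed against the
    mid-forehead reference region for the top-``top_n`` regions by Q.
    """
    config = config or AnalysisConfig()
    regions = rois.build_triangulation(landmarks)
    rects = rois.build_roi_rects(regions, config.roi_size, frames.frame_size)
    usable = [r for r in rects if not r.clipped]
    if len(usable) < len(rects):
        warnings.warn(f"{len(rects) - len(usable)} ROI rectangles clipped at the "
                      "frame edge; their regions are excluded from ranking")

    region_signals: dict[int, fsig.RegionSignal] = {}
    quality: dict[int, fsig.QualityMetrics] = {}
    trains: dict[int, timing.PeakTrain] = {}
    for rect in usable:
        raw = fsig.extract_raw_signal(frames, rect)
        sig = fsig.RegionSignal.from_raw(rect.region_id, raw, frames.fps,
                                         config.pulse_band, config.breath_band,
                                         config.window_s)
        region_signals[rect.region_id] = sig
        try:
            train = timing.detect_peaks(sig.pulse, frames.fps, rect.region_id,
                                        refine=config.subframe_refine)
        except timing.TimingError:
            continue
        trains[rect.region_id] = train
        quality[rect.region_id] = fsig.QualityMetrics.from_signal(sig, train.troughs)

    q_scores = {rid: q.q for rid, q in quality.items() if np.isfinite(q.q)}
    top = rois.select_top_regions(q_scores, min(config.top_n, len(q_scores)))

    analysis = RecordingAnalysis(config, regions, rects, region_signals,
                                 quality, top, peak_trains=trains)

    ref_id = config.reference_region
    if ref_id in trains:
        ref_train = trains[ref_id]
        for rid in top:
            deltas = timing.match_peaks(trains[rid], ref_train)
            if deltas.size >= 1:
                analysis.lags_ms[rid] = timing.time_lag(deltas, frames.fps)
                analysis.matched_cycles[rid] = int(deltas.size)
    else:
        warnings.warn(f"reference region {ref_id} has no usable peak train; "
                      "lags not computed")

    # goodness with PR fixed globally from the best-Q region
    if top:
        best = top[0]
        spec = fmaps.estimate_psd(region_signals[best].pulse, frames.fps,
                                  config.goodness_band, config.goodness_b)
        analysis.pr_hz = spec.pr_hz
        for rid, sig in region_signals.items():
            s = fmaps.estimate_psd(sig.pulse, frames.fps, config.goodness_band,
                                   config.goodness_b, pr_hz=spec.pr_hz)
            analysis.goodness_values[rid] = fmaps.goodness(s)
    return analysis


def build_maps(analysis: RecordingAnalysis) -> dict[str, fmaps.FacialMap]:
    """The three facial maps (goodness, weighted AC, time lag)."""
    g = analysis.goodness_values
    gmap = fmaps.goodness_map(g, analysis.config.goodness_threshold)
    ac = {rid: q.ac_mean for rid, q in analysis.quality.items()
          if np.isfinite(q.ac_mean) and rid in g}
    acmap = fmaps.weighted_ac_map(ac, {r: g[r] for r in ac},
                                  analysis.config.goodness_threshold)
    lagmap = fmaps.time_lag_map(analysis.lags_ms,
                                excluded=gmap.excluded & set(analysis.lags_ms))
    return {"goodness": gmap, "weighted_ac": acmap, "time_lag": lagmap}


def area_lag_table(lag_samples: pd.DataFrame, n_boot: int = 5000,
                   seed: int = 0) -> pd.DataFrame:
    """Left/right comparison per anatomical area from per-recording lags.

    ``lag_samples`` is tidy with columns area, side, recording, lag_ms (as
    produced by repeated recordings or the synthetic design generator).
    For each area: left and right mean lag, the paired mean-of-difference,
    its BCa bootstrap CI, and the Wilcoxon signed-rank p value.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for area, sub in lag_samples.groupby("area", sort=False):
        piv = sub.groupby(["side", "recording"])["lag_ms"].mean().unstack("recording")
        left = piv.loc["left"].to_numpy()
        right = piv.loc["right"].to_numpy()
        mod = timing.mean_of_difference(left, right)
        ci = timing.bca_bootstrap_ci(left - right, np.mean, n_boot=n_boot, seed=rng)
        _, p = timing.wilcoxon_signed_rank(left, right)
        rows.append((area, left.mean(), right.mean(), mod, ci.lower, ci.upper, p))
    return pd.DataFrame(rows, columns=["area", "left_mean_ms", "right_mean_ms",
                                       "mean_of_difference_ms", "ci_low", "ci_high",
                                       "wilcoxon_p"])


def anova_tables(lag_samples: pd.DataFrame) -> pd.DataFrame:
    """The five-row ANOVA summary of the region x side design.

    One-way within each face side over the per-side meta-regions, then the
    balanced two-way decomposition (side, region pair, interaction).
    """
    rows = []
    for side in ("left", "right"):
        sub = lag_samples[lag_samples["side"] == side]
        groups = [g["lag_ms"].to_numpy() for _, g in sub.groupby("region_id")]
        r = timing.one_way_anova(groups, factor=f"within {side} face")
        rows.append(r)

    # balanced (side, pair, recording) cube for the two-way analysis
    piv = lag_samples.pivot_table(index=["area", "region_id"], columns="recording",
                                  values="lag_ms", aggfunc="mean")
    sides = lag_samples.set_index("region_id")["side"].to_dict()
    left_ids = sorted(r for r in piv.index.get_level_values("region_id")
                      if sides[r] == "left")
    from .rois import region_mirror_table
    mirror = region_mirror_table()
    cube = np.stack([
        np.stack([piv.xs(rid, level="region_id").to_numpy()[0] for rid in left_ids]),
        np.stack([piv.xs(int(mirror[rid]), level="region_id").to_numpy()[0]
                  for rid in left_ids]),
    ])
    rows.extend(timing.two_way_anova(cube))
    return pd.DataFrame(
        [(r.factor, r.df_fac, r.df_err, r.ssf, r.sse, r.f_value, r.p_value)
         for r in rows],
        columns=["factor", "df_fac", "df_err", "ssf", "sse", "f_value", "p_value"])
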