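"""Facial maps: pulse-quality Goodness, Goodness-weighted AC intensity,
and inter-region time-lag fields rendered on the face geometry.

Goodness of a region's signal is the ratio of spectral power concentrated
near the pulse-rate frequency to the remaining power in the pulse band,

    G = int_{PR-b}^{PR+b} Y(f) df / ( int_{B1}^{B2} Y(f) df - int_{PR-b}^{PR+b} Y(f) df ),

with Y the power spectral density, PR the pulse-rate frequency, b a
half-width (default 0.1 Hz, wide enough for normal beat-to-beat
variability) and [B1, B2] the pulse band (default 0.5-4 Hz).  Regions with
G below 0.5 carry too little pulse power and are excluded from intensity
maps; the retained regions are weighted by G*AC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .rois import TriangleRegion


class MapError(ValueError):
    pass


GOODNESS_THRESHOLD = 0.5


@dataclass(frozen=True)
class SpectrumEstimate:
    """Welch PSD of one regional signal plus the pulse-rate location."""

    frequencies: np.ndarray
    psd: np.ndarray
    pr_hz: float
    band: tuple[float, float]
    half_width_b: float


def estimate_psd(series: np.ndarray, fps: float,
                 band: tuple[float, float] = (0.5, 4.0),
                 half_width_b: float = 0.1,
                 pr_hz: float | None = None,
                 segment_s: float = 8.0) -> SpectrumEstimate:
    """Welch periodogram (Hann, ~8 s segments, 50% overlap) with the
    pulse-rate frequency PR as the in-band argmax unless fixed by caller.

    Fixing PR globally (from the best-quality region) is the default mode in
    the pipeline because the per-region argmax is unstable on noise-only
    background tiles.
    """
    series = np.asarray(series, dtype=float)
    if series.size < 10 * fps:
        raise MapError("series must span at least 10 s for a stable PSD")
    nperseg = min(series.size, int(round(segment_s * fps)))
    freqs, psd = sps.welch(series - series.mean(), fs=fps, window="hann",
                           nperseg=nperseg, noverlap=nperseg // 2, detrend=False)
    if pr_hz is None:
        sel = (freqs >= band[0]) & (freqs <= band[1])
        f_band, p_band = freqs[sel], psd[sel]
        k = int(np.argmax(p_band))
        pr_hz = float(f_band[k])
        # log-parabolic refinement of the peak bin (the Welch grid is coarse)
        if 0 < k < p_band.size - 1 and p_band[k - 1] > 0 and p_band[k + 1] > 0:
            la, lb, lc = np.log(p_band[k - 1: k + 2])
            denom = la - 2 * lb + lc
            if denom < 0:
                pr_hz += float(0.5 * (la - lc) / denom) * (f_band[1] - f_band[0])
        pr_hz = float(np.clip(pr_hz, band[0], band[1]))
    if not band[0] <= pr_hz <= band[1]:
        raise MapError(f"pulse-rate frequency {pr_hz} Hz outside band {band}")
    return SpectrumEstimate(freqs, psd, float(pr_hz), band, half_width_b)


def _band_integral(freqs: np.ndarray, psd: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoidal integral of the PSD over [lo, hi] with edge interpolation."""
    if hi <= lo:
        return 0.0
    inside = (freqs > lo) & (freqs < hi)
    f = np.concatenate(([lo], freqs[inside], [hi]))
    y = np.concatenate(([np.interp(lo, freqs, psd)], psd[inside],
                        [np.interp(hi, freqs, psd)]))
    return float(np.trapezoid(y, f))


def goodness(spec: SpectrumEstimate) -> float:
    """Goodness ratio; the integration window is clipped to the band.

    A pure tone (zero out-of-window power) yields ``+inf``.
    """
    b1, b2 = spec.band
    lo = max(b1, spec.pr_hz - spec.half_width_b)
    hi = min(b2, spec.pr_hz + spec.half_width_b)
    inside = _band_integral(spec.frequencies, spec.psd, lo, hi)
    total = _band_integral(spec.frequencies, spec.psd, b1, b2)
    outside = total - inside
    if outside <= 0:
        return np.inf
    return inside / outside


@dataclass
class FacialMap:
    """A per-region scalar field registered to the first frame."""

    kind: str                                  # goodness | weighted_ac | time_lag
    values: dict[int, float]
    excluded: set[int] = field(default_factory=set)
    color_bounds: tuple[float, float] | None = None

    def included_values(self) -> dict[int, float]:
        return {r: v for r, v in self.values.items() if r not in self.excluded}

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd
        rows = [(r, v, r in self.excluded) for r, v in sorted(self.values.items())]
        pd.DataFrame(rows, columns=["region_id", "value", "excluded"]).to_csv(
            path, index=False)

    def render(self, regions: list[TriangleRegion], path: str | Path | None = None,
               ax=None, cmap: str = "jet", background=None):
        """Draw the map as coloured triangles over the face geometry."""
        import matplotlib
        if path is not None and ax is None:
            matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        from matplotlib.collections import PolyCollection

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        if background is not None:
            ax.imshow(background, cmap="gray", vmin=0, vmax=255)
        inc = self.included_values()
        polys = [r.vertices for r in regions if r.region_id in inc]
        vals = [inc[r.region_id] for r in regions if r.region_id in inc]
        if polys:
            coll = PolyCollection(polys, array=np.asarray(vals), cmap=cmap,
                                  edgecolors="k", linewidths=0.2)
            if self.color_bounds is not None:
                coll.set_clim(*self.color_bounds)
            ax.add_collection(coll)
            plt.colorbar(coll, ax=ax, shrink=0.8)
        ax.autoscale_view()
        if background is None:
            ax.invert_yaxis()
        ax.set_aspect("equal")
        ax.set_title(self.kind)
        if path is not None:
            ax.figure.savefig(path, dpi=120, bbox_inches="tight")
            plt.close(ax.figure)
        return ax

    def save_bounds(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"kind": self.kind,
                                          "color_bounds": self.color_bounds}))


def goodness_map(goodness_values: dict[int, float],
                 threshold: float = GOODNESS_THRESHOLD) -> FacialMap:
    excluded = {r for r, g in goodness_values.items() if g < threshold}
    finite = [g for g in goodness_values.values() if np.isfinite(g)]
    bounds = (0.0, max(finite)) if finite else None
    return FacialMap("goodness", dict(goodness_values), excluded, bounds)


def weighted_ac_map(ac_values: dict[int, float],
                    goodness_values: dict[int, float],
                    threshold: float = GOODNESS_THRESHOLD) -> FacialMap:
    """G*AC per region; regions with G below the threshold are masked."""
    missing = set(ac_values) - set(goodness_values)
    if missing:
        raise MapError(f"goodness missing for regions {sorted(missing)}")
    values = {r: goodness_values[r] * ac for r, ac in ac_values.items()}
    excluded = {r for r in ac_values if goodness_values[r] < threshold}
    inc = [v for r, v in values.items() if r not in excluded]
    bounds = (0.0, max(inc)) if inc else None
    return FacialMap("weighted_ac", values, excluded, bounds)


def time_lag_map(lag_ms: dict[int, float],
                 excluded: set[int] | None = None) -> FacialMap:
    """Per-region lag (ms) vs. the reference; exclusion mask propagates
    from the goodness analysis."""
    excluded = set(excluded or ())
    inc = [v for r, v in lag_ms.items() if r not in excluded]
    bounds = (min(inc), max(inc)) if inc else None
    return FacialMap("time_lag", dict(lag_ms), excluded, bounds)


def grid_goodness(frames, tile: int = 40,
                  band: tuple[float, float] = (0.5, 4.0),
                  half_width_b: float = 0.1,
                  pr_hz: float | None = None) -> np.ndarray:
    """Goodness over a dense rectangular tiling of the whole frame.

    Covers background as well as the face, reproducing the
    face-versus-background contrast of quality imaging.  Returns a 2-D array
    of G values, one per tile.
    """
    stack = frames.green().astype(float)
    t, h, w = stack.shape
    ny, nx = h // tile, w // tile
    out = np.full((ny, nx), np.nan)
    for iy in range(ny):
        for ix in range(nx):
            series = stack[:, iy * tile:(iy + 1) * tile,
                           ix * tile:(ix + 1) * tile].mean(axis=(1, 2))
            spec = estimate_psd(series, frames.fps, band, half_width_b, pr_hz=pr_hz)
            out[iy, ix] = goodness(spec)
    return out
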