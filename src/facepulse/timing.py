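"""Cardiac peak timing, inter-region time lags, and the statistical layer.

The time lag of region *i* against the mid-forehead reference is the mean
peak-arrival-time difference over matched cardiac cycles,

    T_i = (1/K) * sum_k (P_{i,k} - P_{ref,k}) / fps   (reported in ms),

positive when the region's pulse arrives later than the reference.  At
40 fps one frame spans 25 ms while inter-region lags are single-digit
milliseconds, so peaks are refined to fractional frame indices by 3-point
parabolic interpolation before differencing; without sub-frame refinement
the statistic cannot resolve the scale of interest.

The statistical layer operates on per-recording regional lag samples:
mean-of-difference effect sizes with bias-corrected and accelerated (BCa)
bootstrap confidence intervals, Wilcoxon signed-rank tests for paired
regions, and one-/two-way ANOVA over the region x face-side design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import stats as st


class TimingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# peak detection and matching

@dataclass
class PeakTrain:
    """Refined cardiac peak/trough locations for one region."""

    region_id: int
    peaks: np.ndarray      # fractional frame indices, strictly increasing
    troughs: np.ndarray
    fps: float

    @property
    def median_interval(self) -> float:
        return float(np.median(np.diff(self.peaks)))


def _parabolic_refine(series: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Sub-sample extremum location via a parabola through three points."""
    refined = idx.astype(float).copy()
    for j, i in enumerate(idx):
        if 0 < i < series.size - 1:
            a, b, c = series[i - 1], series[i], series[i + 1]
            denom = a - 2 * b + c
            if denom != 0:
                delta = 0.5 * (a - c) / denom
                if abs(delta) <= 1:
                    refined[j] = i + delta
    return refined


def detect_peaks(pulse: np.ndarray, fps: float, region_id: int = -1,
                 refine: bool = True,
                 prominence_factor: float = 0.3) -> PeakTrain:
    """Local maxima/minima of the pulse-band signal as a cardiac peak train.

    Candidate peaks are separated by at least fps/4 frames (the 4 Hz band
    edge) and must reach a prominence of ``prominence_factor`` times the
    median candidate prominence, which suppresses noise riders without a
    fixed amplitude threshold.  Troughs are detected on the negated signal.
    """
    pulse = np.asarray(pulse, dtype=float)
    min_dist = max(1, int(round(fps / 4.0)))

    def _find(x: np.ndarray) -> np.ndarray:
        cand, props = sps.find_peaks(x, distance=min_dist, prominence=0.0)
        if cand.size == 0:
            return cand
        keep = props["prominences"] >= prominence_factor * np.median(props["prominences"])
        cand = cand[keep]
        return _parabolic_refine(x, cand) if refine else cand.astype(float)

    peaks = _find(pulse)
    troughs = _find(-pulse)
    if peaks.size < 2:
        raise TimingError(
            f"fewer than 2 cardiac peaks found (region {region_id}); "
            "signal may be degenerate or too short")
    return PeakTrain(region_id, peaks, troughs, fps)


def match_peaks(train: PeakTrain, reference: PeakTrain) -> np.ndarray:
    """Pair each reference peak with the nearest region peak.

    A region peak qualifies when it lies within half the reference's median
    inter-peak interval; each region peak is used at most once (the closer
    reference peak wins).  Returns the matched differences
    ``P_region - P_ref`` in frames; K = len(result).
    """
    if train.peaks.size == 0 or reference.peaks.size == 0:
        raise TimingError("cannot match empty peak trains")
    tol = reference.median_interval / 2.0
    deltas = []
    used = np.zeros(train.peaks.size, dtype=bool)
    for p_ref in reference.peaks:
        j = int(np.argmin(np.abs(train.peaks - p_ref)))
        d = train.peaks[j] - p_ref
        if abs(d) <= tol and not used[j]:
            used[j] = True
            deltas.append(d)
    deltas = np.asarray(deltas)
    if deltas.size < 3:
        warnings.warn(f"only {deltas.size} matched cycles for region "
                      f"{train.region_id}: lag is low-confidence")
    return deltas


def time_lag(matched_deltas: np.ndarray, fps: float) -> float:
    """Mean matched peak difference converted to milliseconds."""
    d = np.asarray(matched_deltas, dtype=float)
    if d.size < 1:
        raise TimingError("need at least one matched cycle")
    return float(d.mean() / fps * 1000.0)


def time_lag_sum(matched_deltas: np.ndarray, fps: float) -> float:
    """Un-normalised sum of matched differences in ms (audit variant)."""
    return float(np.sum(matched_deltas) / fps * 1000.0)


# ---------------------------------------------------------------------------
# effect size, bootstrap, rank test

def mean_of_difference(samples_a: np.ndarray, samples_b: np.ndarray) -> float:
    """Effect size for paired regional lag samples: mean(a) - mean(b)."""
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.shape != b.shape:
        raise TimingError("paired samples must have equal length")
    return float(a.mean() - b.mean())


@dataclass(frozen=True)
class BootstrapCI:
    point: float
    lower: float
    upper: float
    level: float
    n_boot: int
    z0: float
    acceleration: float


def bca_bootstrap_ci(samples: np.ndarray, statistic=np.mean,
                     n_boot: int = 5000, level: float = 0.95,
                     seed: int | np.random.Generator = 0) -> BootstrapCI:
    """Bias-corrected and accelerated bootstrap interval for a statistic.

    z0 comes from the proportion of bootstrap statistics below the point
    estimate, the acceleration from jackknife skewness; the endpoints are
    the correspondingly adjusted percentiles of the bootstrap distribution.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 8:
        raise TimingError("BCa bootstrap needs at least 8 samples")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    theta = float(statistic(x))

    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    if statistic is np.mean:
        boots = x[idx].mean(axis=1)
    else:
        boots = np.array([statistic(x[row]) for row in idx])

    if np.ptp(x) == 0:
        warnings.warn("degenerate samples (all equal): zero-width interval")
        return BootstrapCI(theta, theta, theta, level, n_boot, 0.0, 0.0)

    prop = np.mean(boots < theta)
    prop = min(max(prop, 1.0 / n_boot), 1.0 - 1.0 / n_boot)   # guard infinite z0
    z0 = st.norm.ppf(prop)

    jack = np.array([statistic(np.delete(x, i)) for i in range(x.size)])
    d = jack.mean() - jack
    denom = 6.0 * np.sum(d * d) ** 1.5
    a = float(np.sum(d ** 3) / denom) if denom > 0 else 0.0

    alpha = (1.0 - level) / 2.0
    lo_hi = []
    for q in (alpha, 1.0 - alpha):
        z = z0 + st.norm.ppf(q)
        adj = st.norm.cdf(z0 + z / (1.0 - a * z))
        lo_hi.append(float(np.quantile(boots, adj)))
    return BootstrapCI(theta, lo_hi[0], lo_hi[1], level, n_boot, float(z0), a)


def wilcoxon_signed_rank(a: np.ndarray, b: np.ndarray,
                         exact_max_n: int = 25) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped, ties mid-ranked; the exact null
    distribution is used up to ``exact_max_n`` non-zero differences (when
    tie-free), the continuity-corrected normal approximation beyond.
    Returns ``(statistic, p)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise TimingError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; p = 1")
        return 0.0, 1.0
    has_ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= exact_max_n and not has_ties) else "approx"
    res = st.wilcoxon(d, alternative="two-sided", zero_method="wilcox",
                      correction=(method == "approx"), method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# ANOVA over the region x side design

@dataclass(frozen=True)
class AnovaRow:
    factor: str
    df_fac: int
    df_err: int
    ssf: float
    sse: float
    f_value: float
    p_value: float


def one_way_anova(groups: list[np.ndarray], factor: str = "region") -> AnovaRow:
    """Single-factor ANOVA: SSF/SSE decomposition, F = MSF/MSE."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise TimingError("need at least 2 groups with at least 2 samples each")
    allx = np.concatenate(groups)
    grand = allx.mean()
    ssf = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    sse = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    df_fac = len(groups) - 1
    df_err = allx.size - len(groups)
    f = (ssf / df_fac) / (sse / df_err)
    p = float(st.f.sf(f, df_fac, df_err))
    return AnovaRow(factor, df_fac, df_err, float(ssf), float(sse), float(f), p)


def two_way_anova(values: np.ndarray) -> list[AnovaRow]:
    """Balanced two-factor ANOVA with interaction.

    ``values`` has shape ``(a, b, n)``: factor A (face side, a=2), factor B
    (region, b=19 in the reference design), n replicates per cell.  Returns
    rows for A, B, the interaction, all sharing the interaction-model error
    term with ``df_err = a*b*(n-1)``.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 3:
        raise TimingError("expected a (sides, regions, replicates) array; "
                          "unbalanced designs are not supported")
    a, b, n = v.shape
    if n < 2:
        raise TimingError("need at least 2 replicates per cell")
    grand = v.mean()
    mean_a = v.mean(axis=(1, 2))
    mean_b = v.mean(axis=(0, 2))
    mean_ab = v.mean(axis=2)
    ss_a = b * n * float(np.sum((mean_a - grand) ** 2))
    ss_b = a * n * float(np.sum((mean_b - grand) ** 2))
    ss_ab = n * float(np.sum((mean_ab - mean_a[:, None] - mean_b[None, :] + grand) ** 2))
    ss_e = float(np.sum((v - mean_ab[..., None]) ** 2))
    df_err = a * b * (n - 1)
    rows = []
    for name, ss, df in (("side", ss_a, a - 1), ("region", ss_b, b - 1),
                         ("side x region", ss_ab, (a - 1) * (b - 1))):
        f = (ss / df) / (ss_e / df_err)
        rows.append(AnovaRow(name, df, df_err, ss, ss_e, float(f),
                             float(st.f.sf(f, df, df_err))))
    return rows


def total_sum_of_squares(values: np.ndarray) -> float:
    v = np.asarray(values, dtype=float).ravel()
    return float(np.sum((v - v.mean()) ** 2))
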