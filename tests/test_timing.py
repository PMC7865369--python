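"""Peak detection, peak matching, time lags, and the statistical layer
(BCa bootstrap, Wilcoxon signed-rank, one-/two-way ANOVA)."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st_h
from scipy import stats as st

import facepulse as fp
from facepulse.synthetic import harmonic_sum
from facepulse.timing import TimingError, total_sum_of_squares


class TestDetectPeaks:
    def test_counts_and_spacing_on_clean_pulse(self):
        fps = 40.0
        t = np.arange(int(30 * fps)) / fps
        pulse = harmonic_sum(2 * np.pi * 1.0 * t)
        train = fp.detect_peaks(pulse, fps)
        assert 29 <= train.peaks.size <= 30
        np.testing.assert_allclose(np.diff(train.peaks), 40.0, atol=0.2)

    def test_rising_ramp_is_degenerate(self):
        with pytest.raises(TimingError):
            fp.detect_peaks(np.linspace(0, 1, 400), 40.0)

    def test_parabolic_refinement_recovers_fractional_peak(self):
        # analytic pulse with a peak at exactly 31.5 frames
        fps = 40.0
        t = np.arange(int(10 * fps)) / fps
        pulse = harmonic_sum(2 * np.pi * 1.0 * (t - 31.5 / fps))
        train = fp.detect_peaks(pulse, fps)
        nearest = train.peaks[np.argmin(np.abs(train.peaks - 31.5))]
        assert nearest == pytest.approx(31.5, abs=0.2)

    def test_troughs_alternate_with_peaks(self):
        fps = 40.0
        t = np.arange(1200) / fps
        train = fp.detect_peaks(harmonic_sum(2 * np.pi * 1.2 * t), fps)
        interior = train.troughs[(train.troughs > train.peaks[0])
                                 & (train.troughs < train.peaks[-1])]
        assert interior.size == train.peaks.size - 1


class TestMatchPeaks:
    def _train(self, peaks, rid=0):
        return fp.PeakTrain(rid, np.asarray(peaks, float), np.array([]), 40.0)

    def test_identical_trains_self_match(self):
        t = self._train([40, 80, 120, 160])
        deltas = fp.match_peaks(t, t)
        assert deltas.size == 4
        np.testing.assert_allclose(deltas, 0.0)

    def test_constant_shift_preserved(self):
        ref = self._train([40, 80, 120, 160])
        shifted = self._train([42, 82, 122, 162], rid=1)
        np.testing.assert_allclose(fp.match_peaks(shifted, ref), 2.0)

    def test_missing_peak_drops_pair_without_mispairing(self):
        ref_peaks = np.array([40.0, 80, 120, 160, 200])
        region_peaks = np.delete(ref_peaks, 2) + 1.0
        deltas = fp.match_peaks(self._train(region_peaks, 1), self._train(ref_peaks))
        # brute-force nearest assignment oracle
        tol = np.median(np.diff(ref_peaks)) / 2
        expected = []
        used = set()
        for p in ref_peaks:
            j = int(np.argmin(np.abs(region_peaks - p)))
            if abs(region_peaks[j] - p) <= tol and j not in used:
                used.add(j)
                expected.append(region_peaks[j] - p)
        np.testing.assert_allclose(np.sort(deltas), np.sort(expected))
        assert deltas.size == ref_peaks.size - 1

    def test_few_matches_warn(self):
        with pytest.warns(UserWarning, match="low-confidence"):
            fp.match_peaks(self._train([40, 80]), self._train([40, 80]))


class TestTimeLag:
    def test_two_frames_at_40fps_is_50ms(self):
        assert fp.time_lag(np.array([2.0, 2.0, 2.0]), 40.0) == pytest.approx(50.0)

    def test_cancellation(self):
        assert fp.time_lag(np.array([1.0, -1.0]), 40.0) == pytest.approx(0.0)

    @given(st_h.lists(st_h.floats(-5, 5), min_size=1, max_size=20))
    def test_mean_convention(self, deltas):
        d = np.asarray(deltas)
        assert fp.time_lag(d, 40.0) == pytest.approx(d.mean() / 40.0 * 1000.0)


class TestMeanOfDifference:
    @pytest.mark.parametrize("a, b, expected", [
        (-0.620, -2.245, 1.625),     # largest left/right gap (chin)
        (-4.291, -4.492, 0.201),     # smallest (upper peri-oral)
        (-0.9, 6.2, -7.1),           # forehead left vs right
    ])
    def test_reported_arithmetic(self, a, b, expected):
        assert fp.mean_of_difference([a], [b]) == pytest.approx(expected)

    def test_identity(self, rng):
        x = rng.normal(size=18)
        assert fp.mean_of_difference(x, x) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(TimingError):
            fp.mean_of_difference([1.0], [1.0, 2.0])


class TestBCaBootstrap:
    def test_symmetric_samples_close_to_percentile_interval(self, rng):
        x = rng.normal(0, 1, size=60)
        ci = fp.bca_bootstrap_ci(x, np.mean, n_boot=5000, seed=42)
        # rebuild the same bootstrap distribution with the identical rng stream
        rng2 = np.random.default_rng(42)
        idx = rng2.integers(0, x.size, size=(5000, x.size))
        boots = x[idx].mean(axis=1)
        lo, hi = np.quantile(boots, [0.025, 0.975])
        se = x.std() / np.sqrt(x.size)
        assert ci.lower == pytest.approx(lo, abs=0.2 * se)
        assert ci.upper == pytest.approx(hi, abs=0.2 * se)
        assert abs(ci.z0) < 0.1 and abs(ci.acceleration) < 0.05

    def test_degenerate_samples_zero_width(self):
        with pytest.warns(UserWarning, match="degenerate"):
            ci = fp.bca_bootstrap_ci(np.full(10, 7.0), np.mean, seed=0)
        assert (ci.lower, ci.upper) == (7.0, 7.0)

    def test_seeded_reproducibility(self, rng):
        x = rng.exponential(size=30)
        a = fp.bca_bootstrap_ci(x, np.mean, seed=5)
        b = fp.bca_bootstrap_ci(x, np.mean, seed=5)
        assert (a.lower, a.upper) == (b.lower, b.upper)

    def test_agrees_with_scipy_bca(self, rng):
        x = rng.gamma(2.0, size=40)
        ci = fp.bca_bootstrap_ci(x, np.mean, n_boot=9999, seed=3)
        res = st.bootstrap((x,), np.mean, n_resamples=9999, method="BCa",
                           confidence_level=0.95, random_state=7)
        se = x.std() / np.sqrt(x.size)
        assert ci.lower == pytest.approx(res.confidence_interval.low, abs=0.25 * se)
        assert ci.upper == pytest.approx(res.confidence_interval.high, abs=0.25 * se)

    def test_too_few_samples_rejected(self):
        with pytest.raises(TimingError):
            fp.bca_bootstrap_ci(np.arange(5.0), np.mean)


class TestWilcoxon:
    def test_exact_p_matches_sign_enumeration_n6(self):
        a = np.array([1.0, 2, 3, 4, 5, 6])
        b = np.zeros(6)
        stat, p = fp.wilcoxon_signed_rank(a, b)
        # enumerate all 2^6 sign assignments of ranks 1..6
        ranks = np.arange(1, 7)
        w_obs = ranks.sum()  # all positive
        w_plus = [sum(r for r, s in zip(ranks, signs) if s)
                  for signs in itertools.product([0, 1], repeat=6)]
        w_plus = np.array(w_plus)
        mu = ranks.sum() / 2
        p_exact = np.mean(np.abs(w_plus - mu) >= abs(w_obs - mu))
        assert p_exact == pytest.approx(2 / 64)
        assert p == pytest.approx(p_exact, rel=1e-12)

    def test_equal_pairs_give_p_one(self):
        with pytest.warns(UserWarning, match="zero"):
            _, p = fp.wilcoxon_signed_rank(np.ones(8), np.ones(8))
        assert p == 1.0

    def test_power_against_one_sigma_shift(self):
        rng = np.random.default_rng(77)
        rejections = 0
        for _ in range(200):
            a = rng.normal(1.0, 1.0, size=18)
            b = rng.normal(0.0, 1.0, size=18)
            _, p = fp.wilcoxon_signed_rank(a, b)
            rejections += p < 0.05
        assert rejections / 200 > 0.60

    def test_large_n_uses_normal_approximation(self, rng):
        a = rng.normal(0.3, 1, size=40)
        b = rng.normal(0.0, 1, size=40)
        _, p = fp.wilcoxon_signed_rank(a, b)
        ref = st.wilcoxon(a - b, correction=True, method="approx")
        assert p == pytest.approx(ref.pvalue)


def _oneway_oracle(groups):
    allx = np.concatenate(groups)
    grand = sum(allx) / len(allx)
    ssf = sse = 0.0
    for g in groups:
        m = sum(g) / len(g)
        ssf += len(g) * (m - grand) ** 2
        for v in g:
            sse += (v - m) ** 2
    return ssf, sse


class TestOneWayAnova:
    def test_reference_design_degrees_of_freedom(self, rng):
        groups = [rng.normal(size=18) for _ in range(19)]
        row = fp.one_way_anova(groups)
        assert (row.df_fac, row.df_err) == (18, 323)

    def test_identical_group_means_give_zero_f(self):
        g = np.array([1.0, -1.0, 0.5, -0.5])
        row = fp.one_way_anova([g, g + 0, g.copy()])
        assert row.ssf == pytest.approx(0.0, abs=1e-12)

    def test_matches_loop_oracle(self, rng):
        groups = [rng.normal(m, 1 + m / 4, size=12) for m in range(3)]
        row = fp.one_way_anova(groups)
        ssf, sse = _oneway_oracle(groups)
        assert row.ssf == pytest.approx(ssf, rel=1e-10)
        assert row.sse == pytest.approx(sse, rel=1e-10)
        # cross-check p against scipy's F one-way
        ref = st.f_oneway(*groups)
        assert row.f_value == pytest.approx(ref.statistic, rel=1e-10)
        assert row.p_value == pytest.approx(ref.pvalue, rel=1e-8)

    def test_decomposition_identity(self, rng):
        groups = [rng.normal(m, 1, size=7) for m in range(4)]
        row = fp.one_way_anova(groups)
        sst = total_sum_of_squares(np.concatenate(groups))
        assert row.ssf + row.sse == pytest.approx(sst, rel=1e-10)


class TestTwoWayAnova:
    def test_reference_design_degrees_of_freedom(self, rng):
        cube = rng.normal(size=(2, 19, 18))
        rows = fp.two_way_anova(cube)
        by = {r.factor: r for r in rows}
        assert by["side"].df_fac == 1
        assert by["region"].df_fac == 18
        assert by["side x region"].df_fac == 18
        assert all(r.df_err == 646 for r in rows)

    def test_sums_of_squares_decompose_total(self, rng):
        cube = rng.normal(size=(2, 5, 6))
        rows = fp.two_way_anova(cube)
        ss = sum(r.ssf for r in rows) + rows[0].sse
        assert ss == pytest.approx(total_sum_of_squares(cube), rel=1e-8)

    def test_matches_statsmodels(self, rng):
        import pandas as pd
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        cube = rng.normal(size=(2, 4, 5)) + np.arange(4)[None, :, None]
        rows = {r.factor: r for r in fp.two_way_anova(cube)}
        recs = [(s, r, cube[s, r, k]) for s in range(2) for r in range(4)
                for k in range(5)]
        df = pd.DataFrame(recs, columns=["side", "region", "y"])
        fit = ols("y ~ C(side) * C(region)", data=df).fit()
        table = sm.stats.anova_lm(fit, typ=2)
        assert rows["side"].ssf == pytest.approx(table.loc["C(side)", "sum_sq"], rel=1e-8)
        assert rows["region"].ssf == pytest.approx(table.loc["C(region)", "sum_sq"], rel=1e-8)
        assert rows["side x region"].ssf == pytest.approx(
            table.loc["C(side):C(region)", "sum_sq"], rel=1e-8)
        assert rows["side"].p_value == pytest.approx(table.loc["C(side)", "PR(>F)"], rel=1e-6)

    def test_null_interaction_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(2024)
        rejections = 0
        n_sims = 200
        for _ in range(n_sims):
            # additive model: side and region effects, no interaction
            side = rng.normal(0, 1, size=(2, 1, 1))
            region = rng.normal(0, 1, size=(1, 6, 1))
            cube = side + region + rng.normal(0, 1, size=(2, 6, 8))
            rows = {r.factor: r for r in fp.two_way_anova(cube)}
            rejections += rows["side x region"].p_value < 0.05
        assert 0.01 <= rejections / n_sims <= 0.10

    def test_unbalanced_design_rejected(self):
        with pytest.raises(TimingError):
            fp.two_way_anova(np.zeros((2, 3)))
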