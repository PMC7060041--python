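"""Pair-level MVR statistics: geometry, regressions, controls."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mvrmap import mvrstats, synthkit
from mvrmap.errors import ParameterError


def make_pair(xy_a=(0.0, 50.0), xy_b=(0.0, 150.0), amp_a=100.0, amp_b=80.0,
              center=(0.0, 0.0), pid="p0"):
    return mvrstats.characterize_mvr_pair(
        pid, "b0", 0, xy_a, xy_b, amp_a, amp_b, center
    )


class TestCharacterizePair:
    def test_equal_amplitudes_tie_flagged(self):
        p = make_pair(amp_a=100.0, amp_b=100.0)
        assert p.amp_diff_pct == 0.0
        assert p.amplitude_tie
        assert p.proximal_index == 0  # nearer member

    def test_amp_diff_and_proximal_assignment(self):
        p = make_pair(xy_a=(0.0, 50.0), xy_b=(0.0, 200.0), amp_a=100.0, amp_b=80.0)
        assert p.amp_diff_pct == pytest.approx(20.0)
        assert p.proximal_index == 0
        assert p.larger_is_proximal
        assert p.separation == pytest.approx(150.0)

    def test_cross_bouton_pair_rejected(self):
        with pytest.raises(ParameterError):
            mvrstats.characterize_mvr_pair(
                "p", "b0", 0, (0, 0), (1, 1), 10, 10, (0, 0), bouton_id_b="b1"
            )

    def test_midpoint_distance_matches_direct_geometry(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            a, b, c = rng.uniform(-500, 500, (3, 2))
            p = mvrstats.characterize_mvr_pair("p", "b", 0, a, b, 10, 20, c)
            assert p.midpoint_dist_to_center == pytest.approx(
                float(np.hypot(*((a + b) / 2 - c))), abs=1e-9
            )
            assert p.separation == pytest.approx(float(np.hypot(*(a - b))), abs=1e-9)

    def test_invariance_under_rigid_motion(self):
        rng = np.random.default_rng(2)
        a, b, c = rng.uniform(-500, 500, (3, 2))
        th = 1.1
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        t = np.array([77.0, -33.0])
        p1 = mvrstats.characterize_mvr_pair("p", "b", 0, a, b, 10, 20, c)
        p2 = mvrstats.characterize_mvr_pair("p", "b", 0, a @ R.T + t, b @ R.T + t,
                                            10, 20, c @ R.T + t)
        assert p2.separation == pytest.approx(p1.separation)
        assert p2.amp_diff_pct == pytest.approx(p1.amp_diff_pct)
        assert p2.midpoint_dist_to_center == pytest.approx(p1.midpoint_dist_to_center)


class TestAmpDiffRegression:
    def _pairs_on_line(self, slope, intercept, n=50, noise_sd=0.0, seed=0):
        rng = np.random.default_rng(seed)
        seps = rng.uniform(100, 600, n)
        pairs = []
        for i, s in enumerate(seps):
            diff = intercept + slope * s + rng.normal(0, noise_sd)
            diff = float(np.clip(diff, 0.0, 99.0))
            amp_a = 100.0
            amp_b = amp_a * (1 - diff / 100.0)
            pairs.append(mvrstats.characterize_mvr_pair(
                f"p{i}", "b", i, (0.0, 0.0), (s, 0.0), amp_a, max(amp_b, 1e-3),
                (0.0, 0.0),
            ))
        return pairs

    def test_exact_line_recovered(self):
        pairs = self._pairs_on_line(0.02106, 3.108)
        fit = mvrstats.amp_diff_vs_separation_fit(pairs)
        assert fit.slope == pytest.approx(0.02106, abs=1e-9)
        assert fit.intercept == pytest.approx(3.108, abs=1e-7)

    def test_constant_diff_zero_slope(self):
        pairs = self._pairs_on_line(0.0, 10.0)
        fit = mvrstats.amp_diff_vs_separation_fit(pairs)
        assert fit.slope == pytest.approx(0.0, abs=1e-9)

    def test_identical_separations_rejected(self):
        pairs = [make_pair(pid=f"p{i}") for i in range(5)]
        with pytest.raises(ParameterError):
            mvrstats.amp_diff_vs_separation_fit(pairs)

    def test_ci_coverage_of_generative_slope(self):
        # noisy generation at the reference coefficients, n=245 per seed:
        # the 95% CI covers the true slope in >= 93/100 seeds
        covered = 0
        for seed in range(100):
            pairs = self._pairs_on_line(0.02106, 3.108, n=245, noise_sd=2.0,
                                        seed=seed)
            fit = mvrstats.amp_diff_vs_separation_fit(pairs)
            lo, hi = fit.slope_ci()
            covered += lo <= 0.02106 <= hi
        assert covered >= 93


class TestSlopeComparison:
    def test_identical_groups_nonsignificant(self):
        rng = np.random.default_rng(3)
        pairs = TestAmpDiffRegression()._pairs_on_line(0.02, 3.0, n=100,
                                                       noise_sd=5.0, seed=3)
        res = mvrstats.compare_regression_slopes(pairs, pairs)
        assert res.p_value > 0.5

    def test_covariate_rescaling_preserves_p_value(self):
        a = TestAmpDiffRegression()._pairs_on_line(0.02, 3.0, n=80, noise_sd=5.0,
                                                   seed=4)
        b = TestAmpDiffRegression()._pairs_on_line(0.005, 8.0, n=80, noise_sd=5.0,
                                                   seed=5)
        res1 = mvrstats.compare_regression_slopes(a, b)

        def scale(pairs, k):
            return [
                mvrstats.characterize_mvr_pair(
                    p.pair_id, p.bouton_id, p.stimulus_index,
                    (p.xy_a[0] * k, p.xy_a[1] * k), (p.xy_b[0] * k, p.xy_b[1] * k),
                    p.amp_a, p.amp_b, (0.0, 0.0),
                )
                for p in pairs
            ]

        res2 = mvrstats.compare_regression_slopes(scale(a, 2.0), scale(b, 2.0))
        assert res2.p_value == pytest.approx(res1.p_value, rel=1e-6)
        assert res2.extra["slope_a"] == pytest.approx(res1.extra["slope_a"] / 2)


class TestSeparationFractions:
    def test_all_below(self):
        pairs = [make_pair(xy_b=(0.0, 150.0), pid=f"p{i}") for i in range(4)]
        assert mvrstats.separation_fraction_below(pairs, [600.0]) == [1.0]

    def test_strict_threshold(self):
        p1 = make_pair(xy_a=(0.0, 0.0), xy_b=(100.0, 0.0), pid="a")
        p2 = make_pair(xy_a=(0.0, 0.0), xy_b=(700.0, 0.0), pid="b")
        assert mvrstats.separation_fraction_below([p1, p2], [600.0]) == [0.5]
        # boundary: exactly 600 nm is NOT below 600 (strict <)
        p3 = make_pair(xy_a=(0.0, 0.0), xy_b=(600.0, 0.0), pid="c")
        assert mvrstats.separation_fraction_below([p3], [600.0]) == [0.0]


class TestLargerEventPosition:
    def _pairs_with_split(self, n_prox, n_dist):
        pairs = []
        for i in range(n_prox):
            pairs.append(make_pair(xy_a=(0.0, 50.0), xy_b=(0.0, 200.0),
                                   amp_a=100.0, amp_b=80.0, pid=f"p{i}"))
        for i in range(n_dist):
            pairs.append(make_pair(xy_a=(0.0, 50.0), xy_b=(0.0, 200.0),
                                   amp_a=80.0, amp_b=100.0, pid=f"d{i}"))
        return pairs

    def test_even_split_not_significant(self):
        res = mvrstats.larger_event_position_test(self._pairs_with_split(50, 50))
        assert res.p_value > 0.9

    def test_biased_split_highly_significant(self):
        # 70/30 at n=245: chi2 = (171.5-122.5)^2/122.5 * 2 -> p << 0.001
        res = mvrstats.larger_event_position_test(self._pairs_with_split(172, 73))
        assert res.p_value < 1e-3
        assert res.extra["fraction_larger_proximal"] > 0.5

    def test_all_tied_rejected(self):
        tied = [make_pair(amp_a=100.0, amp_b=100.0, pid=f"t{i}") for i in range(20)]
        with pytest.raises(ParameterError):
            mvrstats.larger_event_position_test(tied)


class TestTrainTrend:
    def _events(self, probs, n_boutons=30, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for b in range(n_boutons):
            for s, p in enumerate(probs):
                if rng.random() < 0.3:
                    double = rng.random() < p
                    pid = f"b{b}-s{s}" if double else ""
                    rows.append((f"b{b}", s, pid))
                    if double:
                        rows.append((f"b{b}", s, pid))
        return pd.DataFrame(rows, columns=["bouton_id", "stimulus_index", "pair_id"])

    def test_increasing_rate_detected(self):
        probs = np.linspace(0.0, 0.8, 60)
        fit = mvrstats.double_event_train_trend(self._events(probs, seed=1))
        assert fit.slope > 0
        assert fit.p_value < 0.01

    def test_single_stimulus_rejected(self):
        df = pd.DataFrame({"bouton_id": ["b0"], "stimulus_index": [0],
                           "pair_id": [""]})
        with pytest.raises(ParameterError):
            mvrstats.double_event_train_trend(df)


class TestAsynchronousControl:
    def test_identical_samples_statistic_zero(self):
        x = np.linspace(50, 150, 50)
        res = mvrstats.asynchronous_amplitude_control(x, x.copy())
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_strontium_amplitudes_left_shifted(self, acq):
        # synchronous (delay 0) vs asynchronous (uniform intra-frame delays)
        sync_amps, async_amps = [], []
        for seed in range(12):
            b = synthkit.make_bouton_model(180, 8, 0.5, 0.4, seed=seed)
            sync_amps += [e.amplitude for e in synthkit.sample_release_sequence(
                b, acq, mvr_fraction=0.0, desync_sd_ms=0.0, seed=seed)]
            b_sr = synthkit.make_bouton_model(
                180, 8, 0.5, 0.4, condition="strontium", seed=seed)
            async_amps += [e.amplitude for e in synthkit.sample_release_sequence(
                b_sr, acq, mvr_fraction=0.0, seed=900 + seed)]
        sync_amps, async_amps = np.array(sync_amps[:500]), np.array(async_amps[:500])
        assert len(sync_amps) == len(async_amps) == 500
        res = mvrstats.asynchronous_amplitude_control(sync_amps, async_amps)
        assert res.p_value < 0.01
        assert res.extra["median_async"] < res.extra["median_sync"]
        # E[remaining-frame fraction] = 1/2 under uniform delays
        ratio = res.extra["median_async"] / res.extra["median_sync"]
        assert ratio == pytest.approx(0.5, abs=0.1)
        # asynchronous amplitudes are non-Gaussian (mass spread toward 0)
        assert sps.normaltest(async_amps).pvalue < 1e-3


class TestConditionContrast:
    def test_egta_tightens_pair_separations(self, acq):
        # a 300 nm AZ radius leaves room for >400 nm intra-pair separations
        def fraction_above_400(condition, seed0):
            seps = []
            for seed in range(40):
                b = synthkit.make_bouton_model(300, 10, 0.1, 0.02,
                                               condition=condition, seed=seed)
                events = synthkit.sample_release_sequence(
                    b, acq, mvr_fraction=0.5, seed=seed0 + seed)
                by_pair = {}
                for e in events:
                    if e.pair_id:
                        by_pair.setdefault(e.pair_id, []).append(e)
                for m in by_pair.values():
                    seps.append(np.hypot(m[0].x_nm - m[1].x_nm,
                                         m[0].y_nm - m[1].y_nm))
            return np.mean(np.array(seps) > 400.0), len(seps)

        frac_ctrl, n_ctrl = fraction_above_400("control", 100)
        frac_egta, n_egta = fraction_above_400("egta", 200)
        assert n_ctrl > 100 and n_egta > 100
        assert frac_egta < frac_ctrl


class TestEndToEndSpatialBias:
    def test_larger_event_sits_closer_to_center(self, acq):
        # generator truth: first (undelayed, larger) fusion at higher-P_r,
        # more central sites; second delayed and peripheral-biased. Low
        # quantal CV and wide desync make amplitude order track fusion order.
        d_larger, d_smaller = [], []
        for seed in range(60):
            b = synthkit.make_bouton_model(180, 8, 0.1, 0.01, seed=seed)
            events = synthkit.sample_release_sequence(
                b, acq, mvr_fraction=0.4, desync_sd_ms=5.0, quantal_cv=0.05,
                seed=3000 + seed)
            pos = np.array([[e.x_nm, e.y_nm] for e in events]) if events else None
            if pos is None:
                continue
            center = pos.mean(axis=0)
            by_pair = {}
            for e in events:
                if e.pair_id:
                    by_pair.setdefault(e.pair_id, []).append(e)
            for m in by_pair.values():
                if m[0].amplitude == m[1].amplitude:
                    continue
                big, small = sorted(m, key=lambda e: -e.amplitude)
                d_larger.append(np.hypot(big.x_nm - center[0], big.y_nm - center[1]))
                d_smaller.append(np.hypot(small.x_nm - center[0],
                                          small.y_nm - center[1]))
        assert len(d_larger) >= 150
        t = sps.ttest_rel(d_larger, d_smaller)
        assert np.mean(d_larger) < np.mean(d_smaller)
        assert t.pvalue < 0.05
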