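"""Stillness/bout/tilt summaries and Lomb-Scargle screening."""

import numpy as np
import pytest

from skatesurv import activity as act
from skatesurv import synthetic_tags as synth
from skatesurv.tag_model import MobilitySeries

from conftest import pilot


def _series(mobility, pct_upright=None, window_hours=2.0, starts=None):
    mobility = np.asarray(mobility, dtype=float)
    n = len(mobility)
    if pct_upright is None:
        pct_upright = np.ones(n)
    if starts is None:
        starts = np.arange(n) * window_hours * 3600.0
    return MobilitySeries("t", starts, window_hours, mobility, np.asarray(pct_upright))


class TestStillness:
    def test_constant_below_cutoff(self):
        _, pct = act.classify_stillness(_series([7.0] * 10))
        assert pct == 1.0

    def test_half_still(self):
        _, pct = act.classify_stillness(_series([8, 10, 8, 10]))
        assert pct == 0.5

    def test_exact_cutoff_counts_as_not_still(self):
        flags, _ = act.classify_stillness(_series([9.0]))
        assert not flags[0]

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            act.classify_stillness(_series([]))

    def test_control_dead_tag_emulates_printed_stillness(self):
        cfg = synth.default_regime_config("control_dead")
        d = synth.simulate_deployment(cfg, seed=1, keep_archival=False)
        _, pct = act.classify_stillness(d.mobility_series)
        assert 0.85 <= pct <= 0.91

    def test_pct_still_invariant_to_window_order_but_bouts_are_not(self):
        mob = np.array([7.0] * 13 + [12.0] * 7)  # one 26 h bout
        _, pct = act.classify_stillness(_series(mob))
        perm = np.array([7.0, 12.0] * 7 + [7.0] * 6)  # interleaved
        _, pct_perm = act.classify_stillness(_series(perm))
        assert pct == pct_perm
        n1, _ = act.still_bouts(mob < 9, 2.0)
        n2, _ = act.still_bouts(perm < 9, 2.0)
        assert n1 == 1 and n2 == 0


class TestStillBouts:
    def test_no_still_windows(self):
        n, durs = act.still_bouts(np.zeros(10, dtype=bool), 2.0)
        assert n == 0 and len(durs) == 0

    def test_single_26h_run(self):
        flags = np.array([False] * 3 + [True] * 13 + [False] * 4)
        n, durs = act.still_bouts(flags, 2.0)
        assert n == 1
        assert durs.max() == pytest.approx(26.0)

    def test_duration_exactly_at_threshold_not_counted(self):
        flags = np.array([True] * 12)  # 24 h exactly
        n, _ = act.still_bouts(flags, 2.0, min_hours=24.0)
        assert n == 0

    def test_short_transmission_gap_bridged(self):
        # 26 h of stillness with one dropped window in the middle
        starts = np.array([0, 2, 4, 6, 10, 12, 14, 16, 18, 20, 22, 24]) * 3600.0
        flags = np.ones(len(starts), dtype=bool)
        n, durs = act.still_bouts(flags, 2.0, window_start_s=starts)
        assert n == 1
        assert durs.max() == pytest.approx(26.0)

    def test_long_gap_splits_bout(self):
        starts = np.array([0, 2, 4, 20, 22, 24]) * 3600.0
        flags = np.ones(6, dtype=bool)
        n, durs = act.still_bouts(flags, 2.0, window_start_s=starts, max_gap_h=6.0)
        assert len(durs) == 2

    def test_dead_plateau_tag_has_long_bout(self):
        cfg = synth.default_regime_config("dead_plateau")
        d = synth.simulate_deployment(cfg, seed=2, keep_archival=False)
        ms = d.mobility_series
        flags, _ = act.classify_stillness(ms)
        n, _ = act.still_bouts(flags, ms.window_hours, 40.0, ms.window_start_s)
        assert n >= 1


class TestTilt:
    def test_fully_upright(self):
        h, frac = act.tilt_hours(_series([7] * 5))
        assert h == 0.0 and frac == 0.0

    def test_half_window(self):
        h, _ = act.tilt_hours(_series([7.0], pct_upright=[0.5]))
        assert h == pytest.approx(1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="pct_upright"):
            act.tilt_hours(_series([7.0], pct_upright=[1.2]))

    def test_dead_canyon_tag_tilted_hours(self):
        cfg = pilot("dead_canyon")  # first 5 days include the spring tide
        d = synth.simulate_deployment(cfg, seed=1, keep_archival=False)
        h, _ = act.tilt_hours(d.mobility_series)
        assert h >= 2.0


class TestLombScargle:
    def _sinusoid(self, period_h=24.0, days=30, noise=0.5, seed=0, window_h=2.0):
        rng = np.random.default_rng(seed)
        t = np.arange(0, days * 24, window_h) * 3600.0
        y = np.sin(2 * np.pi * t / (period_h * 3600.0)) + rng.normal(0, noise, len(t))
        return t, y

    def test_known_period_recovered(self):
        t, y = self._sinusoid()
        pr = act.lomb_scargle(t, y)
        assert abs(pr.peak_period_h - 24.0) <= 0.5

    def test_gap_robustness_same_peak(self):
        t, y = self._sinusoid()
        rng = np.random.default_rng(1)
        keep = rng.random(len(t)) >= 0.2
        pr_full = act.lomb_scargle(t, y)
        pr_gappy = act.lomb_scargle(t[keep], y[keep])
        assert abs(pr_gappy.peak_period_h - pr_full.peak_period_h) <= 0.5

    def test_offset_and_scale_invariance(self):
        t, y = self._sinusoid()
        pr = act.lomb_scargle(t, y)
        pr2 = act.lomb_scargle(t, 5.0 * y + 40.0)
        assert np.allclose(pr.power, pr2.power)

    def test_constant_series_flagged(self):
        t = np.arange(0, 100) * 7200.0
        pr = act.lomb_scargle(t, np.full(100, 7.0))
        assert pr.no_variance and pr.p_value == 1.0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="8"):
            act.lomb_scargle(np.arange(5) * 7200.0, np.arange(5.0))


class TestSignificance:
    def test_strong_sinusoid_significant(self):
        rng_t = np.arange(0, 30 * 24, 2.0) * 3600.0
        y = np.sin(2 * np.pi * rng_t / (24.5 * 3600.0))
        y += np.random.default_rng(2).normal(0, 0.3, len(y))
        pr = act.lomb_scargle(rng_t, y)
        p = act.periodogram_significance(pr, rng_t, y, n_perm=999, seed=3)
        assert p <= 0.01

    def test_constant_series_p_one(self):
        t = np.arange(0, 100) * 7200.0
        pr = act.lomb_scargle(t, np.full(100, 7.0))
        assert act.periodogram_significance(pr, t, np.full(100, 7.0), seed=0) == 1.0

    def test_too_few_permutations_rejected(self):
        t, y = np.arange(20) * 7200.0, np.random.default_rng(0).normal(size=20)
        pr = act.lomb_scargle(t, y)
        with pytest.raises(ValueError, match="n_perm"):
            act.periodogram_significance(pr, t, y, n_perm=10, seed=0)


class TestEventAlignment:
    def test_all_high_values_near_events(self):
        t = np.arange(0, 30 * 86400, 7200.0)
        v = np.full(len(t), 5.0)
        near = np.abs(t - 10 * 86400.0) <= 86400.0
        v[near] = 20.0
        frac = act.event_alignment(t, v, np.array([10 * 86400.0]), threshold=9.0)
        assert frac == 1.0

    def test_no_high_values_gives_nan(self):
        t = np.arange(10) * 7200.0
        assert np.isnan(act.event_alignment(t, np.zeros(10), np.array([0.0]), 9.0))
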