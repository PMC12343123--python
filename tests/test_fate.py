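"""Movement detection, Bray-Curtis/NMDS, and the fate rule table."""

import numpy as np
import pytest

from skatesurv import fate
from skatesurv import synthetic_tags as synth
from skatesurv.activity import ActivitySummary
from skatesurv.tag_model import DepthSeries


def _depth_series(depths, tag="t", t0_h=0.0):
    depths = np.asarray(depths, dtype=float)
    t = t0_h * 3600.0 + np.arange(len(depths)) * 150.0
    win = np.floor(t / 7200.0).astype(int)
    return DepthSeries(tag, t, depths, win)


def _flat(depth, hours, noise=0.0, seed=0):
    n = int(hours * 3600 / 150)
    rng = np.random.default_rng(seed)
    return np.full(n, float(depth)) + rng.normal(0, noise, n)


class TestMovementDetection:
    def test_flat_series_with_small_noise_not_flagged(self):
        ds = _depth_series(_flat(1500.0, 48, noise=2.5, seed=1))
        ev = fate.detect_vertical_movement(ds)
        assert not ev.movement_flag
        assert ev.error_band == pytest.approx(15.0, abs=0.2)

    def test_single_35m_downward_step_counted_not_flagged(self):
        d = np.concatenate([_flat(1400.0, 48), _flat(1435.0, 48)])
        ev = fate.detect_vertical_movement(_depth_series(d))
        assert not ev.movement_flag
        assert ev.downward_shifts == 1

    def test_upward_step_is_movement(self):
        d = np.concatenate([_flat(1435.0, 48), _flat(1400.0, 48)])
        ev = fate.detect_vertical_movement(_depth_series(d))
        assert ev.movement_flag

    def test_repeated_excursions_flagged(self):
        base = _flat(1300.0, 96, noise=2.0, seed=2)
        for start in (400, 1200, 2000):
            base[start : start + 100] -= np.concatenate(
                [np.linspace(0, 200, 50), np.linspace(200, 0, 50)]
            )
        ev = fate.detect_vertical_movement(_depth_series(base))
        assert ev.movement_flag
        assert ev.max_excursion > 100.0

    def test_insufficient_benthic_data_flagged(self):
        ds = _depth_series(_flat(1500.0, 3.0))
        ev = fate.detect_vertical_movement(ds)
        assert ev.insufficient

    def test_survivor_simulation_flagged(self):
        d = synth.simulate_deployment(
            synth.default_regime_config("survivor_active"), seed=9, keep_archival=False
        )
        ev = fate.detect_vertical_movement(d.depth_series)
        assert ev.movement_flag

    def test_dead_simulation_not_flagged(self):
        d = synth.simulate_deployment(
            synth.default_regime_config("dead_plateau"), seed=9, keep_archival=False
        )
        ev = fate.detect_vertical_movement(d.depth_series)
        assert not ev.movement_flag


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        f = np.array([[0.2, 0.5, 1.0, 0.0]] * 2)
        assert fate.bray_curtis(f)[0, 1] == 0.0

    def test_disjoint_rows_one(self):
        f = np.array([[1.0, 0, 0, 0], [0, 1.0, 0, 0]])
        assert fate.bray_curtis(f)[0, 1] == pytest.approx(1.0)

    def test_matches_direct_formula(self, rng):
        f = rng.uniform(0, 1, (5, 4))
        d = fate.bray_curtis(f)
        for i in range(5):
            for j in range(5):
                expect = np.sum(np.abs(f[i] - f[j])) / np.sum(f[i] + f[j])
                assert d[i, j] == pytest.approx(expect)
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0)

    def test_negative_features_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            fate.bray_curtis(np.array([[-0.1, 0.2], [0.3, 0.4]]))


class TestNmds:
    def test_points_on_line_near_zero_stress(self):
        x = np.arange(6, dtype=float)
        d = np.abs(x[:, None] - x[None, :]) / 5.0
        res = fate.nmds(d, n_restarts=8, seed=0)
        assert res.stress <= 0.01

    def test_two_clusters_separate_in_ordination(self, rng):
        a = rng.normal(0.0, 0.1, (5, 4)) + 0.25
        b = rng.normal(0.0, 0.1, (5, 4)) + 0.75
        feats = np.clip(np.vstack([a, b]), 0, None)
        res = fate.nmds(fate.bray_curtis(feats), seed=1)
        c = res.coordinates
        within, between = [], []
        for i in range(10):
            for j in range(i + 1, 10):
                dist = np.linalg.norm(c[i] - c[j])
                (within if (i < 5) == (j < 5) else between).append(dist)
        within, between = np.array(within), np.array(between)
        # between-cluster pairs larger than within-cluster pairs
        assert np.mean(between[:, None] > within[None, :]) >= 0.95

    def test_all_zero_dissimilarity_degenerate(self):
        res = fate.nmds(np.zeros((5, 5)))
        assert res.stress == 0.0

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1, 2, 3], [0.5, 0, 1, 2], [2, 1, 0, 1], [3, 2, 1, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            fate.nmds(d)


def _summary(**kw):
    base = dict(
        tag_id="t",
        mean_mobility=10.0,
        pct_still=0.5,
        n_long_still_bouts=1,
        hours_tilted=5.0,
        pct_time_tilted=0.01,
        detachment_type="scheduled",
    )
    base.update(kw)
    return ActivitySummary(**base)


def _evidence(flag, insufficient=False, shifts=0):
    return fate.MovementEvidence(
        tag_id="t",
        benthic_depth_range=10.0,
        error_band=14.0,
        movement_flag=flag,
        max_excursion=200.0 if flag else 5.0,
        downward_shifts=shifts,
        insufficient=insufficient,
    )


class TestFateRules:
    def test_movement_means_survivor(self):
        c = fate.call_fate(_evidence(True), "mobile", _summary(pct_still=0.03))
        assert c.fate == "survivor" and c.rule_id.startswith("R1")

    def test_non_mobile_without_movement_is_mortality(self):
        c = fate.call_fate(
            _evidence(False), "non_mobile", _summary(pct_still=0.55,
                                                     detachment_type="early")
        )
        assert c.fate == "mortality" and c.rule_id.startswith("R2")

    def test_mobile_without_movement_is_ambiguous(self):
        c = fate.call_fate(
            _evidence(False), "mobile", _summary(pct_still=0.22,
                                                 detachment_type="early")
        )
        assert c.fate == "ambiguous" and c.rule_id.startswith("R3")

    def test_missing_evidence_is_ambiguous(self):
        c = fate.call_fate(None, "mobile", _summary())
        assert c.fate == "ambiguous" and "insufficient" in c.rule_id

    def test_insufficient_benthic_is_ambiguous(self):
        c = fate.call_fate(_evidence(False, insufficient=True), "mobile", _summary())
        assert c.fate == "ambiguous"

    def test_rule_table_total_and_unique(self):
        """Exactly one rule fires for every evidence combination."""
        for flag in (True, False):
            for label in ("mobile", "non_mobile", None):
                for insufficient in (True, False):
                    for act_s in (_summary(), None):
                        ev = _evidence(flag, insufficient=insufficient)
                        c = fate.call_fate(ev, label, act_s)
                        assert c.fate in fate.FATES
                        assert c.rule_id.split("-")[0] in {"R0", "R1", "R2", "R3"}


class TestCountFates:
    def _calls(self):
        mk = lambda tag, f: fate.FateCall(tag, f, "R", {})
        return [
            mk("a", "survivor"),
            mk("b", "mortality"),
            mk("c", "ambiguous"),
            mk("ctrl", "mortality"),
        ]

    def test_ambiguous_as_mortality_default(self):
        k, n = fate.count_fates(self._calls(), exclude_controls=["ctrl"])
        assert (k, n) == (1, 3)

    def test_ambiguous_as_survivor(self):
        k, n = fate.count_fates(
            self._calls(), ambiguous_as="survivor", exclude_controls=["ctrl"]
        )
        assert (k, n) == (2, 3)

    def test_ambiguous_excluded(self):
        k, n = fate.count_fates(
            self._calls(), ambiguous_as="excluded", exclude_controls=["ctrl"]
        )
        assert (k, n) == (1, 2)

    def test_invalid_mapping_rejected(self):
        with pytest.raises(ValueError, match="ambiguous_as"):
            fate.count_fates(self._calls(), ambiguous_as="drop")
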