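"""Sensor accuracy, depth binning, archival summarization and CSV round trips."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from skatesurv import synthetic_tags as synth
from skatesurv import tag_model as tm

from conftest import pilot


class TestSensorAccuracy:
    @pytest.mark.parametrize(
        "reading,expected", [(1700.0, 17.0), (0.0, 0.0), (1300.0, 13.0), (1800.0, 18.0)]
    )
    def test_one_percent_of_reading(self, reading, expected):
        assert tm.sensor_accuracy(reading) == pytest.approx(expected)

    def test_negative_reading_rejected_naming_field(self):
        with pytest.raises(ValueError, match="depth_reading"):
            tm.sensor_accuracy(-1.0)

    def test_linear_and_monotone(self):
        d = np.linspace(0, 2000, 50)
        acc = tm.sensor_accuracy(d)
        assert np.all(np.diff(acc) > 0)
        assert np.allclose(acc, 0.01 * d)


class TestEncodeWindow:
    def test_160m_range_gives_10m_bins(self):
        depths = np.linspace(1340.0, 1500.0, 48)
        bw = tm.encode_window(depths)
        assert bw.bin_width == pytest.approx(10.0)

    def test_constant_window_zero_width_decodes_to_constant(self):
        bw = tm.encode_window(np.full(48, 1425.5))
        assert bw.bin_width == 0.0
        assert np.all(tm.decode_window(bw) == 1425.5)

    def test_uniform_window_decode_error_bounded_by_direct_quantization(self, rng):
        raw = rng.uniform(1400.0, 1480.0, 48)
        bw = tm.encode_window(raw)
        decoded = tm.decode_window(bw)
        # independent direct quantization of every sample
        width = (raw.max() - raw.min()) / 16
        expected_idx = np.minimum(
            np.floor((raw - raw.min()) / width).astype(int), 15
        )
        assert np.array_equal(bw.bin_indices, expected_idx)
        assert np.max(np.abs(decoded - raw)) <= width / 2 + 1e-12
        assert np.max(np.abs(decoded - raw)) <= 2.5

    def test_max_sample_goes_to_top_bin(self):
        bw = tm.encode_window([0.0, 16.0])
        assert bw.bin_indices[-1] == 15

    def test_invalid_steps_rejected(self):
        with pytest.raises(ValueError, match="n_steps"):
            tm.encode_window([1.0, 2.0], n_steps=0)

    @settings(max_examples=200, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=2000.0, allow_nan=False),
            min_size=1,
            max_size=60,
        )
    )
    def test_quantization_error_at_most_half_bin(self, depths):
        raw = np.asarray(depths)
        bw = tm.encode_window(raw)
        err = np.abs(tm.decode_window(bw) - raw)
        assert np.all(err <= bw.bin_width / 2 + 1e-9)


class TestSummarizeArchival:
    def _record(self, mobility, az, n=7200):
        return tm.ArchivalRecord(
            tag_id="t",
            time_s=np.arange(n, dtype=float),
            depth_m=np.full(n, 1500.0),
            temperature_c=np.full(n, 2.0),
            az_g=np.broadcast_to(az, n).astype(float),
            mobility=np.broadcast_to(mobility, n).astype(float),
        )

    def test_constant_window(self):
        ms = tm.summarize_archival(self._record(7.0, -1.0))
        assert ms.n_windows == 1
        assert ms.mean_mobility[0] == pytest.approx(7.0)
        assert ms.pct_upright[0] == 1.0

    def test_alternating_mobility_matches_direct_average(self):
        mob = np.tile([5.0, 63.0], 3600)
        rec = self._record(0.0, -1.0)
        rec.mobility = mob
        ms = tm.summarize_archival(rec)
        assert ms.mean_mobility[0] == pytest.approx(mob.mean()) == pytest.approx(34.0)

    def test_roundtrip_matches_simulator_transmitted_series(self):
        cfg = pilot("dead_plateau", dropout_fraction=0.0)
        dep = synth.simulate_deployment(cfg, seed=3, keep_archival=True)
        ms = tm.summarize_archival(dep.archival, cfg.window_hours)
        assert np.array_equal(ms.mean_mobility, dep.mobility_series.mean_mobility)
        assert np.array_equal(ms.pct_upright, dep.mobility_series.pct_upright)

    def test_invalid_window_hours(self):
        with pytest.raises(ValueError, match="window_hours"):
            tm.summarize_archival(self._record(7.0, -1.0), window_hours=3)


class TestCsvRoundTrips:
    def _deployment(self, tag="t1", **kw):
        base = dict(
            tag_id=tag,
            capture_depth_m=1400.0,
            total_length_mm=1100.0,
            sex="F",
            time_out_water_min=5.0,
            soak_time_h=12.0,
            region="canyon",
            detachment_type="scheduled",
            days_at_liberty=30.0,
            is_control=False,
        )
        base.update(kw)
        return tm.TagDeployment(**base)

    def test_minimal_roundtrip(self, tmp_path):
        deps = [self._deployment("a"), self._deployment("b", sex="M")]
        p = tmp_path / "deployments.csv"
        tm.write_deployments(deps, p)
        again = tm.read_deployments(p)
        assert [d.tag_id for d in again] == ["a", "b"]
        assert again[1].sex == "M"

    def test_shuffled_column_order_same_object(self, tmp_path):
        deps = [self._deployment("a")]
        p = tmp_path / "deployments.csv"
        tm.write_deployments(deps, p)
        df = pd.read_csv(p)
        df[df.columns[::-1]].to_csv(tmp_path / "shuffled.csv", index=False)
        again = tm.read_deployments(tmp_path / "shuffled.csv")
        assert again[0].capture_depth_m == deps[0].capture_depth_m
        assert again[0].detachment_type == deps[0].detachment_type

    def test_unknown_columns_preserved(self, tmp_path):
        deps = [self._deployment("a", extras={"voyage": "K2023"})]
        p = tmp_path / "deployments.csv"
        tm.write_deployments(deps, p)
        assert tm.read_deployments(p)[0].extras["voyage"] == "K2023"

    def test_missing_column_named_in_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        pd.DataFrame({"tag_id": ["a"]}).to_csv(p, index=False)
        with pytest.raises(ValueError, match="capture_depth_m"):
            tm.read_deployments(p)

    def test_nonmonotone_timestamps_rejected_with_row(self, tmp_path):
        p = tmp_path / "series_x.csv"
        pd.DataFrame(
            {"time_s": [0.0, 300.0, 150.0], "depth_m": [1, 2, 3], "window_id": [0, 0, 0]}
        ).to_csv(p, index=False)
        with pytest.raises(ValueError, match="row 2"):
            tm.read_depth_series(p)

    def test_simulated_cohort_roundtrip_equality(self, tmp_path):
        configs = {r: pilot(r) for r in synth.REGIMES}
        cohort = synth.simulate_cohort((6, 16, 2), seed=7, regime_configs=configs)
        assert len(cohort) == 24
        tm.write_deployments([c.deployment for c in cohort], tmp_path / "d.csv")
        deps = tm.read_deployments(tmp_path / "d.csv")
        for orig, d in zip((c.deployment for c in cohort), deps):
            assert d.tag_id == orig.tag_id
            assert d.capture_depth_m == pytest.approx(orig.capture_depth_m)
            assert d.days_at_liberty == pytest.approx(orig.days_at_liberty)
            assert d.is_control == orig.is_control
        c0 = cohort[0]
        tm.write_depth_series(c0.depth_series, tmp_path / "s.csv")
        ds = tm.read_depth_series(tmp_path / "s.csv", c0.deployment.tag_id)
        assert np.array_equal(ds.depth_m, c0.depth_series.depth_m)
        tm.write_mobility_series(c0.mobility_series, tmp_path / "m.csv")
        ms = tm.read_mobility_series(tmp_path / "m.csv", c0.deployment.tag_id)
        assert np.array_equal(ms.mean_mobility, c0.mobility_series.mean_mobility)


class TestDeploymentInvariants:
    def test_days_at_liberty_cannot_exceed_programmed(self):
        with pytest.raises(ValueError, match="programmed"):
            tm.TagDeployment(
                tag_id="x",
                capture_depth_m=1400.0,
                total_length_mm=1100.0,
                sex="F",
                time_out_water_min=5.0,
                soak_time_h=10.0,
                region="canyon",
                detachment_type="scheduled",
                days_at_liberty=31.0,
            )

    def test_capture_depth_positive(self):
        with pytest.raises(ValueError, match="capture_depth_m"):
            tm.TagDeployment(
                tag_id="x",
                capture_depth_m=0.0,
                total_length_mm=1100.0,
                sex="F",
                time_out_water_min=5.0,
                soak_time_h=10.0,
                region="canyon",
                detachment_type="scheduled",
                days_at_liberty=30.0,
            )
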