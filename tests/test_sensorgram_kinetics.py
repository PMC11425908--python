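"""Sensorgram construction, smoothing, levels, rates, group comparison."""

import numpy as np
import pytest

from plasmogram import sensorgram_kinetics as sk
from plasmogram.spectral_tracking import CentroidTrace

from conftest import mannwhitney_exact_oracle


def make_trace(values, times=None, **kw):
    v = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float) if times is not None else 10.0 * np.arange(v.shape[0])
    return CentroidTrace(values=v, times=t, is_shift=True, **kw)


def make_temporal(times_min, smoothed, raw=None):
    y = np.asarray(smoothed, dtype=float)
    return sk.TemporalSensorgram(
        times_min=np.asarray(times_min, dtype=float),
        raw=y.copy() if raw is None else np.asarray(raw, dtype=float),
        smoothed=y,
    )


class TestSpatiotemporal:
    def test_upsampled_field_passes_through_native_knots(self):
        rng = np.random.default_rng(0)
        trace = make_trace(rng.random((13, 6)))
        sg = sk.build_spatiotemporal(trace)
        assert len(sg.up_times) == 61  # 5*(13-1)+1
        assert len(sg.up_positions) == 26  # 5*(6-1)+1
        np.testing.assert_allclose(sg.up_values[::5, ::5], sg.native_values, atol=1e-12)

    def test_zero_at_origin_is_exact(self):
        rng = np.random.default_rng(1)
        sg = sk.build_spatiotemporal(make_trace(5 + rng.random((9, 4))))
        assert np.all(sg.native_values[0] == 0.0)
        assert np.all(sg.up_values[0] == 0.0)

    def test_constant_field_offsets_to_zero(self):
        sg = sk.build_spatiotemporal(make_trace(np.full((8, 4), 3.7)))
        assert np.all(sg.native_values == 0.0)
        assert np.allclose(sg.smoothed, 0.0, atol=1e-12)

    def test_flagged_values_interpolated_in_time(self):
        v = np.outer(np.arange(9.0), np.ones(4))
        v[4, 2] = np.nan
        sg = sk.build_spatiotemporal(make_trace(v))
        assert sg.native_values[4, 2] == pytest.approx(4.0)

    def test_mostly_flagged_position_is_excluded(self):
        v = np.random.default_rng(2).random((10, 4))
        v[3:, 1] = np.nan  # 70% flagged
        sg = sk.build_spatiotemporal(make_trace(v))
        assert sg.excluded_positions == [1]
        assert sg.native_values.shape[1] == 3


class TestExtractTemporal:
    def _sg(self, field):
        return sk.build_spatiotemporal(make_trace(field))

    def test_identical_wells_average_to_either(self):
        rng = np.random.default_rng(3)
        f = rng.random((9, 24))
        left, right = self._sg(f), self._sg(f)
        tem = sk.extract_temporal(left, right)
        single = sk.extract_temporal(left)
        np.testing.assert_allclose(tem.raw, single.raw, atol=1e-12)
        assert tem.contributing_wells != single.contributing_wells

    def test_zero_left_halves_right(self):
        rng = np.random.default_rng(4)
        r = rng.random((9, 24))
        tem = sk.extract_temporal(self._sg(np.zeros((9, 24))), self._sg(r))
        right_only = sk.extract_temporal(self._sg(r))
        np.testing.assert_allclose(tem.raw, right_only.raw / 2.0, atol=1e-12)

    def test_single_well_notes_provenance(self):
        tem = sk.extract_temporal(self._sg(np.random.default_rng(5).random((9, 24))))
        assert "single well" in tem.provenance

    def test_raw_trace_zero_at_origin(self):
        tem = sk.extract_temporal(self._sg(np.random.default_rng(6).random((9, 24))))
        assert tem.raw[0] == 0.0


class TestSmoothing:
    def test_constant_trace_is_fixed_point(self):
        out = sk.smooth_trace(np.full(400, 1.25))
        assert np.abs(out - 1.25).max() < 1e-12

    def test_single_frame_spike_suppressed(self):
        y = np.zeros(300)
        y[150] = 5.0
        out = sk.smooth_trace(y)
        assert np.abs(out).max() < 0.5


class TestSecretionLevel:
    def test_constant_trace_level_is_constant(self):
        tem = make_temporal(np.arange(0, 1201, 10.0), np.full(121, 2.2))
        assert sk.secretion_level(tem, 12.0, 1.0) == pytest.approx(2.2)

    def test_linear_trace_symmetric_window_gives_midpoint(self):
        t = np.arange(0, 1201, 10.0)
        m = 0.07  # shift units per hour
        tem = make_temporal(t, m * t / 60.0)
        assert sk.secretion_level(tem, 12.0, 1.0) == pytest.approx(m * 12.0)

    def test_window_clipped_at_end_of_run(self):
        t = np.arange(0, 1201, 10.0)
        m = 0.07
        tem = make_temporal(t, m * t / 60.0)
        h = 2.0
        # clipped window [20-h, 20]: mean of the linear segment = m*(20 - h/2)
        assert sk.secretion_level(tem, 20.0, h) == pytest.approx(m * (20.0 - h / 2))

    def test_window_outside_record_is_error(self):
        tem = make_temporal(np.arange(0, 601, 10.0), np.zeros(61))
        with pytest.raises(ValueError, match="window"):
            sk.secretion_level(tem, 30.0, 1.0)


class TestSecretionRate:
    def test_linear_trace_has_constant_rate_and_zero_sd(self):
        t = np.arange(0, 1201, 10.0)
        m = 0.05
        kin = sk.secretion_rate(make_temporal(t, m * t / 60.0))
        np.testing.assert_allclose(kin.rate_per_h, m, atol=1e-9)
        assert kin.rate_sd < 1e-9
        assert kin.mean_rate == pytest.approx(m)

    def test_constant_trace_has_zero_rate(self):
        kin = sk.secretion_rate(make_temporal(np.arange(0, 601, 10.0), np.full(61, 1.0)))
        np.testing.assert_allclose(kin.rate_per_h, 0.0, atol=1e-12)

    def test_logistic_trace_peak_rate_is_lk_over_4(self):
        t = np.arange(0, 1201, 2.0)
        L, k, t0 = 0.3, 0.5, 10.0  # k per hour, midpoint in hours
        y = L / (1 + np.exp(-k * (t / 60.0 - t0)))
        kin = sk.secretion_rate(make_temporal(t, y))
        i = int(np.argmax(kin.rate_per_h))
        assert abs(t[i] / 60.0 - t0) <= np.diff(t).max() / 60.0
        assert kin.rate_per_h[i] == pytest.approx(L * k / 4, rel=0.02)

    def test_too_few_samples_is_error(self):
        with pytest.raises(ValueError, match="3 time samples"):
            sk.secretion_rate(make_temporal([0.0, 10.0], [0.0, 1.0]))


class TestOnset:
    def test_onset_detected_at_ten_percent_crossing(self):
        t = np.arange(0, 1201, 10.0)
        y = np.clip((t - 240.0) / 600.0, 0.0, 1.0)
        tem = make_temporal(t, y)
        # 10% of final level 1.0 crossed at t = 240 + 60 = 300 min = 5 h
        assert sk.onset_time(tem) == pytest.approx(5.0, abs=1e-9)

    def test_flat_zero_trace_has_no_onset(self):
        tem = make_temporal(np.arange(0, 601, 10.0), np.zeros(61))
        assert np.isnan(sk.onset_time(tem))


class TestCompareGroups:
    def test_complete_separation_gives_zero_u(self):
        u, p = sk.compare_groups([1, 2, 3], [4, 5, 6])
        assert u == 0.0

    def test_identical_multisets_give_midrank_u(self):
        u, _ = sk.compare_groups([1, 2, 3, 4], [1, 2, 3, 4])
        assert u == 8.0  # n^2/2 with midranks

    def test_exact_p_matches_permutation_oracle(self):
        a, b = [1.1, 2.3, 3.0], [1.9, 2.7]
        u, p = sk.compare_groups(a, b)
        u_want, p_want = mannwhitney_exact_oracle(a, b)
        assert u == pytest.approx(u_want, abs=1e-12)
        assert p == pytest.approx(p_want, abs=1e-12)

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError, match="non-empty"):
            sk.compare_groups([], [1.0, 2.0, 3.0])
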