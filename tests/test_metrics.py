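import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as hst

import simtempo as st
from simtempo.metrics import DegenerateTraceError


class TestSpectrumSeries:
    def test_constant_frame_has_only_dc(self):
        stack = np.full((3, 16, 16), 2.0)
        spec = st.spectrum_series(stack)
        c = 16 // 2
        assert spec.magnitudes[0, c, c] == pytest.approx(2.0 * 16 * 16)
        off_dc = spec.magnitudes[0].copy()
        off_dc[c, c] = 0.0
        assert np.all(off_dc < 1e-9)

    def test_unit_delta_gives_flat_spectrum(self):
        stack = np.zeros((1, 16, 16))
        stack[0, 3, 11] = 1.0
        spec = st.spectrum_series(stack)
        np.testing.assert_allclose(spec.magnitudes[0], 1.0, atol=1e-12)

    def test_magnitudes_linear_in_intensity(self):
        rng = np.random.default_rng(0)
        stack = rng.random((2, 16, 16))
        a = st.spectrum_series(stack).magnitudes
        b = st.spectrum_series(2.0 * stack).magnitudes
        np.testing.assert_allclose(b, 2.0 * a, rtol=1e-12)

    def test_window_times_carried_from_hr_stack(self):
        hr = st.HRStack(
            frames=np.zeros((3, 16, 16)) + np.eye(16),
            window_start=np.array([0, 3, 6]),
            scheme="rolling3",
        )
        spec = st.spectrum_series(hr)
        assert np.array_equal(spec.times, [0, 3, 6])


class TestNormalizeTrace:
    def test_zero_mean_unit_std(self):
        z = st.normalize_trace(np.random.default_rng(1).random(50))
        assert abs(z.values.mean()) < 1e-9
        assert abs(z.values.std() - 1.0) < 1e-9

    @given(
        a=hst.floats(min_value=0.1, max_value=10),
        b=hst.floats(min_value=-5, max_value=5),
    )
    def test_invariant_under_positive_affine_maps(self, a, b):
        x = np.random.default_rng(2).random(40)
        z1 = st.normalize_trace(x).values
        z2 = st.normalize_trace(a * x + b).values
        np.testing.assert_allclose(z1, z2, atol=1e-6)

    def test_constant_trace_is_degenerate(self):
        with pytest.raises(DegenerateTraceError):
            st.normalize_trace(np.full(10, 3.0))


class TestRmseTrace:
    def test_perfect_and_antiphase_bounds(self):
        z = st.normalize_trace(np.random.default_rng(3).random(64)).values
        assert st.rmse_trace(z, z) == 0.0
        assert st.rmse_trace(z, -z) == pytest.approx(2.0, abs=1e-12)

    def test_equals_sqrt_two_one_minus_correlation(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            x = st.normalize_trace(rng.normal(size=30)).values
            g = st.normalize_trace(rng.normal(size=30)).values
            rho = np.mean(x * g)  # population-z-scored operands
            assert st.rmse_trace(x, g) == pytest.approx(
                np.sqrt(2.0 * (1.0 - rho)), abs=1e-9
            )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            st.rmse_trace(np.zeros(5), np.zeros(6))


class TestDotMetric:
    def test_identical_traces_give_one(self):
        z = st.normalize_trace(np.sin(np.arange(64) / 3.0)).values
        assert st.dot_metric(z, z) == pytest.approx(1.0, abs=1e-12)

    def test_phase_insensitive(self):
        z = st.normalize_trace(np.sin(np.arange(64) / 5.0)).values
        assert st.dot_metric(z, -z) == pytest.approx(
            st.dot_metric(z, z), abs=1e-12
        )

    def test_disjoint_divisor_frequencies_orthogonal(self):
        t = np.arange(64)
        x = st.normalize_trace(np.sin(2 * np.pi * 4 * t / 64)).values
        g = st.normalize_trace(np.sin(2 * np.pi * 8 * t / 64)).values
        assert st.dot_metric(x, g) == pytest.approx(0.0, abs=1e-9)

    def test_unnormalized_matches_manual_power_inner_product(self):
        rng = np.random.default_rng(5)
        x, g = rng.normal(size=32), rng.normal(size=32)
        manual = float(
            np.dot(np.abs(np.fft.fft(x)) ** 2, np.abs(np.fft.fft(g)) ** 2)
        )
        assert st.dot_metric(x, g, normalized=False) == pytest.approx(manual)


class TestRmseMap:
    def _series_from_traces(self, base, trace_values):
        stack = base[None] * trace_values[:, None, None]
        return st.spectrum_series(stack)

    def test_frames_tracking_the_modulation_score_zero(self):
        base = np.random.default_rng(6).random((16, 16)) + 0.1
        tm = 8.0
        trace = st.ModulationTrace.make(tm, 32)
        spec = self._series_from_traces(base, trace.values)
        m = st.rmse_map(spec, trace, registration="start")
        assert m.values.shape == (16, 16)
        assert np.nanmax(m.values) < 1e-6

    def test_antiphase_frames_score_two(self):
        base = np.random.default_rng(7).random((16, 16)) + 0.1
        tm = 8.0
        trace = st.ModulationTrace.make(tm, 32)
        # intensities moving opposite to GTm (still positive)
        anti = 1.75 - trace.values
        spec = self._series_from_traces(base, anti)
        m = st.rmse_map(spec, trace, registration="start")
        assert np.nanmin(m.values) > 2.0 - 1e-6
        assert np.nanmax(m.values) <= 2.0 + 1e-9

    def test_center_registration_shifts_comparison_times(self):
        base = np.random.default_rng(8).random((16, 16)) + 0.1
        tm = 16.0
        # frames indexed by window start but containing centre-time content
        starts = np.arange(24)
        centred_values = st.modulation_value(starts + 4.0, tm)
        stack = base[None] * centred_values[:, None, None]
        spec = st.spectrum_series(stack, times=starts)
        m = st.rmse_map(spec, st.ModulationTrace.make(tm, 40), "center")
        assert np.nanmax(m.values) < 1e-6

    def test_degenerate_ground_truth_rejected(self):
        base = np.random.default_rng(9).random((16, 16))
        spec = st.spectrum_series(base[None] * np.arange(1, 10)[:, None, None],
                                  times=np.arange(9) * 4)
        with pytest.raises(DegenerateTraceError):
            # Tm = 4 sampled every 4 frames: constant ground truth
            st.rmse_map(spec, st.ModulationTrace.make(4.0, 36), "start")


class TestRadialAverage:
    def test_constant_map_gives_constant_bins(self):
        prof = st.radial_average(np.full((32, 32), 0.7))
        assert np.all(prof.bins == pytest.approx(0.7))

    def test_floor_radius_map_recovers_bin_index(self):
        n = 32
        k = np.arange(n) - n // 2
        radius = np.hypot(k[None, :], k[:, None])
        prof = st.radial_average(np.floor(radius))
        valid = prof.counts > 0
        np.testing.assert_allclose(
            prof.bins[valid], np.arange(n // 2)[valid], atol=1e-12
        )

    def test_brute_force_binning_oracle(self):
        rng = np.random.default_rng(10)
        values = rng.random((32, 32))
        prof = st.radial_average(values)
        c = 32 // 2
        for r in range(16):
            acc = [
                values[y, x]
                for y in range(32)
                for x in range(32)
                if r <= np.hypot(x - c, y - c) < r + 1
            ]
            if acc:
                assert prof.bins[r] == pytest.approx(np.mean(acc))
                assert prof.counts[r] == len(acc)

    def test_counts_partition_pixels_within_nyquist(self):
        prof = st.radial_average(np.ones((32, 32)))
        k = np.arange(32) - 16
        radius = np.hypot(k[None, :], k[:, None])
        assert prof.counts.sum() == np.count_nonzero(radius < 16)

    def test_nan_pixels_excluded_not_zeroed(self):
        values = np.ones((32, 32))
        values[16, 18] = np.nan  # radius 2 pixel
        prof = st.radial_average(values)
        assert prof.bins[2] == pytest.approx(1.0)

    def test_all_nan_bin_marked_missing(self):
        values = np.full((32, 32), np.nan)
        values[16, 16] = 1.0
        prof = st.radial_average(values)
        assert prof.bins[0] == 1.0
        assert np.isnan(prof.bins[5])
        assert prof.counts[5] == 0


@pytest.fixture(scope="module")
def tiny_world():
    samp = st.generate_point_sample(32, 0.02, 1.0, seed=11)
    patterns = st.make_pattern_set(32, 4.75)
    otf = st.make_otf(32, 8.0)
    return samp, patterns, otf


class TestSweep:
    def test_even_divisor_periods(self):
        assert list(st.even_divisor_periods(512)) == [
            2, 4, 8, 16, 32, 64, 128, 256, 512,
        ]
        assert list(st.even_divisor_periods(18)) == [2, 6, 18]

    def test_sweep_shape_and_determinism(self, tiny_world):
        samp, patterns, otf = tiny_world
        cfg = st.ReconstructionConfig(scheme="rolling1")
        kw = dict(periods=[5, 13], n_frames=18, seed=3)
        a = st.sweep_modulation_periods(samp, patterns, otf, cfg, **kw)
        b = st.sweep_modulation_periods(samp, patterns, otf, cfg, **kw)
        assert a.matrix.shape == (16, 2)
        assert np.array_equal(a.matrix, b.matrix, equal_nan=True)

    def test_dot_sweep_restricted_to_even_divisors(self, tiny_world):
        samp, patterns, otf = tiny_world
        cfg = st.ReconstructionConfig(scheme="rolling1")
        m = st.sweep_modulation_periods(
            samp, patterns, otf, cfg, periods=[2, 5, 6, 7, 18],
            n_frames=18, kind="dot", seed=3,
        )
        assert list(m.periods) == [2, 6, 18]

    def test_sweep_rejects_empty_period_list(self, tiny_world):
        samp, patterns, otf = tiny_world
        with pytest.raises(ValueError):
            st.sweep_modulation_periods(
                samp, patterns, otf, st.ReconstructionConfig(), [], 18
            )


class TestDifferenceMap:
    def _map(self, matrix):
        return st.SpatioTemporalMap(
            matrix=np.asarray(matrix, dtype=float),
            periods=np.arange(np.shape(matrix)[1], dtype=float),
            kind="rmse",
        )

    def test_self_difference_is_zero(self):
        a = self._map(np.random.default_rng(12).random((4, 3)))
        assert np.all(st.difference_map(a, a).matrix == 0.0)

    def test_difference_recovers_offset(self):
        rng = np.random.default_rng(13)
        b, c = rng.random((4, 3)), rng.random((4, 3))
        out = st.difference_map(self._map(b + c), self._map(b))
        np.testing.assert_allclose(out.matrix, c, atol=1e-12)

    def test_missing_cells_propagate(self):
        b = np.ones((2, 2))
        a = b.copy()
        a[0, 0] = np.nan
        assert np.isnan(st.difference_map(self._map(a), self._map(b)).matrix[0, 0])

    def test_axis_mismatch_rejected(self):
        with pytest.raises(ValueError):
            st.difference_map(self._map(np.ones((2, 2))), self._map(np.ones((2, 3))))


def test_end_to_end_rmse_invariant_to_signal_scale(tiny_otf):
    """z-scoring removes the intensity scale: scaling max_signal leaves the
    RMSE map unchanged (linearity of the whole pipeline).  Holds for every
    pixel inside the SIM pass band; outside, traces are pure float rounding
    with no defined scale behaviour."""
    patterns = st.make_pattern_set(32, 4.75)
    maps = []
    for signal in (1.0, 50.0):
        samp = st.generate_point_sample(32, 0.02, signal, seed=14)
        gt = st.build_ground_truth_stack(samp, 27, tm=12.0)
        raw = st.acquire_raw_frames(gt, patterns, tiny_otf)
        hr = st.reconstruct_series(
            raw, patterns, tiny_otf, st.ReconstructionConfig(scheme="rolling3")
        )
        maps.append(st.rmse_map(st.spectrum_series(hr), gt.trace).values)
    # within a 2-px margin of the pass-band edge the Wiener-suppressed
    # signal reaches float-rounding level, so stay clear of it
    limit = st.sim_passband_limit(8.0, 4.75, 32)
    k = np.arange(32) - 16
    inside = np.hypot(k[None, :], k[:, None]) < limit - 2
    np.testing.assert_allclose(maps[0][inside], maps[1][inside], atol=1e-6)
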