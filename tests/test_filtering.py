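"""Median filter and TVD: exactness, invariants, oracle equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hemitrace as ht
from hemitrace.filtering import tv_denoise_exact, tv_denoise_mm, total_variation


def _trace(y, fs=1000.0, vm=70.0):
    return ht.Trace(samples=np.asarray(y, dtype=float), sampling_rate=fs, vm=vm)


class TestMedianFilter:
    def test_constant_trace_unchanged(self):
        tr = _trace(np.full(500, 3.2))
        out = ht.median_filter(tr, 0.05)
        np.testing.assert_array_equal(out.samples, tr.samples)

    def test_step_amplitude_preserved_away_from_edge(self):
        y = np.where(np.arange(2000) >= 1000, 10.0, 0.0)
        out = ht.median_filter(_trace(y), 0.1)  # 100-sample window
        # away from the edge the filter is the identity; the step survives
        np.testing.assert_array_equal(out.samples[:940], 0.0)
        np.testing.assert_array_equal(out.samples[1060:], 10.0)
        assert np.ptp(out.samples) == pytest.approx(10.0)

    def test_narrow_impulse_removed(self):
        y = np.zeros(1000)
        y[500:510] = 5.0  # 10 samples << half of the 100-sample window
        out = ht.median_filter(_trace(y), 0.1)
        # oracle: median of any full window containing <= 10 impulse samples
        # out of 100 is 0
        assert np.max(np.abs(out.samples[60:-60])) == 0.0

    def test_matches_direct_median_oracle(self):
        rng = np.random.default_rng(0)
        y = rng.normal(0, 1, 200)
        w = 31
        out = ht.median_filter(_trace(y), w / 1000.0)
        oracle = np.array([
            np.median(y[max(0, i - w // 2): i + w // 2 + 1])
            for i in range(y.size)])
        np.testing.assert_allclose(out.samples, oracle, atol=1e-12)

    def test_window_longer_than_trace_rejected(self):
        with pytest.raises(ValueError):
            ht.median_filter(_trace(np.zeros(10)), 1.0)

    def test_idempotent_on_long_segment_piecewise_constant(self):
        # odd window: a clean multi-level signal passes through unchanged,
        # so refiltering is exact (even windows interpolate at the jumps)
        y = np.repeat([0.0, 8.0, 3.0], 400)
        tr = _trace(y)
        once = ht.median_filter(tr, 0.101)
        twice = ht.median_filter(once, 0.101)
        np.testing.assert_allclose(twice.samples, once.samples, atol=1e-12)

    def test_metadata_and_length_preserved(self):
        tr = ht.Trace(samples=np.arange(100.0), sampling_rate=250.0, vm=-40.0,
                      t0=2.0, metadata={"id": "x"})
        out = ht.median_filter(tr, 0.02)
        assert len(out) == len(tr)
        assert out.sampling_rate == tr.sampling_rate
        assert out.vm == tr.vm and out.t0 == tr.t0


class TestTVD:
    def test_lambda_zero_is_identity(self):
        rng = np.random.default_rng(1)
        tr = _trace(rng.normal(0, 1, 300))
        out = ht.tvd_denoise(tr, lam=0.0)
        np.testing.assert_array_equal(out.samples, tr.samples)

    def test_huge_lambda_approaches_the_mean(self):
        rng = np.random.default_rng(2)
        y = rng.normal(0, 1, 200) + np.repeat([0.0, 4.0], 100)
        out = tv_denoise_mm(y, 1e9, iterations=200)
        np.testing.assert_allclose(out, np.mean(y), atol=1e-6)

    def test_exact_solver_matches_dual_box_qp(self):
        # independent validation of the direct solver: TVD duality says
        # x* = y - D^T z* with z* the box-constrained least-squares solution
        from scipy.optimize import lsq_linear
        rng = np.random.default_rng(3)
        for _ in range(8):
            n = int(rng.integers(3, 40))
            y = rng.normal(0, 1, n) + np.repeat(
                rng.normal(0, 3, 4), int(np.ceil(n / 4)))[:n]
            lam = float(rng.uniform(0.05, 3.0))
            D = np.diff(np.eye(n), axis=0)
            z = lsq_linear(D.T, y, bounds=(-lam, lam), method="bvls",
                           tol=1e-14).x
            np.testing.assert_allclose(tv_denoise_exact(y, lam), y - D.T @ z,
                                       atol=1e-9)

    def test_mm_converges_to_exact_solution(self):
        rng = np.random.default_rng(4)
        y = rng.normal(0, 1, 150) + np.repeat(rng.normal(0, 3, 5), 30)
        for lam in (0.1, 1.0, 5.0):
            xm = tv_denoise_mm(y, lam, iterations=100000, tol=1e-13)
            np.testing.assert_allclose(xm, tv_denoise_exact(y, lam), atol=1e-6)

    def test_total_variation_never_increases(self):
        rng = np.random.default_rng(5)
        tr = _trace(rng.normal(0, 1, 500))
        tv_in = total_variation(tr.samples)
        out = ht.tvd_denoise(tr, lam=2.0)
        assert total_variation(out.samples) <= tv_in + 1e-9

    def test_tv_monotone_in_lambda(self):
        rng = np.random.default_rng(6)
        y = rng.normal(0, 1, 400) + np.repeat(rng.normal(0, 5, 4), 100)
        tvs = [total_variation(tv_denoise_exact(y, lam))
               for lam in (0.0, 0.1, 0.5, 1.0, 5.0, 25.0)]
        assert all(a >= b - 1e-9 for a, b in zip(tvs, tvs[1:]))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=60),
           st.floats(0.01, 10.0))
    def test_exact_solver_optimality_property(self, y, lam):
        # the minimizer's objective must not beat any perturbed candidate
        y = np.asarray(y)
        x = tv_denoise_exact(y, lam)

        def objective(v):
            return 0.5 * np.sum((y - v) ** 2) + lam * total_variation(v)

        f0 = objective(x)
        rng = np.random.default_rng(0)
        for _ in range(10):
            assert f0 <= objective(x + rng.normal(0, 0.01, y.size)) + 1e-9

    def test_auto_lambda_scales_with_noise(self):
        rng = np.random.default_rng(7)
        small = ht.auto_lambda(rng.normal(0, 1, 5000))
        large = ht.auto_lambda(rng.normal(0, 10, 5000))
        assert large == pytest.approx(10 * small, rel=0.1)

    def test_trace_length_and_metadata_preserved(self):
        tr = ht.Trace(samples=np.arange(50.0), sampling_rate=10.0, vm=70.0)
        out = ht.tvd_denoise(tr, lam=1.0)
        assert len(out) == 50 and out.sampling_rate == 10.0
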