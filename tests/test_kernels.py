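"""Convolution-matrix kernels, the kernel library, and position estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aistrack.features import select_and_order_electrodes
from aistrack.kernels import (
    Kernel,
    build_convolution_matrix,
    build_kernel_library,
    estimate_ais_position,
    estimate_kernel,
    match_electrode,
    normalized_rms_error,
    predict_waveform,
)
from aistrack.pipeline import biphasic_pulse, make_fixture


class TestConvolutionMatrix:
    def test_impulse_gives_identity_columns(self):
        x = np.zeros(10)
        x[0] = 1.0
        X = build_convolution_matrix(x, 3)
        np.testing.assert_allclose(X, np.eye(10)[:, :3])

    def test_identity_kernel_reproduces_input(self):
        x = biphasic_pulse(96, 40, 30.0)
        X = build_convolution_matrix(x, 5)
        h = np.zeros(5)
        h[0] = 1.0
        np.testing.assert_allclose(X @ h, x)

    def test_first_column_is_x(self):
        x = np.arange(12.0)
        X = build_convolution_matrix(x, 4)
        np.testing.assert_allclose(X[:, 0], x)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            build_convolution_matrix(np.ones(4), 5)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_direct_convolution_sum(self, seed):
        """Matrix form equals the direct convolution sum (oracle)."""
        rng = np.random.default_rng(seed)
        n, L = 40, 7
        x = rng.normal(size=n)
        h = rng.normal(size=L)
        direct = np.array(
            [sum(h[m] * x[i - m] for m in range(L) if 0 <= i - m < n) for i in range(n)]
        )
        assert np.abs(build_convolution_matrix(x, L) @ h - direct).max() <= 1e-10


class TestKernelEstimation:
    def test_identity_transformation(self):
        # white input keeps the Toeplitz system well conditioned
        x = np.random.default_rng(2).normal(size=96)
        k = estimate_kernel(x, x, L=25)
        delta = np.zeros(25)
        delta[0] = 1.0
        assert np.abs(k.h - delta).max() < 1e-6

    def test_known_kernel_recovered(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=96)  # white input: well conditioned
        h_true = np.zeros(25)
        h_true[[0, 3, 11]] = [0.9, -0.4, 0.2]
        y = np.convolve(x, h_true)[:96]
        k = estimate_kernel(x, y, L=25)
        assert np.abs(k.h - h_true).max() <= 1e-8

    def test_scaled_shift(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=96)
        y = 2.0 * np.r_[0.0, x[:-1]]
        k = estimate_kernel(x, y, L=25)
        expected = np.zeros(25)
        expected[1] = 2.0
        assert np.abs(k.h - expected).max() < 1e-8

    def test_all_zero_input_rejected(self):
        with pytest.raises(ValueError):
            estimate_kernel(np.zeros(96), np.ones(96))

    def test_predict_identity_and_zero(self):
        x = biphasic_pulse(96, 32, 40.0)
        ident = Kernel(np.r_[1.0, np.zeros(24)])
        np.testing.assert_allclose(predict_waveform(x, ident), x)
        zero = Kernel(np.zeros(25))
        np.testing.assert_allclose(predict_waveform(x, zero), 0.0)


class TestNormalizedRMS:
    def test_exact_match_is_zero(self):
        y = biphasic_pulse(96, 32, 40.0)
        assert normalized_rms_error(y, y) == 0.0

    def test_constant_offset(self):
        y = biphasic_pulse(96, 32, 40.0)
        c = 3.7
        rng = y.max() - y.min()
        assert normalized_rms_error(y + c, y) == pytest.approx(c / rng)

    def test_scale_invariance(self):
        rng_ = np.random.default_rng(0)
        y = rng_.normal(size=96)
        y_hat = y + rng_.normal(0, 0.1, 96)
        assert normalized_rms_error(2 * y_hat, 2 * y) == pytest.approx(
            normalized_rms_error(y_hat, y)
        )

    def test_flat_estimate_flagged(self):
        assert np.isinf(normalized_rms_error(np.zeros(96), np.ones(96)))


class TestLibrary:
    def test_library_size_counts(self, kernel_footprints):
        """Sub-grid with 24 angles and 3 relocated positions -> 26 x 3 x 24
        kernels per offset."""
        subset = [
            fp for fp in kernel_footprints
            if fp.meta["theta_deg"] % 15.0 == 0.0
            and fp.meta["d_ais"] in (5.0, 15.0, 25.0, 35.0)
        ]
        lib = build_kernel_library(subset)
        assert lib.H.shape == (2, 24, 3, 26, 25)
        assert lib.n_kernels() == 2 * 24 * 3 * 26

    def test_missing_baseline_reported(self, kernel_footprints):
        subset = [fp for fp in kernel_footprints if fp.meta["d_ais"] != 5.0]
        with pytest.raises(ValueError, match="baseline"):
            build_kernel_library(subset)

    def test_self_retrieval_of_stored_kernel(self, kernel_footprints):
        """A pair generated by a stored kernel is retrieved with E ~ 0
        (single-offset library: the match is exact, not offset-averaged)."""
        single = [fp for fp in kernel_footprints if fp.meta["offset"] == (0.0, 0.0)]
        lib = build_kernel_library(single)
        base = [
            fp for fp in single
            if fp.meta["theta_deg"] == 0.0 and fp.meta["d_ais"] == 5.0
        ][0]
        order = select_and_order_electrodes(base, 26)
        it = int(np.searchsorted(lib.thetas, 0.0))
        idd = 3
        m = 4
        x = base.waveforms[order[m]]
        y = predict_waveform(x, Kernel(lib.H[0, it, idd, m]))
        m_star, err = match_electrode(lib, x, y, lib.d_grid[idd])
        assert m_star == m
        assert err < 1e-6

    def test_match_equals_brute_force_scan(self, kernel_lib, kernel_footprints):
        base = [
            fp for fp in kernel_footprints
            if fp.meta["offset"] == (0.0, 0.0) and fp.meta["theta_deg"] == 30.0
            and fp.meta["d_ais"] == 5.0
        ][0]
        comp = [
            fp for fp in kernel_footprints
            if fp.meta["offset"] == (0.0, 0.0) and fp.meta["theta_deg"] == 30.0
            and fp.meta["d_ais"] == 20.0
        ][0]
        order = select_and_order_electrodes(base, 26)
        x, y = base.waveforms[order[2]], comp.waveforms[order[2]]
        d = 20.0
        m_star, err = match_electrode(kernel_lib, x, y, d)
        # brute force over every stored kernel at this position
        idd = int(np.argmin(np.abs(kernel_lib.d_grid - d)))
        best = (None, np.inf)
        X = build_convolution_matrix(x, kernel_lib.L)
        for io in range(kernel_lib.H.shape[0]):
            for it in range(kernel_lib.H.shape[1]):
                for m in range(kernel_lib.M):
                    e = normalized_rms_error(X @ kernel_lib.H[io, it, idd, m], y)
                    if e < best[1]:
                        best = (m, e)
        # match_electrode averages over offsets before the minimum; recompute
        errs = np.full(kernel_lib.M, np.inf)
        for m in range(kernel_lib.M):
            per = []
            for it in range(kernel_lib.H.shape[1]):
                per.append(np.mean([
                    normalized_rms_error(X @ kernel_lib.H[io, it, idd, m], y)
                    for io in range(kernel_lib.H.shape[0])
                ]))
            errs[m] = min(per)
        assert m_star == int(np.argmin(errs))
        assert err == pytest.approx(errs.min())


class TestPositionEstimation:
    def test_identity_pair_estimates_baseline(self, kernel_lib, kernel_footprints):
        base = [
            fp for fp in kernel_footprints
            if fp.meta["offset"] == (0.0, 0.0) and fp.meta["theta_deg"] == 45.0
            and fp.meta["d_ais"] == 5.0
        ][0]
        est = estimate_ais_position(kernel_lib, base, base)
        assert est.error_curve[0] == pytest.approx(0.0, abs=1e-12)
        assert est.d_hat == pytest.approx(5.0, abs=2.0)

    def test_within_family_pair_recovers_position(self, kernel_lib, kernel_footprints):
        sel = {
            fp.meta["d_ais"]: fp for fp in kernel_footprints
            if fp.meta["offset"] == (0.0, 0.0) and fp.meta["theta_deg"] == 0.0
        }
        est = estimate_ais_position(kernel_lib, sel[5.0], sel[15.0])
        assert abs(est.d_hat - 15.0) <= 4.0

    def test_kernel_length_error_trend(self, kernel_footprints):
        """Mean normalized RMS fit error is non-increasing in kernel length
        over L in {5, 10, 15, 20, 25}, averaged over >= 20 footprint pairs."""
        from collections import defaultdict

        fams = defaultdict(dict)
        for fp in kernel_footprints:
            if fp.meta["theta_deg"] % 45.0 == 0.0 and fp.meta["offset"] == (0.0, 0.0):
                fams[fp.meta["theta_deg"]][fp.meta["d_ais"]] = fp
        pairs = []
        for th, fam in fams.items():
            order = select_and_order_electrodes(fam[5.0], 26)
            for d in (15.0, 30.0):
                for e in order[:3]:
                    pairs.append((fam[5.0].waveforms[e], fam[d].waveforms[e]))
        assert len(pairs) >= 20
        means = []
        for L in (5, 10, 15, 20, 25):
            errs = [
                normalized_rms_error(predict_waveform(x, estimate_kernel(x, y, L)), y)
                for x, y in pairs
            ]
            means.append(np.mean(errs))
        assert np.all(np.diff(means) <= 1e-12)
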