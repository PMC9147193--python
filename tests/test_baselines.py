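"""Zero-filled and GRAPPA comparators."""

import numpy as np
import pytest

import neumannmri as nm
from neumannmri.baselines import GrappaKernel, _source_matrix, grappa_calibrate, grappa_reconstruct


class TestZeroFilled:
    def test_fully_sampled_recovers_phantom(self, small_scene):
        _, y_full = nm.simulate_acquisition(small_scene)
        np.testing.assert_allclose(
            nm.zero_filled(y_full), small_scene.image, atol=1e-10
        )
        assert nm.zero_filled(np.zeros_like(y_full)).max() == 0

    def test_undersampling_degrades(self, noisy_scene):
        y, y_full = nm.simulate_acquisition(noisy_scene)
        ref = nm.rss_combine(nm.ifft2c(y_full))
        assert nm.nmse(nm.zero_filled(y), ref) > 0


def planted_kernel_data(seed, coils=2, rows=8, acs_cols=12, accel=2):
    """K-space lying in the null space of the calibration residual for a
    planted kernel, so least-squares calibration must recover it exactly."""
    rng = np.random.default_rng(seed)
    kern = GrappaKernel({}, accel)
    nk = coils * kern.kernel_rows * len(kern.col_offsets)
    w = rng.standard_normal((coils, nk)) + 1j * rng.standard_normal((coils, nk))

    def residual(yb, r=1):
        t_all = np.arange(acs_cols)
        ok = (t_all - r + kern.col_offsets.min() >= 0) & (
            t_all - r + kern.col_offsets.max() < acs_cols
        )
        tv = t_all[ok]
        t_rows = np.repeat(np.arange(rows), tv.size)
        t_cols = np.tile(tv, rows)
        S = _source_matrix(yb, t_rows, t_cols, r, kern.row_offsets, kern.col_offsets)
        return (yb[:, t_rows, t_cols].T - S @ w.T).ravel()

    n = coils * rows * acs_cols
    A = np.zeros((residual(np.zeros((coils, rows, acs_cols), complex)).size, n), complex)
    for i in range(n):
        e = np.zeros(n, complex)
        e[i] = 1
        A[:, i] = residual(e.reshape(coils, rows, acs_cols))
    _, s, vh = np.linalg.svd(A)
    null = vh[np.sum(s > 1e-10) :].conj().T
    coef = rng.standard_normal(null.shape[1]) + 1j * rng.standard_normal(null.shape[1])
    y = (null @ coef).reshape(coils, rows, acs_cols)
    return y, w


class TestGrappaCalibration:
    def test_recovers_planted_kernel(self):
        y, w = planted_kernel_data(seed=3)
        kern = grappa_calibrate(y, 2, tikhonov=0.0)
        assert np.abs(kern.weights[1] - w).max() / np.abs(w).max() < 1e-6

    def test_duplicate_coils_get_symmetric_weights(self, rng):
        base = rng.standard_normal((1, 10, 14)) + 1j * rng.standard_normal((1, 10, 14))
        y = np.concatenate([base, base], axis=0)
        kern = grappa_calibrate(y, 2, tikhonov=1e-6)
        w = kern.weights[1]  # (2, 2*5*4), source order (dr, dc, coil)
        per_src = w.reshape(2, 5 * 4, 2)  # coil axis fastest
        np.testing.assert_allclose(per_src[:, :, 0], per_src[:, :, 1], atol=1e-8)

    def test_zero_tikhonov_matches_plain_lstsq(self, rng):
        y = rng.standard_normal((2, 10, 16)) + 1j * rng.standard_normal((2, 10, 16))
        a = grappa_calibrate(y, 2, tikhonov=0.0).weights[1]
        b = grappa_calibrate(y, 2, tikhonov=1e-12).weights[1]
        assert np.abs(a - b).max() < 1e-4

    def test_underdetermined_acs_rejected(self, rng):
        y = rng.standard_normal((8, 4, 8)) + 1j * rng.standard_normal((8, 4, 8))
        with pytest.raises(ValueError, match="ACS"):
            grappa_calibrate(y, 2)


@pytest.fixture(scope="module")
def recon():
    sc = nm.make_scene(
        rows=64, cols=64, num_coils=8, acceleration=2, acs_fraction=0.25,
        noise_rel=0.0, seed=1,
    )
    y, y_full = nm.simulate_acquisition(sc)
    acs = y[:, :, sc.mask.acs_start : sc.mask.acs_end]
    kern = grappa_calibrate(acs, 2)
    img, filled = grappa_reconstruct(y, sc.mask, kern, return_kspace=True)
    return sc, y, y_full, img, filled


class TestGrappaReconstruction:
    def test_noiseless_2x_nmse_below_one_percent(self, recon):
        sc, _, y_full, img, _ = recon
        ref = nm.rss_combine(nm.ifft2c(y_full))
        assert nm.nmse(img, ref) < 0.01

    def test_acquired_samples_preserved_bit_exact(self, recon):
        sc, y, _, _, filled = recon
        assert np.array_equal(filled[:, :, sc.mask.mask], y[:, :, sc.mask.mask])

    def test_fully_sampled_input_equals_zero_filled(self, recon):
        sc, _, y_full, _, _ = recon
        full_mask = nm.make_equispaced_mask(64, 1, 1.0)
        kern = grappa_calibrate(y_full[:, :, 24:40], 2)
        # a kernel calibrated at 2x cannot be applied to a full mask
        with pytest.raises(ValueError):
            grappa_reconstruct(y_full, full_mask, kern)
        # with nothing to fill (acceleration 1) GRAPPA is exactly zero-filled
        kern1 = grappa_calibrate(y_full[:, :, 24:40], 1)
        img = grappa_reconstruct(y_full, full_mask, kern1)
        np.testing.assert_array_equal(img, nm.zero_filled(y_full))

    def test_calibration_residual_nonincreasing_in_acs(self, rng):
        y = rng.standard_normal((3, 12, 24)) + 1j * rng.standard_normal((3, 12, 24))
        small = grappa_calibrate(y[:, :, :18], 2, tikhonov=0.0)
        big = grappa_calibrate(y[:, :, :24], 2, tikhonov=0.0)

        def sse(kern, wacs):
            t_all = np.arange(wacs)
            ok = (t_all - 1 + kern.col_offsets.min() >= 0) & (
                t_all - 1 + kern.col_offsets.max() < wacs
            )
            tv = t_all[ok]
            t_rows = np.repeat(np.arange(12), tv.size)
            t_cols = np.tile(tv, 12)
            S = _source_matrix(
                y[:, :, :wacs], t_rows, t_cols, 1, kern.row_offsets, kern.col_offsets
            )
            T = y[:, t_rows, t_cols].T
            return np.linalg.norm(T - S @ kern.weights[1].T) ** 2

        # the big-ACS least-squares fit beats the small-ACS kernel on the big system
        assert sse(big, 24) <= sse(small, 24) + 1e-9
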