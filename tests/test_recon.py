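"""Forward operator algebra and the Neumann / k-space recursions."""

import numpy as np
import pytest

import neumannmri as nm
from neumannmri.recon import ForwardModel, NeumannConfig, mdnnsm_series_t
from neumannmri.regularizer import make_regularizer
from neumannmri.sensitivity import SensitivityMaps
from conftest import random_multicoil


@pytest.fixture(scope="module")
def operators(small_scene):
    full = ForwardModel(nm.make_equispaced_mask(16, 1, 1.0), small_scene.maps)
    under = ForwardModel(small_scene.mask, small_scene.maps)
    return full, under


class TestForwardOperator:
    def test_full_mask_single_coil_is_fft(self, rng):
        A = ForwardModel(
            nm.make_equispaced_mask(16, 1, 1.0),
            SensitivityMaps(np.ones((1, 16, 16), complex)),
        )
        x = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
        assert np.abs(nm.forward_apply(A, x)[0] - nm.fft2c(x)).max() < 1e-12
        assert np.abs(nm.forward_adjoint(A, nm.fft2c(x)[None]) - x).max() < 1e-12

    def test_adjoint_inner_product_identity(self, rng, operators):
        _, A = operators
        for _ in range(100):
            x = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
            z = random_multicoil(rng)
            assert (
                abs(np.vdot(z, nm.forward_apply(A, x)) - np.vdot(nm.forward_adjoint(A, z), x))
                < 1e-8
            )

    def test_normal_operator_projection_like(self, rng, operators, small_scene):
        # A A^H A == A where the algebra makes it a projection: with a full
        # mask (S S^H S = S for normalized maps), and for single-coil
        # undersampled data (M F F^-1 M F = M F).  With undersampling AND
        # spatially varying maps the pixelwise coil projection S S^H does not
        # commute with F^-1 M F, so no such identity exists.
        full, _ = operators
        x = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
        ax = nm.forward_apply(full, x)
        again = nm.forward_apply(full, nm.forward_adjoint(full, ax))
        assert np.abs(again - ax).max() < 1e-8
        single = ForwardModel(
            small_scene.mask, SensitivityMaps(np.ones((1, 16, 16), complex))
        )
        ax = nm.forward_apply(single, x)
        again = nm.forward_apply(single, nm.forward_adjoint(single, ax))
        assert np.abs(again - ax).max() < 1e-8

    def test_full_recovery(self, rng, operators):
        full, _ = operators
        x = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
        assert np.abs(nm.forward_adjoint(full, nm.forward_apply(full, x)) - x).max() < 1e-10


class TestDataConsistencyBlock:
    def test_lambda_limits(self, rng, small_scene):
        k = random_multicoil(rng)
        m = small_scene.mask
        assert np.array_equal(nm.data_consistency_block(k, m, 0.0), k)
        out = nm.data_consistency_block(k, m, 1.0)
        assert np.all(out[..., m.mask] == 0)
        assert np.array_equal(out[..., ~m.mask], k[..., ~m.mask])
        full = nm.make_equispaced_mask(16, 1, 1.0)
        assert np.abs(nm.data_consistency_block(k, full, 1.0)).max() == 0


class TestNeumannClosedForms:
    def test_full_mask_lambda_one_exact(self, small_scene, operators):
        full, _ = operators
        y = nm.forward_apply(full, small_scene.image)
        cfg = NeumannConfig(num_blocks=6)
        xhat, state = nm.neumann_reconstruct(y, full, cfg, return_state=True)
        assert np.abs(xhat - small_scene.image).max() < 1e-10
        for it in state.iterates[1:]:
            assert np.abs(it).max() < 1e-12

    @pytest.mark.parametrize("N", range(7))
    def test_geometric_series_closed_form(self, N, small_scene, operators):
        full, _ = operators
        y = nm.forward_apply(full, small_scene.image)
        cfg = NeumannConfig(num_blocks=N, lambdas=0.5)
        xhat = nm.neumann_reconstruct(y, full, cfg)
        expected = (1 - 0.5 ** (N + 1)) * small_scene.image
        assert np.abs(xhat - expected).max() < 1e-10

    def test_matches_dense_pseudoinverse(self, rng):
        maps = nm.make_coil_maps(8, 8, 4, seed=5)
        m = nm.make_equispaced_mask(8, 2, 0.25)
        A = ForwardModel(m, maps)
        M = np.zeros((4 * 64, 64), complex)
        for i in range(64):
            e = np.zeros(64)
            e[i] = 1
            M[:, i] = nm.forward_apply(A, e.reshape(8, 8)).ravel()
        x = rng.random((8, 8))
        y = nm.forward_apply(A, x)
        x_pinv = (np.linalg.pinv(M) @ y.ravel()).reshape(8, 8)
        cfg = NeumannConfig(num_blocks=200, lambdas=1.0)
        xhat = nm.neumann_reconstruct(y, A, cfg)
        rel = np.linalg.norm(xhat - x_pinv) / np.linalg.norm(x_pinv)
        assert rel < 1e-4

    def test_linearity_in_y(self, rng, operators):
        _, A = operators
        y1, y2 = random_multicoil(rng), random_multicoil(rng)
        cfg = NeumannConfig(num_blocks=4, lambdas=0.7)
        lhs = nm.neumann_reconstruct(2.0 * y1 - 3.0j * y2, A, cfg)
        rhs = 2.0 * nm.neumann_reconstruct(y1, A, cfg) - 3.0j * nm.neumann_reconstruct(
            y2, A, cfg
        )
        assert np.abs(lhs - rhs).max() < 1e-8

    def test_nonfinite_iterate_reports_block(self, rng, operators):
        _, A = operators
        y = random_multicoil(rng)
        bad = lambda x: x * np.inf
        cfg = NeumannConfig(num_blocks=2, regularizer=bad)
        with pytest.raises(FloatingPointError, match="block 1"):
            nm.neumann_reconstruct(y, A, cfg)


class TestKspaceRecursion:
    def test_single_coil_equivalence_with_image_domain(self):
        sc = nm.make_scene(
            rows=16, cols=16, num_coils=1, acceleration=2, acs_fraction=0.25, seed=7
        )
        y, _ = nm.simulate_acquisition(sc)
        reg = make_regularizer("multi_domain", 1, np.random.default_rng(0))
        for k, p in reg.named_parameters():
            if "final" in k:
                p.data = np.random.default_rng(1).standard_normal(p.data.shape) * 0.1
        S = SensitivityMaps(np.ones((1, 16, 16), complex))
        A = ForwardModel(sc.mask, S)
        cfg_i = NeumannConfig(num_blocks=3, lambdas=0.8, regularizer=reg)
        cfg_k = NeumannConfig(
            num_blocks=3, lambdas=0.8, regularizer=reg, accumulate_domain="kspace"
        )
        x_img = nm.neumann_reconstruct(y, A, cfg_i)
        khat = mdnnsm_series_t(y, sc.mask, S, cfg_k).data
        assert np.abs(khat - nm.fft2c(x_img)).max() < 1e-8

    def test_full_mask_lambda_one_gives_rss_zero_fill(self, small_scene):
        y = nm.fft2c(nm.apply_maps(small_scene.maps, small_scene.image))
        full = nm.make_equispaced_mask(16, 1, 1.0)
        A = ForwardModel(full, small_scene.maps)
        cfg = NeumannConfig(num_blocks=4, accumulate_domain="kspace")
        xhat, state = nm.mdnnsm_reconstruct(y, A, cfg, return_state=True)
        np.testing.assert_allclose(xhat, nm.rss_combine(nm.ifft2c(y)), atol=1e-10)
        for it in state.iterates[1:]:
            assert np.abs(it).max() < 1e-12

    def test_zero_blocks_is_scaled_zero_fill(self, small_scene):
        y, _ = nm.simulate_acquisition(small_scene)
        A = ForwardModel(small_scene.mask, small_scene.maps)
        cfg = NeumannConfig(num_blocks=0, lambdas=0.5, accumulate_domain="kspace")
        xhat = nm.mdnnsm_reconstruct(y, A, cfg)
        expected = nm.rss_combine(nm.ifft2c(0.5 * nm.apply_mask(y, small_scene.mask)))
        np.testing.assert_allclose(xhat, expected, atol=1e-12)

    def test_accumulator_bookkeeping_bit_exact(self, small_scene):
        y, _ = nm.simulate_acquisition(small_scene)
        A = ForwardModel(small_scene.mask, small_scene.maps)
        reg = make_regularizer("image_only", 1, np.random.default_rng(2))
        for k, p in reg.named_parameters():
            if "final" in k:
                p.data = np.random.default_rng(3).standard_normal(p.data.shape) * 0.1
        cfg = NeumannConfig(num_blocks=5, regularizer=reg, accumulate_domain="kspace")
        _, state = nm.mdnnsm_reconstruct(y, A, cfg, return_state=True)
        resummed = state.iterates[0]
        for it in state.iterates[1:]:
            resummed = resummed + it
        assert np.array_equal(resummed, state.accumulator)

    def test_rss_magnitude_invariant_under_global_phase(self, noisy_scene):
        y, _ = nm.simulate_acquisition(noisy_scene)
        rot = np.exp(1j * 1.2345) * y
        cfg = NeumannConfig(num_blocks=3, accumulate_domain="kspace")
        a = nm.mdnnsm_reconstruct(
            y, ForwardModel(noisy_scene.mask, nm.acs_lowres_maps(y, noisy_scene.mask)), cfg
        )
        b = nm.mdnnsm_reconstruct(
            rot,
            ForwardModel(noisy_scene.mask, nm.acs_lowres_maps(rot, noisy_scene.mask)),
            cfg,
        )
        assert np.abs(a - b).max() < 1e-8


class TestSharedVsUnshared:
    def test_block_zero_identical(self, small_scene):
        # parameter sharing changes training, not the operator algebra
        y, _ = nm.simulate_acquisition(small_scene)
        A = ForwardModel(small_scene.mask, small_scene.maps)
        reg = make_regularizer("image_only", 1, np.random.default_rng(4))
        shared = NeumannConfig(num_blocks=3, regularizer=reg)
        unshared = NeumannConfig(num_blocks=3, regularizer=[reg, reg, reg])
        _, s1 = nm.neumann_reconstruct(y, A, shared, return_state=True)
        _, s2 = nm.neumann_reconstruct(y, A, unshared, return_state=True)
        assert np.array_equal(s1.iterates[0], s2.iterates[0])
        assert np.array_equal(s1.iterates[1], s2.iterates[1])
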