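"""NMSE/SSIM identities, the direct-formula SSIM oracle, and evaluation."""

import numpy as np
import pytest

from neumannmri.metrics import (
    EVAL_RANGE,
    evaluate_images,
    nmse,
    normalize_for_eval,
    ssim,
    ssim_loss,
)
from neumannmri.nn.autodiff import Tensor


def direct_formula_ssim(x, y, win, data_range):
    """Independent SSIM evaluation with explicit loops over valid windows."""
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    n = win * win
    vals = []
    for i in range(x.shape[0] - win + 1):
        for j in range(x.shape[1] - win + 1):
            a = x[i : i + win, j : j + win].ravel()
            b = y[i : i + win, j : j + win].ravel()
            mx, my = a.mean(), b.mean()
            vx = ((a - mx) ** 2).sum() / (n - 1)
            vy = ((b - my) ** 2).sum() / (n - 1)
            vxy = ((a - mx) * (b - my)).sum() / (n - 1)
            vals.append(
                ((2 * mx * my + c1) * (2 * vxy + c2))
                / ((mx**2 + my**2 + c1) * (vx + vy + c2))
            )
    return float(np.mean(vals))


class TestNmse:
    def test_identities(self, rng):
        x = rng.random((16, 16)) + 0.1
        assert nmse(x, x) == 0.0
        assert nmse(np.zeros_like(x), x) == pytest.approx(1.0)
        assert nmse(1.1 * x, x) == pytest.approx(0.01)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            nmse(np.ones((4, 4)), np.zeros((4, 4)))

    def test_not_symmetric(self, rng):
        x = rng.random((8, 8)) + 0.5
        assert nmse(2 * x, x) != nmse(x, 2 * x)


class TestSsim:
    def test_identical_images_give_one(self, rng):
        x = rng.random((16, 16))
        assert ssim(x, x, data_range=1.0) == pytest.approx(1.0, abs=1e-12)

    def test_constant_shift_lowers_luminance_term(self, rng):
        x = rng.random((16, 16))
        assert ssim(x + 5.0, x, data_range=1.0) < 1.0

    def test_matches_direct_formula_oracle(self, rng):
        x = np.indices((8, 8)).sum(axis=0) % 2.0  # checkerboard
        y = 1.0 - x
        mine = ssim(x, y, data_range=1.0, win=7)
        assert mine == pytest.approx(direct_formula_ssim(x, y, 7, 1.0), abs=1e-10)
        a, b = rng.random((12, 10)), rng.random((12, 10))
        assert ssim(a, b, data_range=1.0) == pytest.approx(
            direct_formula_ssim(a, b, 7, 1.0), abs=1e-10
        )

    def test_matches_skimage(self, rng):
        from skimage.metrics import structural_similarity

        a = rng.random((32, 32))
        b = np.clip(a + 0.1 * rng.standard_normal((32, 32)), 0, 1)
        ref = structural_similarity(
            b, a, data_range=1.0, win_size=7, gaussian_weights=False
        )
        assert ssim(b, a, data_range=1.0) == pytest.approx(ref, abs=1e-12)

    def test_symmetry(self, rng):
        a, b = rng.random((16, 16)), rng.random((16, 16))
        assert ssim(a, b, data_range=1.0) == pytest.approx(
            ssim(b, a, data_range=1.0), abs=1e-12
        )

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            ssim(np.ones((4, 4)), np.ones((4, 4)), data_range=1.0)


class TestSsimLoss:
    def test_zero_at_identity_and_bounded(self, rng):
        x = rng.random((16, 16))
        assert ssim_loss(Tensor(x), x).item() == pytest.approx(0.0, abs=1e-12)
        y = rng.random((16, 16))
        assert 0.0 <= ssim_loss(Tensor(y), x).item() <= 2.0

    def test_gradient_matches_finite_differences(self, rng):
        x = rng.random((10, 10))
        target = rng.random((10, 10))
        p = Tensor(x, requires_grad=True)
        loss = ssim_loss(p, target, data_range=1.0)
        loss.backward()
        d = rng.standard_normal((10, 10))
        eps = 1e-6
        lp = ssim_loss(Tensor(x + eps * d), target, data_range=1.0).item()
        lm = ssim_loss(Tensor(x - eps * d), target, data_range=1.0).item()
        assert np.sum(p.grad * d) == pytest.approx((lp - lm) / (2 * eps), rel=1e-5)


class TestEvaluate:
    def test_reference_against_itself(self, rng):
        x = rng.random((2, 16, 16))
        rep = evaluate_images(x, x, method="self")
        assert rep.mean_nmse == 0.0
        assert rep.mean_ssim == pytest.approx(1.0)
        assert [s["slice"] for s in rep.per_slice] == [0, 1]

    def test_invariant_to_joint_rescaling(self, rng):
        ref = rng.random((1, 16, 16))
        rec = ref + 0.05 * rng.standard_normal((1, 16, 16))
        a = evaluate_images(rec, ref)
        b = evaluate_images(37.0 * rec, 37.0 * ref)
        assert a.mean_nmse == pytest.approx(b.mean_nmse, rel=1e-10)
        assert a.mean_ssim == pytest.approx(b.mean_ssim, rel=1e-10)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            normalize_for_eval(np.ones((8, 8)))

    def test_normalization_range(self, rng):
        out = normalize_for_eval(rng.random((8, 8)))
        assert out.min() == 0.0 and out.max() == pytest.approx(EVAL_RANGE)
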