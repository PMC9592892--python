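"""Numerical checks of the autodiff core: convolution against a dense
brute-force oracle, and finite-difference gradient checks for every
differentiable operation the network uses."""

import numpy as np
import pytest
from scipy.signal import correlate2d

from lenseg.le_net import ds_dilated_conv
from lenseg.nn import functional as F
from lenseg.nn.autograd import Tensor


def inflate_kernel(k3: np.ndarray, rate: int) -> np.ndarray:
    """Zero-inflate a 3x3 kernel to the dense equivalent of dilation ``rate``."""
    size = 2 * rate + 1
    dense = np.zeros((size, size))
    dense[::rate, ::rate] = k3
    return dense


def oracle_ds_conv(x: np.ndarray, dw: np.ndarray, pw: np.ndarray, rate: int) -> np.ndarray:
    """Brute-force depthwise-separable dilated conv via dense correlation."""
    c, h, w = x.shape
    mid = np.stack([
        correlate2d(x[i], inflate_kernel(dw[i, 0], rate), mode="same")
        for i in range(c)
    ])
    return np.einsum("oc,chw->ohw", pw[:, :, 0, 0], mid)


class TestDilatedDepthwiseSeparableConv:
    @pytest.mark.parametrize("rate", [1, 6, 12, 18])
    def test_equals_zero_inflated_dense_conv(self, rate, rng):
        for _ in range(5):
            x = rng.normal(size=(3, 32, 32))
            dw = rng.normal(size=(3, 1, 3, 3))
            pw = rng.normal(size=(4, 3, 1, 1))
            ours = ds_dilated_conv(x, dw, pw, rate)
            ref = oracle_ds_conv(x, dw, pw, rate)
            assert ours.shape == ref.shape == (4, 32, 32)
            assert np.max(np.abs(ours - ref)) < 1e-6

    def test_impulse_response_rate_1(self):
        x = np.zeros((1, 5, 5))
        x[0, 2, 2] = 1.0
        dw = np.ones((1, 1, 3, 3))
        pw = np.ones((1, 1, 1, 1))
        out = ds_dilated_conv(x, dw, pw, 1)
        expected = np.zeros((1, 5, 5))
        expected[0, 1:4, 1:4] = 1.0
        assert np.array_equal(out, expected)

    def test_zero_input_zero_output(self, rng):
        out = ds_dilated_conv(
            np.zeros((2, 8, 8)), rng.normal(size=(2, 1, 3, 3)),
            rng.normal(size=(5, 2, 1, 1)), 6,
        )
        assert np.all(out == 0.0)

    def test_channel_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            ds_dilated_conv(
                np.zeros((3, 8, 8)), rng.normal(size=(2, 1, 3, 3)),
                rng.normal(size=(5, 2, 1, 1)), 1,
            )


def numeric_grad(fn, x, eps=1e-6):
    g = np.zeros_like(x)
    flat, gf = x.ravel(), g.ravel()
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        hi = fn()
        flat[i] = orig - eps
        lo = fn()
        flat[i] = orig
        gf[i] = (hi - lo) / (2 * eps)
    return g


class TestGradients:
    """Finite-difference checks of every backward implementation."""

    def check(self, make_out, *leaves):
        out = make_out()
        out.backward()
        for leaf in leaves:
            num = numeric_grad(lambda: make_out().item(), leaf.data)
            assert np.allclose(leaf.grad, num, atol=1e-5), (
                f"max err {np.abs(leaf.grad - num).max():.2e}"
            )

    def scalarize(self, t, w):
        # weighted sum -> scalar, with fixed random weights to probe all entries
        return Tensor((t.data * w).sum(), parents=((t, lambda g: g * w),))

    def test_conv2d_grads(self, rng):
        x = Tensor(rng.normal(size=(2, 4, 6, 6)), requires_grad=True)
        wt = Tensor(rng.normal(size=(6, 2, 3, 3)), requires_grad=True)
        b = Tensor(rng.normal(size=6), requires_grad=True)
        w = rng.normal(size=(2, 6, 6, 6))

        def make():
            out = F.conv2d(x, wt, b, stride=1, padding=2, dilation=2, groups=2)
            return self.scalarize(out, w)

        self.check(make, x, wt, b)

    def test_conv_transpose2d_grads(self, rng):
        x = Tensor(rng.normal(size=(1, 3, 4, 4)), requires_grad=True)
        wt = Tensor(rng.normal(size=(3, 2, 3, 3)), requires_grad=True)
        w = rng.normal(size=(1, 2, 8, 8))

        def make():
            return self.scalarize(F.conv_transpose2d(x, wt), w)

        self.check(make, x, wt)

    def test_batch_norm_grads(self, rng):
        x = Tensor(rng.normal(size=(3, 2, 4, 4)), requires_grad=True)
        gamma = Tensor(rng.normal(size=2) + 1.0, requires_grad=True)
        beta = Tensor(rng.normal(size=2), requires_grad=True)
        w = rng.normal(size=(3, 2, 4, 4))

        def make():
            rm, rv = np.zeros(2), np.ones(2)
            out = F.batch_norm(x, gamma, beta, rm, rv, training=True)
            return self.scalarize(out, w)

        self.check(make, x, gamma, beta)

    def test_bilinear_resize_grads(self, rng):
        x = Tensor(rng.normal(size=(1, 2, 5, 7)), requires_grad=True)
        w = rng.normal(size=(1, 2, 10, 14))

        def make():
            return self.scalarize(F.bilinear_resize(x, 10, 14), w)

        self.check(make, x)

    def test_pool_broadcast_grads(self, rng):
        x = Tensor(rng.normal(size=(2, 3, 4, 4)), requires_grad=True)
        w = rng.normal(size=(2, 3, 4, 4))

        def make():
            return self.scalarize(F.broadcast_spatial(F.spatial_mean(x), 4, 4), w)

        self.check(make, x)

    def test_softmax_cross_entropy_grads(self, rng):
        x = Tensor(rng.normal(size=(2, 3, 4, 4)), requires_grad=True)
        t = rng.dirichlet(np.ones(3), size=(2, 4, 4)).transpose(0, 3, 1, 2)

        def make():
            return F.softmax_cross_entropy(x, t)

        self.check(make, x)

    def test_soft_iou_loss_grads(self, rng):
        x = Tensor(rng.normal(size=(1, 3, 5, 5)), requires_grad=True)
        labels = rng.integers(0, 3, size=(5, 5))
        t = np.stack([(labels == k).astype(float) for k in range(3)])[None]

        def make():
            return F.soft_iou_loss(x, t)

        self.check(make, x)


class TestBilinearResize:
    def test_2x2_to_1x1_averages_corners(self):
        x = Tensor(np.array([[[[1.0, 0.0], [0.0, 1.0]]]]))
        out = F.bilinear_resize(x, 1, 1)
        assert np.isclose(out.data[0, 0, 0, 0], 0.5)

    def test_identity_at_same_size(self, rng):
        x = Tensor(rng.normal(size=(1, 1, 6, 5)))
        assert np.allclose(F.bilinear_resize(x, 6, 5).data, x.data)

    def test_constant_field_preserved(self):
        x = Tensor(np.full((1, 2, 8, 8), 3.25))
        assert np.allclose(F.bilinear_resize(x, 3, 5).data, 3.25)


def test_transposed_conv_doubles_resolution(rng):
    x = Tensor(rng.normal(size=(2, 3, 5, 5)))
    wt = Tensor(rng.normal(size=(3, 4, 3, 3)))
    assert F.conv_transpose2d(x, wt).shape == (2, 4, 10, 10)


def test_conv_transpose_adjoint_of_conv(rng):
    """<conv(x), y> == <x, conv_T(y)> with shared weights (transpose pair)."""
    x = rng.normal(size=(1, 3, 8, 8))
    y = rng.normal(size=(1, 5, 4, 4))
    w = rng.normal(size=(5, 3, 3, 3))
    cx = F.conv2d(Tensor(x), Tensor(w), stride=2, padding=1).data
    # same kernel reinterpreted as (C_in=5, C_out=3, kh, kw)
    cty = F.conv_transpose2d(Tensor(y), Tensor(w),
                             stride=2, padding=1, output_padding=1).data
    assert np.isclose((cx * y).sum(), (x * cty).sum())
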