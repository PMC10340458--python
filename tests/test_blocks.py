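"""CRNN cell, localization network, affine warp, and SARC/RC block behavior."""

import numpy as np
import pytest

from sarc_unet.blocks import (
    CrnnCell,
    IDENTITY_THETA,
    LocalizationNet,
    RcBlock,
    SarcBlock,
    apply_affine,
    identity_theta,
)
from sarc_unet.nn import Tensor, concat


from _oracles import warp_oracle

RNG = np.random.default_rng(0)


class TestApplyAffine:
    def test_identity_is_identity(self):
        x = Tensor(RNG.normal(size=(2, 3, 8, 8)).astype(np.float32))
        out = apply_affine(x, identity_theta(2))
        np.testing.assert_allclose(out.data, x.data, atol=1e-6)

    def test_integer_translation_matches_roll(self):
        # shift by exactly one pixel right: tx = 2/(W-1) in normalized units
        h = w = 7
        img = RNG.normal(size=(1, 1, h, w)).astype(np.float64)
        tx = 2.0 / (w - 1)
        theta = np.array([[[1.0, 0.0, tx], [0.0, 1.0, 0.0]]])
        out = apply_affine(Tensor(img), Tensor(theta)).data[0, 0]
        # sampling grid shifted right by one pixel: output column j reads input j+1
        expect = np.zeros_like(img[0, 0])
        expect[:, :-1] = img[0, 0][:, 1:]
        np.testing.assert_allclose(out, expect, atol=1e-5)

    def test_random_thetas_match_bruteforce_oracle(self):
        for _ in range(5):
            img = RNG.normal(size=(8, 8)).astype(np.float64)
            theta = np.array(
                [[1, 0, 0], [0, 1, 0]], dtype=np.float64
            ) + RNG.normal(0, 0.2, size=(2, 3))
            out = apply_affine(Tensor(img[None, None]), Tensor(theta[None])).data[0, 0]
            np.testing.assert_allclose(out, warp_oracle(img, theta), atol=1e-5)

    def test_nonfinite_theta_rejected(self):
        x = Tensor(np.zeros((1, 1, 4, 4)))
        bad = np.array([[[np.inf, 0, 0], [0, 1, 0]]])
        with pytest.raises(ValueError):
            apply_affine(x, Tensor(bad))


class TestCrnnCell:
    def test_zero_hidden_zero_input_zero_output(self):
        cell = CrnnCell(3, np.random.default_rng(1))  # bias starts at zero
        h = cell.init_hidden(2, 5, 5)
        out = cell(h, Tensor(np.zeros((2, 3, 5, 5), dtype=np.float32)))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_spatial_extent_preserved(self):
        cell = CrnnCell(4, np.random.default_rng(2))
        x = Tensor(RNG.normal(size=(1, 4, 9, 7)).astype(np.float32))
        out = cell(cell.init_hidden(1, 9, 7), x)
        assert out.shape == (1, 4, 9, 7)

    def test_single_site_matches_dot_product(self):
        # 1x1 spatial input: with "same" padding only the kernel center sees data
        cell = CrnnCell(2, np.random.default_rng(3))
        hid = np.array([0.5, -1.0], dtype=np.float32)
        x = np.array([2.0, 3.0], dtype=np.float32)
        out = cell(
            Tensor(hid.reshape(1, 2, 1, 1)), Tensor(x.reshape(1, 2, 1, 1))
        ).data.ravel()
        stacked = np.concatenate([hid, x])
        w_center = cell.conv.w.data[:, :, 1, 1]  # (out_ch, 4)
        expect = np.maximum(w_center @ stacked + cell.conv.b.data, 0.0)
        np.testing.assert_allclose(out, expect, rtol=1e-5)

    def test_spatial_mismatch_errors(self):
        cell = CrnnCell(2, np.random.default_rng(4))
        with pytest.raises(ValueError):
            cell(cell.init_hidden(1, 4, 4), Tensor(np.zeros((1, 2, 5, 5))))


class TestLocalizationNet:
    def test_identity_at_initialization_for_any_input(self):
        loc = LocalizationNet(4, 8, np.random.default_rng(5))
        x_pre = Tensor(RNG.normal(size=(3, 8, 4, 4)).astype(np.float32))
        hidden = Tensor(RNG.normal(size=(3, 4, 8, 8)).astype(np.float32))
        theta = loc(x_pre, hidden)
        np.testing.assert_allclose(
            theta.data, np.broadcast_to(IDENTITY_THETA, (3, 2, 3)), atol=1e-7
        )

    def test_elementwise_max_reduction(self):
        per_pixel = Tensor(
            np.array([[[1, 0, 0, 0, 1, 0], [2, -1, 0, 0, 1, 3]]], dtype=np.float32)
        )  # (1, 2 pixels, 6)
        reduced = per_pixel.max(axis=1)
        np.testing.assert_array_equal(reduced.data, [[2, 0, 0, 0, 1, 3]])

    def test_single_pixel_bypasses_reduction(self):
        # 1x1 pre-upsampling map: theta must equal that pixel's head output
        loc = LocalizationNet(4, 8, np.random.default_rng(6))
        loc.fc2.w.data[:] = np.random.default_rng(7).normal(size=loc.fc2.w.shape)
        x_pre = Tensor(RNG.normal(size=(1, 8, 1, 1)).astype(np.float32))
        hidden = Tensor(RNG.normal(size=(1, 4, 2, 2)).astype(np.float32))
        theta = loc(x_pre, hidden).data.reshape(6)
        # recompute the head by hand on the single pixel
        from sarc_unet.nn import functional as F

        pooled = F.avgpool2d(hidden, 2)
        feat = loc.norm(loc.conv(concat([x_pre, pooled], axis=1))).relu().data.reshape(4)
        h1 = np.maximum(feat @ loc.fc1.w.data + loc.fc1.b.data, 0)
        expect = h1 @ loc.fc2.w.data + loc.fc2.b.data
        np.testing.assert_allclose(theta, expect, rtol=1e-4, atol=1e-5)

    def test_pooling_mismatch_errors(self):
        loc = LocalizationNet(4, 8, np.random.default_rng(8))
        with pytest.raises(ValueError):
            loc(Tensor(np.zeros((1, 8, 3, 3))), Tensor(np.zeros((1, 4, 8, 8))))


def build_pair(channels=3, skip=3, pre=6, seed=9):
    """SARC block and an RC block sharing the recurrent/output weights."""
    sarc = SarcBlock(channels, skip, pre, np.random.default_rng(seed))
    rc = RcBlock(channels, skip, np.random.default_rng(seed + 1))
    rc.cell.load_state_dict(sarc.cell.state_dict())
    rc.out_conv.load_state_dict(sarc.out_conv.state_dict())
    return sarc, rc


class TestSarcVsRc:
    def test_first_step_identical_with_zero_hidden(self):
        sarc, rc = build_pair()
        x_t = Tensor(RNG.normal(size=(2, 3, 8, 8)).astype(np.float32))
        x_pre = Tensor(RNG.normal(size=(2, 6, 4, 4)).astype(np.float32))
        skip = Tensor(RNG.normal(size=(2, 3, 8, 8)).astype(np.float32))
        h0 = sarc.cell.init_hidden(2, 8, 8)
        out_s, h_s, _ = sarc(x_t, x_pre, h0, skip)
        out_r, h_r = rc(x_t, h0, skip)
        np.testing.assert_allclose(out_s.data, out_r.data, atol=1e-6)
        np.testing.assert_allclose(h_s.data, h_r.data, atol=1e-6)

    def test_identity_initialized_sarc_equals_rc_over_sequence(self):
        sarc, rc = build_pair()
        h_s = sarc.cell.init_hidden(1, 8, 8)
        h_r = rc.cell.init_hidden(1, 8, 8)
        for t in range(4):
            x_t = Tensor(RNG.normal(size=(1, 3, 8, 8)).astype(np.float32))
            x_pre = Tensor(RNG.normal(size=(1, 6, 4, 4)).astype(np.float32))
            skip = Tensor(RNG.normal(size=(1, 3, 8, 8)).astype(np.float32))
            out_s, h_s, theta = sarc(x_t, x_pre, h_s, skip)
            out_r, h_r = rc(x_t, h_r, skip)
            np.testing.assert_allclose(theta.data[0], IDENTITY_THETA, atol=1e-6)
            np.testing.assert_allclose(out_s.data, out_r.data, atol=1e-5)

    def test_zero_weights_zero_output(self):
        rc = RcBlock(2, 2, np.random.default_rng(10))
        for p in rc.parameters():
            p.data[:] = 0.0
        out, _ = rc(
            Tensor(RNG.normal(size=(1, 2, 4, 4)).astype(np.float32)),
            rc.cell.init_hidden(1, 4, 4),
            Tensor(RNG.normal(size=(1, 2, 4, 4)).astype(np.float32)),
        )
        np.testing.assert_array_equal(out.data, 0.0)

    def test_localization_gradient_nonzero_for_nonzero_hidden(self):
        sarc, _ = build_pair(seed=12)
        # move the head off identity so the warp actually samples off-grid
        rng = np.random.default_rng(13)
        sarc.localization.fc2.w.data[:] = rng.normal(0, 0.05, size=sarc.localization.fc2.w.shape)
        x_t = Tensor(rng.normal(size=(1, 3, 8, 8)).astype(np.float64))
        x_pre = Tensor(rng.normal(size=(1, 6, 4, 4)).astype(np.float64))
        skip = Tensor(rng.normal(size=(1, 3, 8, 8)).astype(np.float64))
        hidden = Tensor(rng.normal(size=(1, 3, 8, 8)).astype(np.float64))

        def loss_value():
            out, _, _ = sarc(x_t, x_pre, hidden, skip)
            return (out * out).sum()

        loss = loss_value()
        loss.backward()
        w = sarc.localization.fc1.w
        assert w.grad is not None and np.any(w.grad != 0)
        # finite-difference check on the largest-gradient entry
        idx = np.unravel_index(np.argmax(np.abs(w.grad)), w.grad.shape)
        eps = 1e-5
        orig = w.data[idx]
        w.data[idx] = orig + eps
        hi = float(loss_value().data)
        w.data[idx] = orig - eps
        lo = float(loss_value().data)
        w.data[idx] = orig
        fd = (hi - lo) / (2 * eps)
        # float32 parameters bound the attainable agreement
        assert fd == pytest.approx(float(w.grad[idx]), rel=5e-3, abs=1e-6)

    def test_outputs_finite_and_channels_invariant(self):
        sarc, _ = build_pair(seed=14)
        h = sarc.cell.init_hidden(1, 8, 8)
        for _ in range(3):
            out, h, _ = sarc(
                Tensor(RNG.normal(size=(1, 3, 8, 8)).astype(np.float32)),
                Tensor(RNG.normal(size=(1, 6, 4, 4)).astype(np.float32)),
                h,
                Tensor(RNG.normal(size=(1, 3, 8, 8)).astype(np.float32)),
            )
            assert np.all(np.isfinite(out.data))
            assert h.shape[1] == 3
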