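"""Difference-association module: LCE contrast, LCD, LSA."""

import numpy as np
import pytest

from ntsm import autodiff as ad
from ntsm.autodiff import Tensor
from ntsm.da_module import DAConfig, DAModule, LCD, LSA, lce_contrast

from oracles import instancenorm_ref, leaky_ref, lsa_ref


def make_lcd(in_c=3, out_c=8, seed=0, dtype=np.float64):
    return LCD(in_c, DAConfig(out_channels=out_c), np.random.default_rng(seed)).astype(dtype)


def make_lsa(out_c=8, seed=0, dtype=np.float64):
    return LSA(DAConfig(out_channels=out_c), np.random.default_rng(seed)).astype(dtype)


class TestLCEContrast:
    def test_equal_inputs_give_zero(self, rng):
        x = rng.normal(size=(2, 3, 5, 5))
        np.testing.assert_array_equal(lce_contrast(Tensor(x), Tensor(x.copy())).data, 0.0)

    def test_spatially_constant_difference_gives_zero(self, rng):
        """Instance normalization removes the per-slice mean."""
        x = rng.normal(size=(1, 3, 6, 6))
        shift = rng.normal(size=(1, 3, 1, 1)) * np.ones((1, 1, 6, 6))
        out = lce_contrast(Tensor(x + shift), Tensor(x)).data
        np.testing.assert_allclose(out, 0.0, atol=1e-4)

    def test_matches_scalar_loop_oracle(self, rng):
        a = rng.normal(size=(1, 3, 6, 6))
        b = rng.normal(size=(1, 3, 6, 6))
        want = leaky_ref(instancenorm_ref(a - b), 0.01)
        np.testing.assert_allclose(lce_contrast(Tensor(a), Tensor(b)).data, want, atol=1e-10)

    def test_zero_mean_before_activation(self, rng):
        """Instance-norm property: per-slice mean of the normalized difference is 0."""
        a, b = rng.normal(size=(2, 2, 4, 7, 7))
        diff = Tensor(a) - Tensor(b)
        mu = diff.mean(axis=(2, 3), keepdims=True)
        centered = diff - mu
        var = (centered * centered).mean(axis=(2, 3), keepdims=True)
        normed = (centered * ad.pow_const(var + 1e-5, -0.5)).data
        np.testing.assert_allclose(normed.mean(axis=(2, 3)), 0.0, atol=1e-10)

    def test_shape_mismatch_names_both_shapes(self):
        with pytest.raises(ValueError, match=r"1, 3, 4, 4.*1, 3, 5, 5"):
            lce_contrast(Tensor(np.zeros((1, 3, 4, 4))), Tensor(np.zeros((1, 3, 5, 5))))


class TestLCD:
    def test_output_shape(self, rng):
        lcd = make_lcd(in_c=32, out_c=32, dtype=np.float32)
        x = rng.normal(size=(2, 32, 64, 64)).astype(np.float32)
        assert lcd(Tensor(x)).shape == (2, 32, 64, 64)

    def test_zero_weights_give_zero_output(self, rng):
        lcd = make_lcd()
        for p in lcd.parameters():
            p.data[:] = 0.0
        x = rng.normal(size=(1, 3, 8, 8))
        np.testing.assert_allclose(lcd(Tensor(x)).data, 0.0, atol=1e-12)

    def test_perturbation_locality(self, rng):
        """A single-pixel change must not reach pixels far from the perturbed
        row and column (conv radius ≤ 17 on each axis; the 1-D pooled gates
        spread changes along the affected rows/columns only).  Instance norm
        inside LCE leaks a small global statistic, hence the relative floor."""
        lcd = make_lcd(in_c=3, out_c=4, seed=2)
        lcd.eval()
        x = rng.normal(size=(1, 3, 21, 21))
        base = lcd(Tensor(x)).data
        r0, c0 = 2, 3
        xp = x.copy()
        xp[0, :, r0, c0] += 1.0
        delta = np.abs(lcd(Tensor(xp)).data - base).max(axis=(0, 1))
        # widest receptive radius per axis: 3×3 conv at dilation 8 → 8 pixels,
        # well inside the conservative 1+2·8 bound
        rows = np.abs(np.arange(21) - r0)
        cols = np.abs(np.arange(21) - c0)
        far = (rows[:, None] > 8) & (cols[None, :] > 8)
        assert far.any()
        assert delta.max() > 0
        # instance-norm statistics couple all pixels weakly (≈1% here), so the
        # check is that far-field response is at least 20× below the near field
        assert delta[far].max() <= 5e-2 * delta.max()

    def test_sum_fusion_variant_builds(self, rng):
        cfg = DAConfig(out_channels=8, lce_fusion="sum")
        lcd = LCD(3, cfg, np.random.default_rng(0))
        x = rng.normal(size=(1, 3, 8, 8)).astype(np.float32)
        assert lcd(Tensor(x)).shape == (1, 8, 8, 8)


class TestLSA:
    def test_output_shape(self, rng):
        lsa = make_lsa(out_c=32, dtype=np.float32)
        x = rng.normal(size=(1, 32, 64, 64)).astype(np.float32)
        assert lsa(Tensor(x)).shape == (1, 32, 64, 64)

    def test_zero_weights_give_zero_output(self, rng):
        lsa = make_lsa()
        for p in lsa.parameters():
            p.data[:] = 0.0
        x = rng.normal(size=(1, 8, 9, 9))
        np.testing.assert_allclose(lsa(Tensor(x)).data, 0.0, atol=1e-12)

    def test_matches_straight_line_oracle(self, rng):
        lsa = make_lsa(out_c=8, seed=4)
        x = rng.normal(size=(1, 8, 9, 9))
        np.testing.assert_allclose(lsa(Tensor(x)).data, lsa_ref(x, lsa), atol=1e-5)

    def test_channel_mismatch_raises(self):
        lsa = make_lsa(out_c=8)
        with pytest.raises(ValueError, match="channels"):
            lsa(Tensor(np.zeros((1, 4, 8, 8))))

    def test_branches_3_and_4_not_weight_tied(self, rng):
        """Same topology, independent weights — and independently updated."""
        lsa = make_lsa(out_c=4, seed=9)
        w3 = lsa.b3.layers[0].weight
        w4 = lsa.b4.layers[0].weight
        assert not np.allclose(w3.data, w4.data)
        x = Tensor(rng.normal(size=(2, 4, 8, 8)))
        (lsa(x) ** 2).sum().backward()
        assert w3.grad is not None and w4.grad is not None
        assert not np.allclose(w3.grad, w4.grad)


class TestDAEndToEnd:
    @pytest.mark.parametrize("hw", [16, 33, 64])
    def test_shape_preserved_including_odd_extents(self, hw, rng):
        da = DAModule(3, DAConfig(out_channels=8), np.random.default_rng(0))
        x = rng.normal(size=(1, 3, hw, hw)).astype(np.float32)
        assert da(Tensor(x)).shape == (1, 8, hw, hw)
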