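"""Joint BCE + soft-Dice deep-supervision loss."""

import numpy as np
import pytest

from ntsm import autodiff as ad
from ntsm.autodiff import Tensor
from ntsm.losses import LossConfig, bce_dice_level_loss, deep_supervision_loss
from ntsm.model import SegmentationOutput


def probs_from_fg(p_fg):
    """Stack (background, foreground) probability channels."""
    p = np.asarray(p_fg, dtype=np.float64)[:, None]
    return Tensor(np.concatenate([1.0 - p, p], axis=1))


def level_loss_ref(p_fg, target, k=1.0, smooth=1e-5):
    """Straight-line per-level oracle."""
    p = np.clip(np.asarray(p_fg, dtype=np.float64), 1e-7, 1 - 1e-7)
    t = np.asarray(target, dtype=np.float64)
    bce = -(t * np.log(p) + (1 - t) * np.log(1 - p)).mean()
    pf = np.asarray(p_fg, dtype=np.float64)
    dice = (2 * (pf * t).sum() + smooth) / (pf.sum() + t.sum() + smooth)
    return bce + k * (1 - dice)


def test_perfect_prediction_is_almost_zero():
    t = np.array([[[1, 0], [1, 0]]], dtype=np.uint8)
    loss = bce_dice_level_loss(probs_from_fg(t.astype(float)), t, LossConfig())
    assert 0.0 <= loss.item() < 1e-4  # only the smoothing term remains


def test_uniform_half_prediction_gives_ln2_bce():
    t = np.array([[[1, 0, 1], [0, 1, 0]]], dtype=np.uint8)
    cfg = LossConfig()
    loss = bce_dice_level_loss(probs_from_fg(np.full(t.shape, 0.5)), t, cfg)
    # subtract the dice term computed by the oracle to isolate BCE = ln 2
    dice = (2 * 0.5 * 3 + cfg.smooth) / (0.5 * 6 + 3 + cfg.smooth)
    np.testing.assert_allclose(loss.item(), np.log(2.0) + (1 - dice), rtol=1e-6)


def test_fixed_2x2_example_matches_hand_arithmetic():
    """p = ((0.9, 0.1), (0.8, 0.2)), y = ((1, 0), (1, 0)):
    BCE = −¼·(ln .9 + ln .9 + ln .8 + ln .8); soft Dice = 2·1.7/(2.0+2.0)."""
    p_fg = np.array([[[0.9, 0.1], [0.8, 0.2]]])
    t = np.array([[[1, 0], [1, 0]]], dtype=np.uint8)
    cfg = LossConfig(smooth=1e-12)
    bce = -(np.log(0.9) * 2 + np.log(0.8) * 2) / 4
    dice = 2 * 1.7 / (2.0 + 2.0)
    want = bce + 1.0 * (1 - dice)
    got = bce_dice_level_loss(probs_from_fg(p_fg), t, cfg).item()
    np.testing.assert_allclose(got, want, rtol=1e-9)


def test_level_loss_matches_oracle_on_random_data(rng):
    p_fg = rng.random((2, 6, 6))
    t = (rng.random((2, 6, 6)) > 0.6).astype(np.uint8)
    got = bce_dice_level_loss(probs_from_fg(p_fg), t, LossConfig()).item()
    np.testing.assert_allclose(got, level_loss_ref(p_fg, t), rtol=1e-9)


def test_non_binary_target_rejected():
    with pytest.raises(ValueError, match="binary"):
        bce_dice_level_loss(probs_from_fg(np.full((1, 2, 2), 0.5)),
                            np.full((1, 2, 2), 2, dtype=np.uint8), LossConfig())


def test_deep_supervision_composes_level_losses(rng):
    """λ = (0.7, 0.3) two-level toy equals 0.7·L0 + 0.3·L1 from the oracle."""
    logits0 = rng.normal(size=(1, 2, 8, 8))
    logits1 = rng.normal(size=(1, 2, 4, 4))
    t = (rng.random((1, 8, 8)) > 0.5).astype(np.uint8)
    cfg = LossConfig(level_weights=(0.7, 0.3))
    out = SegmentationOutput(logits=[Tensor(logits0), Tensor(logits1)])
    got = deep_supervision_loss(out, t, cfg).item()

    def softmax_fg(z):
        e = np.exp(z - z.max(axis=1, keepdims=True))
        return (e / e.sum(axis=1, keepdims=True))[:, 1]

    want = 0.7 * level_loss_ref(softmax_fg(logits0), t) + 0.3 * level_loss_ref(
        softmax_fg(logits1), t[:, ::2, ::2]
    )
    np.testing.assert_allclose(got, want, rtol=1e-6)


def test_degenerate_weights_reduce_to_finest_level(rng):
    logits0 = rng.normal(size=(1, 2, 4, 4))
    logits1 = rng.normal(size=(1, 2, 2, 2))
    t = (rng.random((1, 4, 4)) > 0.5).astype(np.uint8)
    out = SegmentationOutput(logits=[Tensor(logits0), Tensor(logits1)])
    full = deep_supervision_loss(out, t, LossConfig(level_weights=(1.0, 0.0))).item()
    only0 = bce_dice_level_loss(ad.softmax(Tensor(logits0), 1), t, LossConfig()).item()
    np.testing.assert_allclose(full, only0, rtol=1e-9)


def test_level_count_mismatch_raises(rng):
    out = SegmentationOutput(logits=[Tensor(rng.normal(size=(1, 2, 4, 4)))])
    with pytest.raises(ValueError, match="levels"):
        deep_supervision_loss(out, np.zeros((1, 4, 4), dtype=np.uint8),
                              LossConfig(level_weights=(0.5, 0.5)))


def test_loss_nonnegative_and_zero_only_at_target(rng):
    t = (rng.random((1, 6, 6)) > 0.5).astype(np.uint8)
    for _ in range(20):
        p = rng.random((1, 6, 6))
        assert bce_dice_level_loss(probs_from_fg(p), t, LossConfig()).item() >= 0.0
    exact = bce_dice_level_loss(probs_from_fg(t.astype(float)), t, LossConfig()).item()
    off = bce_dice_level_loss(probs_from_fg(1.0 - t.astype(float)), t, LossConfig()).item()
    assert exact < 1e-4 < off


def test_dice_term_monotone_in_target_corruption(rng):
    """With the prediction fixed at the uncorrupted target, flipping target
    pixels (in either direction) never decreases the Dice-loss term."""
    base = (rng.random((1, 8, 8)) > 0.4).astype(np.uint8)
    p = base.astype(np.float64)
    cfg = LossConfig(smooth=1e-5)

    def dice_term(t):
        return 1 - (2 * (p * t).sum() + cfg.smooth) / (p.sum() + t.sum() + cfg.smooth)

    t = base.copy()
    flips = np.argwhere(np.ones_like(t[0], dtype=bool))
    rng.shuffle(flips)
    prev = dice_term(t)
    for r, c in flips[:20]:
        t[0, r, c] = 1 - t[0, r, c]
        cur = dice_term(t)
        assert cur >= prev - 1e-12
        prev = cur
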