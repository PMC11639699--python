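"""Sen/Spe/Dice/95HD metrics and efficiency indicators."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ntsm import nn
from ntsm.autodiff import Tensor
from ntsm.losses import LossConfig, bce_dice_level_loss
from ntsm.metrics import (
    ConfusionCounts,
    confusion,
    count_params,
    estimate_flops,
    hd95,
    ratio_metrics,
    summarize,
    write_metrics_csv,
    evaluate_pair,
)

from oracles import hausdorff_percentile_ref


def random_mask(rng, shape=(8, 8), p=0.5):
    return (rng.random(shape) < p).astype(np.uint8)


class TestConfusion:
    def test_all_ones(self):
        m = np.ones((4, 4), dtype=np.uint8)
        c = confusion(m, m)
        assert (c.tp, c.fp, c.fn, c.tn) == (16, 0, 0, 0)

    def test_complement_masks(self):
        t = np.zeros((3, 5), dtype=np.uint8)
        t[1] = 1
        c = confusion(1 - t, t)
        assert c.tp == 0 and c.tn == 0
        assert c.fp + c.fn == t.size

    def test_matches_pixel_loop(self, rng):
        p, t = random_mask(rng), random_mask(rng)
        tp = fp = fn = tn = 0
        for i in range(8):
            for j in range(8):
                if p[i, j] and t[i, j]:
                    tp += 1
                elif p[i, j]:
                    fp += 1
                elif t[i, j]:
                    fn += 1
                else:
                    tn += 1
        c = confusion(p, t)
        assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)
        assert c.total == 64

    def test_rejects_non_binary(self):
        with pytest.raises(ValueError, match="binary"):
            confusion(np.full((2, 2), 2), np.zeros((2, 2)))

    def test_rejects_shape_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion(np.zeros((2, 2)), np.zeros((3, 3)))


class TestRatioMetrics:
    def test_direct_substitution(self):
        sen, spe, dice = ratio_metrics(ConfusionCounts(tp=2, fp=1, fn=1, tn=12))
        assert dice == pytest.approx(4 / 6)
        assert sen == pytest.approx(2 / 3)
        assert spe == pytest.approx(12 / 13)

    def test_perfect_prediction(self):
        sen, spe, dice = ratio_metrics(ConfusionCounts(tp=5, fp=0, fn=0, tn=11))
        assert sen == spe == dice == 1.0

    def test_zero_denominators_flagged_none(self):
        sen, spe, dice = ratio_metrics(ConfusionCounts(tp=0, fp=0, fn=0, tn=4))
        assert sen is None and dice is None and spe == 1.0

    def test_matches_exact_fraction_oracle(self, rng):
        for _ in range(1000):
            tp, fp, fn, tn = (int(v) for v in rng.integers(0, 50, size=4))
            sen, spe, dice = ratio_metrics(ConfusionCounts(tp, fp, fn, tn))
            if tp + fn:
                assert abs(sen - Fraction(tp, tp + fn)) <= 1e-12
            else:
                assert sen is None
            if tn + fp:
                assert abs(spe - Fraction(tn, tn + fp)) <= 1e-12
            if fp + 2 * tp + fn:
                assert abs(dice - Fraction(2 * tp, fp + 2 * tp + fn)) <= 1e-12

    @given(st.tuples(*[st.integers(0, 10**6)] * 4))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_rational_exactness_property(self, counts):
        tp, fp, fn, tn = counts
        sen, spe, dice = ratio_metrics(ConfusionCounts(tp, fp, fn, tn))
        assert (sen is None) == (tp + fn == 0)
        assert (spe is None) == (tn + fp == 0)
        assert (dice is None) == (fp + 2 * tp + fn == 0)
        if dice is not None:
            assert 0.0 <= dice <= 1.0
            assert abs(dice - Fraction(2 * tp, fp + 2 * tp + fn)) <= 1e-12

    def test_invariant_under_transposition(self, rng):
        p, t = random_mask(rng, (6, 9)), random_mask(rng, (6, 9))
        assert ratio_metrics(confusion(p, t)) == ratio_metrics(confusion(p.T, t.T))


class TestHD95:
    def test_identical_masks_give_zero(self, rng):
        m = random_mask(rng)
        m[0, 0] = 1
        assert hd95(m, m) == 0.0

    def test_single_point_sets(self):
        a = np.zeros((8, 8), dtype=np.uint8)
        b = np.zeros((8, 8), dtype=np.uint8)
        a[0, 0] = 1
        b[0, 5] = 1
        assert hd95(a, b) == pytest.approx(5.0)

    def test_empty_mask_flagged_none(self):
        assert hd95(np.zeros((4, 4), dtype=np.uint8), np.ones((4, 4), dtype=np.uint8)) is None

    def test_matches_all_pairs_oracle_on_random_blobs(self, rng):
        for _ in range(10):
            a = random_mask(rng, (32, 32), p=0.1)
            b = random_mask(rng, (32, 32), p=0.1)
            if not a.any() or not b.any():
                continue
            assert hd95(a, b) == pytest.approx(hausdorff_percentile_ref(a, b), abs=1e-9)

    def test_bounded_by_exact_hausdorff(self, rng):
        for _ in range(10):
            a = random_mask(rng, (16, 16), p=0.2)
            b = random_mask(rng, (16, 16), p=0.2)
            if not a.any() or not b.any():
                continue
            assert hd95(a, b) <= hd95(a, b, percentile=100.0) + 1e-12


def test_dice_consistent_with_soft_dice_loss_on_binary_masks(rng):
    """1 − Dice-loss term (smooth→0) equals the confusion-matrix Dice."""
    p = random_mask(rng, (1, 8, 8), p=0.4)
    t = random_mask(rng, (1, 8, 8), p=0.4)
    probs = np.concatenate([(1 - p)[:, None], p[:, None]], axis=1).astype(np.float64)
    cfg = LossConfig(smooth=1e-12)
    loss = bce_dice_level_loss(Tensor(probs), t, cfg).item()
    bce = -(np.log(np.clip(np.where(t, p, 1 - p), 1e-7, 1 - 1e-7))).mean()
    dice_from_loss = 1 - (loss - bce)
    _, _, dice = ratio_metrics(confusion(p[0], t[0]))
    np.testing.assert_allclose(dice_from_loss, dice, atol=1e-9)


class TestEfficiency:
    def test_single_conv_param_count(self):
        conv = nn.Conv2d(1, 1, 1, np.random.default_rng(0))
        assert count_params(conv) == 2

    @pytest.mark.parametrize("c", range(1, 9))
    def test_3x3_conv_closed_form(self, c):
        conv = nn.Conv2d(c, c, 3, np.random.default_rng(0))
        assert count_params(conv) == 9 * c**2 + c

    def test_flops_monotone_in_input_area(self):
        conv = nn.Conv2d(2, 2, 3, np.random.default_rng(0), padding=1)
        f16 = estimate_flops(conv, (1, 2, 16, 16))
        f32 = estimate_flops(conv, (1, 2, 32, 32))
        assert f32 > f16 > 0


def test_metrics_csv_roundtrip(tmp_path, rng):
    reports = [evaluate_pair(random_mask(rng), random_mask(rng), f"s{i}") for i in range(3)]
    out = tmp_path / "m.csv"
    summary = write_metrics_csv(reports, out)
    lines = out.read_text().strip().splitlines()
    assert lines[0] == "id,sen,spe,dice,hd95"
    assert len(lines) == 5 and lines[-1].startswith("mean,")
    assert summary["n"] == 3


def test_summarize_excludes_undefined():
    from ntsm.metrics import MetricsReport

    reports = [MetricsReport(sen=1.0, spe=1.0, dice=1.0, hd95=None, id="a"),
               MetricsReport(sen=0.5, spe=1.0, dice=0.5, hd95=2.0, id="b")]
    s = summarize(reports)
    assert s["mean_hd95"] == 2.0 and s["n_undefined_hd95"] == 1
    assert s["mean_dice"] == 0.75
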