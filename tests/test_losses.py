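import numpy as np
import pytest

from podcount.annotations_io import ImageAnnotation
from podcount.autograd import Tensor
from podcount.boxes import Box
from podcount.losses import (
    LossBreakdown,
    NumberLossInputs,
    clip_counts,
    detection_loss,
    iou,
    log_softmax_300,
    number_loss,
    total_loss,
)


class TestLogSoftmax300:
    def test_uniform_logits_give_minus_log_300(self):
        out = log_softmax_300(np.zeros(300))
        assert np.allclose(out, -np.log(300))
        assert -np.log(300) == pytest.approx(-5.7038, abs=1e-4)

    def test_saturated_logit(self):
        x = np.zeros(300)
        x[17] = 40.0
        out = log_softmax_300(x)
        assert out[17] == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(out[np.arange(300) != 17], -40.0, atol=1e-6)

    def test_normalization_identity(self, rng):
        x = rng.standard_normal((5, 300)) * 10
        out = log_softmax_300(x)
        assert np.allclose(np.exp(out).sum(axis=-1), 1.0, atol=1e-9)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            log_softmax_300(np.zeros(299))
        bad = np.zeros(300)
        bad[0] = np.inf
        with pytest.raises(ValueError):
            log_softmax_300(bad)


class TestNumberLoss:
    def test_perfect_prediction_limit(self):
        logits = np.zeros((3, 300))
        targets = np.array([5, 100, 299])
        for i, t in enumerate(targets):
            logits[i, t] = 60.0
        assert number_loss(NumberLossInputs(logits, targets)) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_logits_any_targets(self):
        loss = number_loss(NumberLossInputs(np.zeros((4, 300)), np.array([0, 33, 61, 299])))
        assert loss == pytest.approx(np.log(300), abs=1e-6)
        assert loss == pytest.approx(5.7038, abs=1e-4)

    def test_hand_average_of_per_image_nlls(self):
        # craft distributions whose NLL at the target is exactly 1.0 and 3.0
        logits = np.zeros((2, 300))
        for b, nll in enumerate((1.0, 3.0)):
            p_t = np.exp(-nll)
            rest = (1 - p_t) / 299
            logits[b] = np.log(rest)
            logits[b, 42] = np.log(p_t)
        loss = number_loss(NumberLossInputs(logits, np.array([42, 42])))
        assert loss == pytest.approx(2.0, abs=1e-6)

    def test_tensor_path_matches_numpy_and_backprops(self, rng):
        x = rng.standard_normal((3, 300)).astype(np.float32)
        targets = np.array([1, 2, 3])
        ref = number_loss(NumberLossInputs(x.copy(), targets))
        t = Tensor(x, requires_grad=True)
        out = number_loss(NumberLossInputs(t, targets))
        assert float(out.data) == pytest.approx(ref, abs=1e-5)
        out.backward()
        assert t.grad is not None and np.isfinite(t.grad).all()

    def test_out_of_range_targets_error_and_clip(self):
        with pytest.raises(ValueError):
            NumberLossInputs(np.zeros((1, 300)), np.array([300]))
        with pytest.warns(UserWarning):
            assert clip_counts(np.array([5, 420])).tolist() == [5, 299]


class TestTotalLoss:
    @pytest.mark.parametrize(
        "l_num, l_yolo, expected",
        [(0.0, 1.0, 1.0), (1.0, 0.0, 0.3), (2.0, 1.5, 2.1)],
    )
    def test_weighted_sum(self, l_num, l_yolo, expected):
        assert total_loss(l_num, l_yolo) == pytest.approx(expected)

    def test_linearity_and_breakdown(self):
        b = LossBreakdown(l_num=2.0, l_yolo=1.5)
        assert b.l_total == pytest.approx(0.3 * 2.0 + 1.0 * 1.5)


class TestIoU:
    def test_examples(self):
        x = Box(0, 0, 2, 2)
        assert iou(x, x) == 1.0
        assert iou(x, Box(10, 10, 12, 12)) == 0.0
        assert iou(x, Box(1, 0, 3, 2)) == pytest.approx(1 / 3)


def _raw_single_scale_64(reg_map, obj_map, cls_map):
    """Wrap hand-built 64x64-input maps (strides 8/16/32) into raw format."""
    scales = []
    for s, (reg, obj, cls) in zip((8, 16, 32), zip(reg_map, obj_map, cls_map)):
        scales.append(
            {
                "cls": Tensor(cls, requires_grad=True),
                "reg": Tensor(reg, requires_grad=True),
                "obj": Tensor(obj, requires_grad=True),
            }
        )
    return {"scales": scales}


def _bce(x, t):
    return np.maximum(x, 0) - x * t + np.log1p(np.exp(-np.abs(x)))


def brute_force_center_loss(regs, objs, clss, gt_boxes, radius=1.5):
    """Independent evaluation of the centre-assigned detection loss on a
    64x64 instance: explicit loops, no shared code with the implementation."""
    anchors = []  # (scale_idx, iy, ix, stride)
    for si, s in enumerate((8, 16, 32)):
        n = 64 // s
        for iy in range(n):
            for ix in range(n):
                anchors.append((si, iy, ix, s))
    # assignment: nearest gt centre within radius*stride (chebyshev)
    assign = []
    for (si, iy, ix, s) in anchors:
        cx, cy = (ix + 0.5) * s, (iy + 0.5) * s
        best, best_d = -1, np.inf
        for g, (x0, y0, x1, y1) in enumerate(gt_boxes):
            gcx, gcy = (x0 + x1) / 2, (y0 + y1) / 2
            if abs(cx - gcx) < radius * s and abs(cy - gcy) < radius * s:
                d = (cx - gcx) ** 2 + (cy - gcy) ** 2
                if d < best_d:
                    best, best_d = g, d
        assign.append(best)
    num_fg = sum(1 for a in assign if a >= 0)
    obj_loss = 0.0
    iou_loss = 0.0
    cls_loss = 0.0
    for (si, iy, ix, s), a in zip(anchors, assign):
        xo = objs[si][0, 0, iy, ix]
        obj_loss += _bce(xo, 1.0 if a >= 0 else 0.0)
        if a < 0:
            continue
        reg = regs[si][0, :, iy, ix]
        cx, cy = (reg[0] + ix) * s, (reg[1] + iy) * s
        bw, bh = np.exp(reg[2]) * s, np.exp(reg[3]) * s
        px0, py0, px1, py1 = cx - bw / 2, cy - bh / 2, cx + bw / 2, cy + bh / 2
        gx0, gy0, gx1, gy1 = gt_boxes[a]
        iw = max(min(px1, gx1) - max(px0, gx0), 0.0)
        ih = max(min(py1, gy1) - max(py0, gy0), 0.0)
        inter = iw * ih
        union = bw * bh + (gx1 - gx0) * (gy1 - gy0) - inter + 1e-8
        iou_loss += 1.0 - inter / union
        cls_loss += _bce(clss[si][0, 0, iy, ix], 1.0)
    norm = max(num_fg, 1)
    return 5.0 * iou_loss / norm + obj_loss / norm + cls_loss / norm, num_fg


class TestDetectionLoss:
    def _maps(self, rng, fill_obj=-3.0):
        regs = [rng.standard_normal((1, 4, 64 // s, 64 // s)).astype(np.float32) * 0.3 for s in (8, 16, 32)]
        objs = [np.full((1, 1, 64 // s, 64 // s), fill_obj, dtype=np.float32) for s in (8, 16, 32)]
        clss = [rng.standard_normal((1, 1, 64 // s, 64 // s)).astype(np.float32) for s in (8, 16, 32)]
        return regs, objs, clss

    def test_matches_brute_force_oracle_on_single_box(self, rng):
        regs, objs, clss = self._maps(rng)
        gt = [(18.0, 22.0, 38.0, 44.0)]
        ann = ImageAnnotation("t", 64, 64, [Box(*gt[0])])
        raw = _raw_single_scale_64(regs, objs, clss)
        out = detection_loss(raw, [ann], assigner="center")
        expected, num_fg = brute_force_center_loss(regs, objs, clss, gt)
        assert out["num_fg"] == num_fg > 0
        assert float(out["l_yolo"].data) == pytest.approx(expected, rel=1e-4)

    def test_matches_brute_force_on_multiple_boxes(self, rng):
        regs, objs, clss = self._maps(rng)
        gt = [(2.0, 2.0, 20.0, 18.0), (40.0, 30.0, 60.0, 62.0), (22.0, 40.0, 34.0, 58.0)]
        ann = ImageAnnotation("t", 64, 64, [Box(*g) for g in gt])
        raw = _raw_single_scale_64(regs, objs, clss)
        out = detection_loss(raw, [ann], assigner="center")
        expected, num_fg = brute_force_center_loss(regs, objs, clss, gt)
        assert out["num_fg"] == num_fg
        assert float(out["l_yolo"].data) == pytest.approx(expected, rel=1e-4)

    def test_empty_targets_all_negative_is_near_zero(self):
        regs = [np.zeros((1, 4, 64 // s, 64 // s), dtype=np.float32) for s in (8, 16, 32)]
        objs = [np.full((1, 1, 64 // s, 64 // s), -40.0, dtype=np.float32) for s in (8, 16, 32)]
        clss = [np.zeros((1, 1, 64 // s, 64 // s), dtype=np.float32) for s in (8, 16, 32)]
        raw = _raw_single_scale_64(regs, objs, clss)
        ann = ImageAnnotation("t", 64, 64, [])
        out = detection_loss(raw, [ann], assigner="simota")
        assert out["num_fg"] == 0
        assert float(out["l_yolo"].data) == pytest.approx(0.0, abs=1e-6)

    def test_perfect_encoding_zeroes_iou_term(self):
        # every anchor encodes the gt box exactly, so IoU = 1 at all positives
        gt = Box(20.0, 20.0, 36.0, 36.0)
        gcx, gcy, gw, gh = 28.0, 28.0, 16.0, 16.0
        regs, objs, clss = [], [], []
        for s in (8, 16, 32):
            n = 64 // s
            reg = np.zeros((1, 4, n, n), dtype=np.float32)
            for iy in range(n):
                for ix in range(n):
                    reg[0, :, iy, ix] = (
                        gcx / s - ix, gcy / s - iy, np.log(gw / s), np.log(gh / s)
                    )
            regs.append(reg)
            objs.append(np.full((1, 1, n, n), -40.0, dtype=np.float32))
            clss.append(np.full((1, 1, n, n), 40.0, dtype=np.float32))
        raw = _raw_single_scale_64(regs, objs, clss)
        ann = ImageAnnotation("t", 64, 64, [gt])
        out = detection_loss(raw, [ann], assigner="center")
        assert out["num_fg"] >= 1
        assert float(out["iou"].data) == pytest.approx(0.0, abs=1e-5)

    def test_gradients_flow_to_all_maps(self, rng):
        regs, objs, clss = self._maps(rng)
        ann = ImageAnnotation("t", 64, 64, [Box(10, 10, 30, 30)])
        raw = _raw_single_scale_64(regs, objs, clss)
        out = detection_loss(raw, [ann], assigner="simota")
        out["l_yolo"].backward()
        for sc in raw["scales"]:
            assert sc["obj"].grad is not None
            assert np.isfinite(sc["obj"].grad).all()
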