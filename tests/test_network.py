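import dataclasses

import numpy as np
import pytest

from podcount.autograd import Tensor, no_grad
from podcount.boxes import Box
from podcount.layers import Conv2d
from podcount.network import (
    CBAM,
    ModelConfig,
    _Rng,
    build_model,
    count_flops,
    count_parameters,
    decode_predictions,
    spp_forward,
    sppf_forward,
)


def t(arr):
    return Tensor(np.asarray(arr, dtype=np.float32))


class TestSPPF:
    def test_constant_input_unchanged(self):
        x = t(np.full((1, 2, 8, 8), 3.0))
        for y in sppf_forward(x):
            assert np.allclose(y.data, 3.0)

    def test_equals_spp_5_9_13_on_random_input(self, rng):
        """Chained k=5 poolings reproduce parallel kernels {5, 9, 13} exactly."""
        x = t(rng.standard_normal((1, 8, 16, 16)))
        fast = sppf_forward(x)
        classic = spp_forward(x)
        for a, b in zip(fast, classic):
            assert np.array_equal(a.data, b.data)

    def test_preserves_spatial_dims(self, rng):
        x = t(rng.standard_normal((2, 3, 11, 7)))
        for y in sppf_forward(x):
            assert y.shape == x.shape


class TestCBAM:
    def make(self, c=16):
        return CBAM(c, reduction=4, rng=_Rng(0))

    def test_output_shape_and_attention_range(self, rng):
        cbam = self.make()
        x = t(rng.standard_normal((2, 16, 6, 6)))
        out = cbam(x)
        assert out.shape == x.shape
        # attention gates are sigmoids, so |out| can never exceed |x|
        assert np.all(np.abs(out.data) <= np.abs(x.data) + 1e-6)

    def test_spatially_constant_input_gives_constant_spatial_map(self):
        # channel mean/max maps of a spatially constant input are constant,
        # so away from the 7x7 conv's zero-padded border the spatial
        # attention (and hence the output) is spatially constant too
        cbam = self.make()
        x = t(np.broadcast_to(np.arange(16.0).reshape(1, 16, 1, 1), (1, 16, 16, 16)).copy())
        out = cbam(x).data[:, :, 3:-3, 3:-3]
        assert np.allclose(out, out[:, :, :1, :1], atol=1e-6)

    def test_reduction_must_divide_channels(self):
        with pytest.raises(ValueError):
            CBAM(10, reduction=4, rng=_Rng(0))


class TestNumberHead:
    def test_logits_shape_and_batch(self, tiny_model, rng):
        res = tiny_model.config.input_resolution
        for b in (1, 3):
            x = t(rng.standard_normal((b, 3, res, res)) * 0.1)
            with no_grad():
                out = tiny_model.forward(x)
            assert out["count_logits"].shape == (b, 300)

    def test_zero_init_gives_uniform_distribution(self, tiny_model, rng):
        res = tiny_model.config.input_resolution
        x = t(rng.standard_normal((1, 3, res, res)) * 0.1)
        with no_grad():
            logits = tiny_model.forward(x)["count_logits"].data
        assert np.allclose(logits, 0.0)

    def test_inference_mode_has_no_count_head(self, tiny_config, rng):
        model = build_model(dataclasses.replace(tiny_config, mode="inference"))
        res = model.config.input_resolution
        x = t(rng.standard_normal((1, 3, res, res)))
        with pytest.raises(RuntimeError, match="inference"):
            model.forward(x, with_count=True)

    def test_resolution_mismatch_detected(self, tiny_model, rng):
        x = t(rng.standard_normal((1, 3, 96, 96)))
        with pytest.raises(ValueError, match="resolution"):
            tiny_model.forward(x)


class TestBuildModel:
    def test_inference_strictly_smaller_than_training(self, tiny_config):
        train = build_model(tiny_config)
        infer = build_model(dataclasses.replace(tiny_config, mode="inference"))
        assert count_parameters(infer) < count_parameters(train)
        diff = count_parameters(train) - count_parameters(infer)
        assert diff == train.number_head.num_parameters()

    def test_feature_map_sizes_follow_strides(self, tiny_model, rng):
        res = tiny_model.config.input_resolution
        x = t(rng.standard_normal((1, 3, res, res)) * 0.1)
        with no_grad():
            out = tiny_model.forward(x)
        for maps, s in zip(out["scales"], (8, 16, 32)):
            assert maps["cls"].shape[2:] == (res // s, res // s)
            assert maps["reg"].shape[1] == 4
            assert maps["obj"].shape[1] == 1

    def test_stem_variants_same_geometry(self, rng):
        cfg = ModelConfig(
            depth_multiplier=0.34, width_multiplier=0.25, mode="inference",
            input_resolution=64,
        )
        conv_stem = build_model(cfg)
        focus_stem = build_model(dataclasses.replace(cfg, stem="focus"))
        x = t(rng.standard_normal((1, 3, 64, 64)))
        with no_grad():
            a = conv_stem.backbone.stem(x)
            b = focus_stem.backbone.stem(x)
        assert a.shape == b.shape == (1, 16, 32, 32)
        # identical cost too: 3*6*6 = 12*3*3 weights per output channel
        assert (
            conv_stem.backbone.stem.num_parameters()
            == focus_stem.backbone.stem.num_parameters()
        )

    def test_count_head_decoupled_from_detections(self, tiny_config, rng):
        """Same weights with and without the count branch give identical
        detection maps: the auxiliary head is outside the inference path."""
        model = build_model(tiny_config)
        res = tiny_config.input_resolution
        x = t(rng.standard_normal((1, 3, res, res)) * 0.1)
        model.eval()
        with no_grad():
            with_count = model.forward(x, with_count=True)
            without = model.forward(x, with_count=False)
        for a, b in zip(with_count["scales"], without["scales"]):
            for k in ("cls", "reg", "obj"):
                assert np.array_equal(a[k].data, b[k].data)
        # perturbing count-head weights must not move any detection output
        for p in model.number_head.parameters():
            p.data += 1.0
        with no_grad():
            perturbed = model.forward(x, with_count=False)
        for a, b in zip(without["scales"], perturbed["scales"]):
            assert np.array_equal(a["obj"].data, b["obj"].data)

    def test_forward_deterministic(self, tiny_model, rng):
        res = tiny_model.config.input_resolution
        x = np.asarray(rng.standard_normal((1, 3, res, res)), dtype=np.float32)
        tiny_model.eval()
        with no_grad():
            a = tiny_model.forward(t(x))["scales"][0]["reg"].data
            b = tiny_model.forward(t(x))["scales"][0]["reg"].data
        assert np.array_equal(a, b)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(depth_multiplier=0.0)
        with pytest.raises(ValueError):
            ModelConfig(input_resolution=100)
        with pytest.raises(ValueError):
            ModelConfig(mode="predict")


class TestAccounting:
    def test_single_conv_params_closed_form(self):
        conv = Conv2d(3, 1, 1, bias=True)
        assert conv.num_parameters() == 4  # 3 weights + 1 bias

    def test_single_conv_flops_closed_form(self, rng):
        from podcount.autograd import conv2d, trace_ops

        x = Tensor(rng.standard_normal((1, 1, 10, 10)).astype(np.float32))
        w = Tensor(rng.standard_normal((1, 1, 3, 3)).astype(np.float32))
        with trace_ops() as rec:
            conv2d(x, w, None, stride=1, padding=1)
        assert rec["macs"] == 9 * 100

    def test_flops_scale_quadratically(self, tiny_config):
        model = build_model(dataclasses.replace(tiny_config, mode="inference"))
        f64 = count_flops(model, 64)
        f128 = count_flops(model, 128)
        assert f128 / f64 == pytest.approx(4.0, rel=0.01)


class TestDecode:
    def make_raw(self, obj_logit, n=1, h=2, w=2, ncls=1):
        scales = []
        for _ in range(3):
            scales.append(
                {
                    "cls": np.full((n, ncls, h, w), 10.0, dtype=np.float32),
                    "reg": np.zeros((n, 4, h, w), dtype=np.float32),
                    "obj": np.full((n, 1, h, w), obj_logit, dtype=np.float32),
                }
            )
            h, w = max(h // 2, 1), max(w // 2, 1)
        return {"scales": scales}

    def test_all_suppressed_objectness_gives_empty(self):
        raw = self.make_raw(obj_logit=-40.0)
        assert decode_predictions(raw, 0.25, 0.65) == [[]]

    def test_single_confident_location_survives(self):
        raw = self.make_raw(obj_logit=-40.0)
        raw["scales"][0]["obj"][0, 0, 0, 0] = 40.0
        dets = decode_predictions(raw, 0.25, 0.65)[0]
        assert len(dets) == 1
        b = dets[0]
        # centre at grid (0,0) * stride 8, size e^0 * 8
        assert (b.x_min, b.y_min, b.x_max, b.y_max) == (-4.0, -4.0, 4.0, 4.0)

    def test_nms_keeps_higher_scored_of_overlapping_pair(self):
        a = Box(0, 0, 10, 10, score=0.9)
        b = Box(0, 1, 10, 11, score=0.8)  # IoU 9/11 ~ 0.82
        from podcount.boxes import greedy_nms

        kept = greedy_nms([a, b], 0.65)
        assert kept == [a]

    def test_threshold_validation(self):
        raw = self.make_raw(0.0)
        with pytest.raises(ValueError):
            decode_predictions(raw, -0.1, 0.5)
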