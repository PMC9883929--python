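import dataclasses
import warnings

import numpy as np
import pytest

from podcount.augment import AugmentConfig
from podcount.network import ModelConfig, build_model
from podcount.synthetic import easy_scene_config, generate_scene
from podcount.training import (
    AdamW,
    ImageDataset,
    StageConfig,
    default_stage1,
    default_stage2,
    load_checkpoint,
    lr_at,
    run_stage,
    save_checkpoint,
    train_full,
)

warnings.filterwarnings("ignore", message="overflow")

RES = 64
AUG = AugmentConfig(p_crop=1.0, p_mosaic=0.0, p_mixup=0.0, target_size=RES)


@pytest.fixture(scope="module")
def small_data():
    cfg = easy_scene_config(RES, max_count=4, seed=11)
    return ImageDataset.from_scenes([generate_scene(cfg, i) for i in range(8)])


def tiny_cfg(seed=0):
    return ModelConfig(
        depth_multiplier=0.34,
        width_multiplier=0.25,
        mode="training",
        input_resolution=RES,
        init_seed=seed,
    )


def stage(sid, epochs, lr=1e-3, batch=4, scope=None):
    scope = scope or ("heads-only" if sid == 1 else "full-model")
    return StageConfig(sid, epochs, lr, 0.9, batch, scope)


class TestSchedule:
    def test_published_defaults(self):
        s1, s2 = default_stage1(), default_stage2()
        assert (s1.epochs, s1.initial_lr, s1.gamma, s1.batch_size) == (5, 1e-3, 0.92, 8)
        assert (s2.epochs, s2.initial_lr, s2.gamma, s2.batch_size) == (55, 1e-4, 0.90, 2)
        assert s1.epochs + s2.epochs == 60

    def test_lr_at_examples(self):
        assert lr_at(default_stage1(), 0) == pytest.approx(1e-3)
        assert lr_at(default_stage2(), 0) == pytest.approx(1e-4)
        assert lr_at(default_stage1(), 3) == pytest.approx(1e-3 * 0.92**3)
        assert lr_at(default_stage1(), 3) == pytest.approx(7.787e-4, rel=1e-3)

    def test_lr_strictly_decreasing(self):
        s = default_stage2()
        lrs = [lr_at(s, e) for e in range(s.epochs)]
        assert all(a > b for a, b in zip(lrs, lrs[1:]))

    def test_lr_out_of_range(self):
        with pytest.raises(IndexError):
            lr_at(default_stage1(), 5)

    def test_stage_config_validation(self):
        with pytest.raises(ValueError):
            StageConfig(3, 1, 1e-3, 0.9, 1, "full-model")
        with pytest.raises(ValueError):
            StageConfig(1, 1, 1e-3, 0.0, 1, "heads-only")
        with pytest.raises(ValueError):
            StageConfig(1, 1, 1e-3, 0.9, 1, "everything")


class TestAdamW:
    def test_minimizes_quadratic(self):
        from podcount.layers import Parameter

        p = Parameter(np.array([5.0, -3.0]))
        opt = AdamW([p], lr=0.1, weight_decay=0.0)
        for _ in range(200):
            p.grad = 2 * p.data
            opt.step()
        assert np.abs(p.data).max() < 1e-2

    def test_no_decay_on_1d_params(self):
        from podcount.layers import Parameter

        p = Parameter(np.array([1.0]))
        opt = AdamW([p], lr=0.1, weight_decay=0.5)
        p.grad = np.array([0.0])
        opt.step()
        # zero gradient and no decay on 1-D (bias/norm) parameters
        assert p.data[0] == pytest.approx(1.0)


class TestRunStage:
    def test_stage1_backbone_bitwise_frozen(self, small_data):
        model = build_model(tiny_cfg())
        before = {k: v.copy() for k, v in model.backbone.state_dict().items()}
        neck_before = {k: v.copy() for k, v in model.neck.state_dict().items()}
        run_stage(model, small_data, stage(1, 1), AUG, seed=0)
        for k, v in model.backbone.state_dict().items():
            if "running" in k:
                continue  # batch-norm statistics track activations by design
            assert np.array_equal(before[k], v), k
        for k, v in model.neck.state_dict().items():
            if "running" in k:
                continue
            assert np.array_equal(neck_before[k], v), k

    def test_heads_change_in_stage1(self, small_data):
        model = build_model(tiny_cfg())
        before = {k: v.copy() for k, v in model.heads.state_dict().items()}
        run_stage(model, small_data, stage(1, 1), AUG, seed=0)
        changed = any(
            not np.array_equal(before[k], v)
            for k, v in model.heads.state_dict().items()
            if "running" not in k
        )
        assert changed

    def test_two_epoch_descent_on_easy_scenes(self, small_data):
        model = build_model(tiny_cfg())
        st = run_stage(model, small_data, stage(2, 2, lr=2e-3), AUG, seed=0)
        losses = [h["mean_loss"] for h in st.loss_history]
        assert losses[-1] < losses[0]

    def test_full_precision_determinism(self, small_data):
        curves = []
        for _ in range(2):
            model = build_model(tiny_cfg())
            st = run_stage(model, small_data, stage(2, 1), AUG, seed=5)
            curves.append([h["mean_loss"] for h in st.loss_history])
        assert curves[0] == curves[1]

    def test_mixed_precision_close_to_full(self, small_data):
        finals = []
        for mixed in (False, True):
            model = build_model(tiny_cfg())
            st = run_stage(
                model, small_data, stage(2, 1), AUG, seed=5, mixed_precision=mixed
            )
            finals.append(st.loss_history[-1]["mean_loss"])
        assert abs(finals[0] - finals[1]) / finals[0] < 1e-2

    def test_empty_dataset_error(self):
        model = build_model(tiny_cfg())
        with pytest.raises(ValueError):
            ImageDataset([])

    def test_inference_model_rejected(self, small_data):
        model = build_model(dataclasses.replace(tiny_cfg(), mode="inference"))
        with pytest.raises(ValueError, match="training"):
            run_stage(model, small_data, stage(1, 1), AUG, seed=0)


class TestCheckpoint:
    def test_roundtrip_bit_identical(self, tmp_path, small_data):
        model = build_model(tiny_cfg())
        st = run_stage(model, small_data, stage(2, 1), AUG, seed=1)
        path = tmp_path / "ck.npz"
        save_checkpoint(model, path, st)
        model2, st2 = load_checkpoint(path)
        for (k1, v1), (k2, v2) in zip(
            sorted(model.state_dict().items()), sorted(model2.state_dict().items())
        ):
            assert k1 == k2 and np.array_equal(v1, v2)
        assert st2.iteration == st.iteration
        assert st2.optimizer_state is not None

    def test_resume_matches_uninterrupted(self, tmp_path, small_data):
        # uninterrupted: 2 epochs of stage 2
        m_full = build_model(tiny_cfg())
        run_stage(m_full, small_data, stage(2, 2), AUG, seed=3)
        # interrupted after epoch 1, checkpointed, resumed for epoch 2
        m_half = build_model(tiny_cfg())
        st = run_stage(m_half, small_data, stage(2, 1), AUG, seed=3)
        path = tmp_path / "mid.npz"
        save_checkpoint(m_half, path, st)
        m_resumed, st2 = load_checkpoint(path)
        st2.epoch = 1
        run_stage(m_resumed, small_data, stage(2, 2), AUG, seed=3, state=st2)
        for (k, v1), (_, v2) in zip(
            sorted(m_full.state_dict().items()), sorted(m_resumed.state_dict().items())
        ):
            assert np.allclose(v1, v2, atol=0), k


class TestTrainFull:
    def test_smoke_writes_loadable_checkpoint(self, tmp_path, small_data):
        ck = train_full(
            tiny_cfg(),
            small_data,
            stages=(stage(1, 1), stage(2, 1)),
            seed=0,
            out_dir=tmp_path / "run",
            augment=AUG,
        )
        assert ck.exists()
        model, st = load_checkpoint(ck)
        assert model.config.mode == "training"
        assert (tmp_path / "run" / "manifest.json").exists()
        assert (tmp_path / "run" / "train_log.jsonl").exists()
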