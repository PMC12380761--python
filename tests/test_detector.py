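"""Structural contracts of the assembled detector and its audits."""

import numpy as np
import pytest

from vegdet import nn
from vegdet.audit import (VARIANTS, brute_force_param_count, count_flops,
                          count_parameters_exact)
from vegdet.blocks import zero_init_gate, AAFS
from vegdet.model import (Detector, IDFLayer, ModelConfig, build_model,
                          decode_level)
from vegdet.nn import tensor as T


def probe(model, size):
    return model(T.ShapeProbe((1, 3, size, size)))


class TestBackbone:
    def test_pyramid_resolutions_at_640(self):
        m = build_model(ModelConfig())
        bb = m.backbone(T.ShapeProbe((1, 3, 640, 640)))
        assert bb["P2"].shape[2:] == (160, 160)
        assert bb["P3"].shape[2:] == (80, 80)
        assert bb["P4"].shape[2:] == (40, 40)
        assert bb["P5"].shape[2:] == (20, 20)

    def test_adeconv_backbone_has_no_strided_conv(self):
        m = build_model(ModelConfig(use_adeconv=True))
        strides = [c.stride for c in m.backbone.modules()
                   if isinstance(c, nn.Conv2d)]
        assert all(s == 1 for s in strides)

    def test_baseline_backbone_uses_stride2(self):
        m = build_model(ModelConfig())
        strides = [c.stride for c in m.backbone.modules()
                   if isinstance(c, nn.Conv2d)]
        assert 2 in strides

    def test_input_size_must_divide_32(self):
        with pytest.raises(ValueError, match="divisible by 32"):
            ModelConfig(input_size=100)


class TestNeck:
    def test_idfnet_repeat_count(self):
        m = build_model(ModelConfig(use_idfnet=True))
        layers = [x for x in m.neck.modules() if isinstance(x, IDFLayer)]
        assert len(layers) == 3

    def test_neck_preserves_level_resolutions(self):
        for idf in (False, True):
            m = build_model(ModelConfig(use_idfnet=idf))
            bb = m.backbone(T.ShapeProbe((1, 3, 320, 320)))
            neck = m.neck(bb)
            for lvl, s in (("P3", 40), ("P4", 20), ("P5", 10)):
                assert neck[lvl].shape[2:] == (s, s)

    def test_zero_init_gates_halve_node_sum(self, rng):
        # a fusion node with a zeroed gate multiplies its summed input by 0.5
        from vegdet.model import FusionNode
        node = FusionNode(8, gate_groups=2)
        zero_init_gate(node.aafs)
        node.eval()
        a = T.Tensor(rng.normal(size=(1, 8, 4, 4)).astype(np.float32))
        b = T.Tensor(rng.normal(size=(1, 8, 4, 4)).astype(np.float32))
        gated = node.aafs(T.add(a, b))
        np.testing.assert_allclose(gated.data, (a.data + b.data) / 2,
                                   rtol=1e-5)


class TestMFRoute:
    def test_three_upsamplings_reach_p2_resolution(self):
        m = build_model(ModelConfig(use_mflayer=True))
        out = probe(m, 640)
        # 4 head levels at strides 4/8/16/32
        assert len(out["one2many"]) == 4
        assert out["strides"] == [4, 8, 16, 32]
        cls0, _ = out["one2many"][0]
        assert cls0.shape[2:] == (160, 160)

    def test_head_count_without_mflayer(self):
        m = build_model(ModelConfig())
        out = probe(m, 640)
        assert len(out["one2many"]) == 3
        assert out["strides"] == [8, 16, 32]

    def test_fused_width_matches_config(self):
        cfg = ModelConfig(use_mflayer=True)
        m = build_model(cfg)
        bb = m.backbone(T.ShapeProbe((1, 3, 640, 640)))
        neck = m.neck(bb)
        fused = m.mf(neck["P5"], bb["P2"])
        assert fused.shape[1] == cfg.profile.mf_width


class TestFullModel:
    def test_all_eight_variants_build_and_run(self):
        for _, a, mf, i in VARIANTS:
            m = build_model(ModelConfig(use_adeconv=a, use_mflayer=mf,
                                        use_idfnet=i))
            out = probe(m, 640)
            assert len(out["one2many"]) == (4 if mf else 3)

    def test_forward_determinism(self, rng):
        m = build_model(ModelConfig(num_classes=3, input_size=64,
                                    width_scale=0.125))
        m.eval()
        x = rng.random((1, 3, 64, 64)).astype(np.float32)
        o1 = m(T.Tensor(x))["one2many"][0][0].data
        o2 = m(T.Tensor(x))["one2many"][0][0].data
        assert np.array_equal(o1, o2)

    def test_one_step_reduces_toy_loss(self, rng):
        nn.seed(3)
        m = build_model(ModelConfig(num_classes=3, input_size=64,
                                    width_scale=0.125, use_adeconv=True,
                                    use_mflayer=True, use_idfnet=True))
        x = rng.random((2, 3, 64, 64)).astype(np.float32)

        def loss_value():
            out = m(T.Tensor(x))
            parts = [T.tmean(T.mul(c, c)) + T.tmean(T.mul(r, r))
                     for c, r in out["one2many"]]
            total = parts[0]
            for p in parts[1:]:
                total = total + p
            return total

        opt = nn.SGD(m.parameters(), lr=0.05, momentum=0.9)
        l0 = loss_value()
        m.zero_grad()
        l0.backward()
        opt.step()
        l1 = loss_value()
        assert float(l1.data) < float(l0.data)


class TestAudits:
    def test_param_counter_equals_brute_force(self):
        for kw in ({}, dict(use_adeconv=True, use_mflayer=True,
                            use_idfnet=True)):
            m = build_model(ModelConfig(**kw))
            assert count_parameters_exact(m) == brute_force_param_count(m)

    def test_single_conv_param_closed_form(self):
        conv = nn.Conv2d(8, 16, kernel=1, bias=False)
        assert conv.weight.size == 128

    def test_single_conv_flops_closed_form(self):
        conv = nn.ConvBNAct(16, 16, kernel=3)
        with T.profile() as p:
            conv(T.ShapeProbe((1, 16, 32, 32)))
        assert p.flops == 2 * (3 * 3 * 16) * 16 * 32 * 32

    def test_flops_quadratic_in_resolution(self):
        m = build_model(ModelConfig(use_adeconv=True, use_mflayer=True,
                                    use_idfnet=True))
        f320 = count_flops(m, 320)
        f640 = count_flops(m, 640)
        assert f640 / f320 == pytest.approx(4.0, rel=0.005)

    def test_structural_monotonicity(self):
        base = build_model(ModelConfig())
        ade = build_model(ModelConfig(use_adeconv=True))
        mf = build_model(ModelConfig(use_mflayer=True))
        assert count_parameters_exact(ade) > count_parameters_exact(base)
        assert count_flops(mf) > count_flops(base)


class TestDecode:
    def test_boxes_clipped_to_unit_square(self, rng):
        cls = rng.normal(size=(1, 3, 4, 4)).astype(np.float32)
        reg = rng.normal(size=(1, 64, 4, 4)).astype(np.float32) * 5
        boxes, prob = decode_level(cls, reg, stride=16, input_size=64)
        x1 = boxes[..., 0] - boxes[..., 2] / 2
        x2 = boxes[..., 0] + boxes[..., 2] / 2
        assert np.all(x1 >= -1e-6) and np.all(x2 <= 1 + 1e-6)
        assert np.all(boxes[..., 2:] > 0)
        assert np.all((prob >= 0) & (prob <= 1))
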