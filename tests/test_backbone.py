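import numpy as np
import pytest

import cellforge as cf
from cellforge.backbone import (BackboneConfig, LabelVocabulary,
                                VocabularyError, init_backbone)


class TestVocabulary:
    def test_joint_vocabulary_and_null_index(self):
        v = LabelVocabulary.from_labels(np.array(["b_T", "a_B", "b_T"]))
        assert v.classes == ["a_B", "b_T"]
        assert v.n_classes == 3 and v.null_index == 2
        assert v.encode(["b_T", "a_B"]).tolist() == [1, 0]

    def test_unknown_label_raises(self):
        v = LabelVocabulary(["x"])
        with pytest.raises(VocabularyError):
            v.encode(["y"])


class TestInit:
    def test_seeded_init_deterministic(self):
        cfg = BackboneConfig(latent_dim=4, n_classes=3, seed=2,
                             chunk_widths=[8, 8, 8])
        a, b = init_backbone(cfg), init_backbone(cfg)
        np.testing.assert_array_equal(a.mid.l1.W, b.mid.l1.W)
        np.testing.assert_array_equal(a.embed.E, b.embed.E)

    def test_depth_two_has_seven_modules(self, tiny_backbone):
        p = tiny_backbone
        named = [*p.downs, p.mid, *p.ups, p.fc1, p.fc2]
        assert len(named) == 7
        assert p.cfg.n_chunks == 5          # conditioned chunks D1,D2,mid,U1,U2

    @pytest.mark.parametrize("d", [1, 2, 3])
    def test_conditioned_chunk_count_is_odd(self, d):
        cfg = BackboneConfig(latent_dim=4, n_classes=3, depth=d,
                             chunk_widths=[8] * (d + 1))
        assert cfg.n_chunks == 2 * d + 1
        assert cfg.n_chunks % 2 == 1


class TestConditionInject:
    def test_identity_when_label_one_time_zero(self, tiny_backbone):
        p = tiny_backbone
        cond = p.conds[0]
        cond.label_proj.W[...] = 0.0
        cond.label_proj.b[...] = 1.0
        cond.time_proj.W[...] = 0.0
        cond.time_proj.b[...] = 0.0
        x = np.random.default_rng(0).standard_normal((3, 4))
        out = cf.condition_inject(x, 0, 5, p, 0)
        np.testing.assert_allclose(out, x)

    def test_hand_worked_width_two_example(self):
        cfg = BackboneConfig(latent_dim=2, n_classes=2, depth=1,
                             chunk_widths=[2, 2], embed_dim=2, time_dim=2)
        p = init_backbone(cfg)
        cond = p.conds[0]
        # force the projections: label -> [1, -1], time -> [0.5, 0.5]
        p.embed.E[...] = np.array([[1.0, 0.0], [0.0, 1.0]])
        cond.label_proj.W[...] = np.array([[1.0, -1.0], [0.0, 0.0]])
        cond.label_proj.b[...] = 0.0
        cond.time_proj.W[...] = 0.0
        cond.time_proj.b[...] = 0.5
        out = cf.condition_inject(np.array([[2.0, 3.0]]), 0, 0, p, 0)
        np.testing.assert_allclose(out, [[2.5, -2.5]])

    def test_distinct_labels_give_distinct_outputs(self, tiny_backbone):
        x = np.ones((1, 4))
        a = cf.condition_inject(x, 0, 3, tiny_backbone, 0)
        b = cf.condition_inject(x, 1, 3, tiny_backbone, 0)
        assert not np.allclose(a, b)

    def test_out_of_vocabulary_label(self, tiny_backbone):
        with pytest.raises(IndexError):
            cf.condition_inject(np.ones((1, 4)), 99, 0, tiny_backbone, 0)


class TestForwardFull:
    def test_output_shape_matches_latent(self, tiny_backbone):
        x = np.random.default_rng(0).standard_normal((5, 4))
        eps, feat = tiny_backbone.forward_full(x, 3, 1, cache_depth=2)
        assert eps.shape == (5, 4)
        assert feat.depth_b == 2 and feat.produced_at_t == 3

    def test_permutation_equivariance(self, tiny_backbone):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((6, 4))
        y = np.array([0, 1, 2, 0, 1, 2])
        perm = rng.permutation(6)
        full, _ = tiny_backbone.forward_full(x, 2, y)
        permuted, _ = tiny_backbone.forward_full(x[perm], 2, y[perm])
        np.testing.assert_allclose(full[perm], permuted, atol=1e-12)

    def test_identity_chunks_match_straight_line_trace(self):
        """With identity chunk MLPs and neutral conditioning, the stack of
        additive skips composes to 3x, checked against an independent
        straight-line computation."""
        cfg = BackboneConfig(latent_dim=4, n_classes=2, depth=2,
                             chunk_widths=[4, 4, 4], embed_dim=4, time_dim=4)
        p = init_backbone(cfg)
        eye = np.eye(4)
        for chunk in [*p.downs, p.mid, *p.ups]:
            chunk.l1.W[...] = eye
            chunk.l1.b[...] = 0.0
            chunk.l2.W[...] = eye
            chunk.l2.b[...] = 0.0
        p.fc1.W[...] = eye
        p.fc1.b[...] = 0.0
        p.fc2.W[...] = eye
        p.fc2.b[...] = 0.0
        for cond in p.conds:
            cond.label_proj.W[...] = 0.0
            cond.label_proj.b[...] = 1.0
            cond.time_proj.W[...] = 0.0
            cond.time_proj.b[...] = 0.0
        x = np.abs(np.random.default_rng(0).standard_normal((3, 4)))
        # independent trace: d1=x, d2=d1, mid=d2, u1=mid+d2=2x, u2=u1+d1=3x
        d1 = x.copy()
        d2 = d1.copy()
        mid = d2.copy()
        u1 = mid + d2
        u2 = u1 + d1
        eps, _ = p.forward_full(x, 0, 0)
        np.testing.assert_allclose(eps, u2, atol=1e-12)

    def test_width_mismatch_raises(self, tiny_backbone):
        with pytest.raises(ValueError):
            tiny_backbone.forward_full(np.zeros((2, 7)), 0, 0)


class TestForwardCached:
    def test_consistency_with_full_pass(self, tiny_backbone):
        """A feature exported at step t reproduces the full pass exactly."""
        rng = np.random.default_rng(2)
        x = rng.standard_normal((4, 4))
        for b in (1, 2):
            eps_full, feat = tiny_backbone.forward_full(x, 7, 2, cache_depth=b)
            eps_cached = tiny_backbone.forward_cached(x, 7, 2, feat)
            np.testing.assert_allclose(eps_cached, eps_full, atol=1e-12)

    def test_cached_pass_touches_only_shallow_modules(self, tiny_backbone):
        p = tiny_backbone
        x = np.random.default_rng(0).standard_normal((2, 4))
        _, feat = p.forward_full(x, 5, 1, cache_depth=2)
        calls = []
        originals = {}
        modules = {"D1": p.downs[0], "D2": p.downs[1], "mid": p.mid,
                   "U1": p.ups[0], "U2": p.ups[1], "FC1": p.fc1,
                   "FC2": p.fc2}
        for name, mod in modules.items():
            originals[name] = mod.forward
            mod.forward = (lambda v, _n=name, _f=mod.forward:
                           calls.append(_n) or _f(v))
        try:
            p.forward_cached(x, 4, 1, feat)
        finally:
            for name, mod in modules.items():
                mod.forward = originals[name]
        assert set(calls) == {"D1", "U2", "FC1", "FC2"}

    def test_cached_deterministic(self, tiny_backbone):
        x = np.random.default_rng(3).standard_normal((2, 4))
        _, feat = tiny_backbone.forward_full(x, 9, 0, cache_depth=2)
        a = tiny_backbone.forward_cached(x, 8, 0, feat)
        b = tiny_backbone.forward_cached(x, 8, 0, feat)
        np.testing.assert_array_equal(a, b)

    def test_cached_cheaper_than_full_for_every_depth(self, tiny_backbone):
        d = tiny_backbone.cfg.depth
        full_cost = 2 * d + 1                      # chunks in a full pass
        for b in range(1, d + 1):
            cached_cost = (d + 1 - b) + (d - b + 1)  # downs + ups evaluated
            assert cached_cost < full_cost

    def test_wrong_width_feature_raises(self, tiny_backbone):
        feat = cf.HighLevelFeature(np.zeros((2, 3)), 5, 2)
        with pytest.raises(ValueError):
            tiny_backbone.forward_cached(np.zeros((3, 4)), 4, 0, feat)


class TestGradients:
    def test_backward_matches_numerical_gradient(self, tiny_backbone):
        p = tiny_backbone
        rng = np.random.default_rng(0)
        x = rng.standard_normal((3, 4))
        t = np.array([3, 7, 1])
        y = np.array([0, 2, 1])
        target = rng.standard_normal((3, 4))

        def loss():
            e, _ = p.forward_full(x, t, y)
            return 0.5 * np.sum((e - target) ** 2)

        probes = [p.downs[0].l1.W, p.mid.l2.W, p.ups[1].l1.W, p.fc2.W,
                  p.embed.E, p.conds[3].label_proj.W, p.conds[0].time_proj.W]
        grads = [p.downs[0].l1.gW, p.mid.l2.gW, p.ups[1].l1.gW, p.fc2.gW,
                 p.embed.gE, p.conds[3].label_proj.gW,
                 p.conds[0].time_proj.gW]
        for g in grads:
            g[...] = 0.0
        e, _ = p.forward_full(x, t, y)
        p.backward_full(e - target)
        h = 1e-6
        for arr, g in zip(probes, grads):
            i, j = 1, 2
            old = arr[i, j]
            arr[i, j] = old + h
            lp = loss()
            arr[i, j] = old - h
            lm = loss()
            arr[i, j] = old
            num = (lp - lm) / (2 * h)
            assert abs(num - g[i, j]) <= 1e-4 * (abs(num) + 1e-6)
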