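import numpy as np
import pytest
from dataclasses import replace

from plantseg3d import (ModelConfig, SegmentationModel, ball_query,
                        combined_loss, relative_codes)
from plantseg3d.autodiff import Tensor
from plantseg3d.errors import ConfigError, ValidationError


@pytest.fixture
def coords(rng):
    return rng.uniform(-1, 1, size=(64, 3)) / np.sqrt(3)


class TestConfig:
    def test_requires_three_distinct_radii(self):
        with pytest.raises(ConfigError):
            ModelConfig(radii=(0.1, 0.2))
        with pytest.raises(ConfigError):
            ModelConfig(radii=(0.1, 0.1, 0.2))

    def test_round_trips_through_dict(self, tiny_model_config):
        d = tiny_model_config.to_dict()
        assert ModelConfig.from_dict(d) == tiny_model_config

    def test_upsample_mode_validated(self):
        with pytest.raises(ConfigError):
            ModelConfig(upsample="bogus")


class TestSortNet:
    def test_constant_scores_select_lowest_indices(self, tiny_model, coords):
        for w in self.zeroed(tiny_model.score_mlp):
            pass
        feats = tiny_model.extract_point_features(coords)
        sel, scores, tokens = tiny_model.pc_sortnet_forward(coords, feats)
        order = np.argsort(-scores.data[:, 0], kind="stable")
        assert sel.tolist() == order[:tiny_model.config.k_local].tolist()

    @staticmethod
    def zeroed(mlp):
        for w in mlp.W:
            w.data[:] = 0.0
        for b in mlp.b:
            b.data[:] = 0.0
        return mlp.W

    def test_tie_rule_with_flat_score_map(self, tiny_model, coords):
        self.zeroed(tiny_model.score_mlp)
        feats = tiny_model.extract_point_features(coords)
        sel, _, _ = tiny_model.pc_sortnet_forward(coords, feats)
        k = tiny_model.config.k_local
        assert sel.tolist() == list(range(k))

    def test_selection_matches_full_sort_oracle(self, tiny_model, coords):
        feats = tiny_model.extract_point_features(coords)
        sel, scores, _ = tiny_model.pc_sortnet_forward(coords, feats)
        s = scores.data[:, 0]
        expected = sorted(range(len(s)), key=lambda i: (-s[i], i))
        assert set(sel) == set(expected[:tiny_model.config.k_local])

    def test_k_equals_n_is_a_permutation(self, tiny_model_config, coords):
        cfg = replace(tiny_model_config, k_local=64)
        model = SegmentationModel(cfg, seed=0)
        feats = model.extract_point_features(coords)
        sel, scores, _ = model.pc_sortnet_forward(coords, feats)
        assert sorted(sel) == list(range(64))
        s = scores.data[:, 0]
        assert (np.diff(s[sel]) <= 1e-15).all()     # sorted descending

    def test_k_larger_than_n_rejected(self, tiny_model_config, rng):
        cfg = replace(tiny_model_config, n_points=16, m_fps=8, k_local=8)
        model = SegmentationModel(cfg, seed=0)
        small = rng.normal(size=(4, 3))
        with pytest.raises(ValidationError):
            model.pc_sortnet_forward(small,
                                     model.extract_point_features(small))


class TestMsgBranch:
    def test_token_count_equals_fps_samples(self, tiny_model, coords):
        feats = tiny_model.extract_point_features(coords)
        centers, out = tiny_model.pc_msg_forward(coords, feats)
        assert len(centers) == tiny_model.config.m_fps
        assert out.features.shape == (tiny_model.config.m_fps,
                                      tiny_model.config.d_m)

    def test_tiny_radii_still_finite(self, tiny_model_config, coords):
        cfg = replace(tiny_model_config, radii=(1e-9, 2e-9, 3e-9))
        model = SegmentationModel(cfg, seed=1)
        feats = model.extract_point_features(coords)
        centers, out = model.pc_msg_forward(coords, feats)
        assert np.isfinite(out.features.data).all()
        # every scale sees only the centre → all relative codes are zero
        nbr = ball_query(coords, centers, 1e-9, cfg.k_max)
        assert (relative_codes(coords, nbr) == 0).all()

    def test_scaling_coords_and_radii_preserves_memberships(self, rng,
                                                            tiny_model_config):
        coords = rng.uniform(-1, 1, size=(64, 3))
        for r in tiny_model_config.radii:
            a = ball_query(coords, np.arange(0, 64, 5), r,
                           tiny_model_config.k_max)
            b = ball_query(2.0 * coords, np.arange(0, 64, 5), 2.0 * r,
                           tiny_model_config.k_max)
            np.testing.assert_array_equal(a.neighbor_idx, b.neighbor_idx)
            np.testing.assert_array_equal(a.valid_mask, b.valid_mask)


class TestDetectionHeadAndForward:
    def test_output_shape_and_classes(self, tiny_model, coords):
        res = tiny_model.forward(coords)
        assert res.logits.scores.shape == (64, 3)
        assert np.isfinite(res.logits.scores.data).all()
        assert len(res.head_features) == 3      # self, local-global, cross

    def test_forward_is_bitwise_deterministic(self, tiny_model, coords):
        a = tiny_model.forward(coords)
        b = tiny_model.forward(coords)
        np.testing.assert_array_equal(a.logits.scores.data,
                                      b.logits.scores.data)

    def test_attention_rows_sum_to_one(self, tiny_model, coords):
        res = tiny_model.forward(coords)
        for name, attn in res.aux["attn"].items():
            np.testing.assert_allclose(attn.sum(axis=-1), 1.0, atol=1e-5,
                                       err_msg=name)

    def test_translation_leaves_rpc_activations_unchanged(self, rng,
                                                          tiny_model):
        # dyadic grid so the offsets cancel exactly (see position tests)
        coords = rng.integers(-512, 512, size=(64, 3)) / 1024.0
        shifted = coords + np.array([4.0, -2.5, 1.25])
        nbr = ball_query(coords, np.arange(0, 64, 4),
                         tiny_model.config.radii[1], tiny_model.config.k_max)
        from plantseg3d import encode_positions
        pc = encode_positions(coords, nbr, tiny_model.theta_rpc_g[1],
                              tiny_model.theta_apc_g[1])
        pc_t = encode_positions(shifted, nbr, tiny_model.theta_rpc_g[1],
                                tiny_model.theta_apc_g[1])
        np.testing.assert_array_equal(pc.rpc_features.data,
                                      pc_t.rpc_features.data)

    def test_wrong_point_count_rejected(self, tiny_model, rng):
        with pytest.raises(ValidationError):
            tiny_model.forward(rng.normal(size=(32, 3)))

    def test_gradient_reaches_every_attention_module(self, tiny_model,
                                                     coords, rng):
        labels = rng.integers(0, 3, 64)
        res = tiny_model.forward(coords)
        bd = combined_loss(res.logits, labels, res.head_features,
                           loss_scal=1.0)
        bd.total.backward()
        for mod_name in ("attn_self", "attn_lg", "attn_cross"):
            mod = getattr(tiny_model, mod_name)
            grads = [p.grad for _, p in mod.named_parameters()]
            assert any(g is not None and np.abs(g).max() > 0 for g in grads), \
                mod_name

    def test_state_dict_round_trip(self, tiny_model_config, coords):
        a = SegmentationModel(tiny_model_config, seed=3)
        b = SegmentationModel(tiny_model_config, seed=99)
        b.load_state_dict(a.state_dict())
        np.testing.assert_array_equal(a.forward(coords).logits.scores.data,
                                      b.forward(coords).logits.scores.data)

    def test_ablation_flags_change_architecture(self, tiny_model_config,
                                                coords):
        no_rpc = SegmentationModel(replace(tiny_model_config, use_rpc=False),
                                   seed=0)
        res = no_rpc.forward(coords)
        assert res.logits.scores.shape == (64, 3)
        baseline = SegmentationModel(
            replace(tiny_model_config, use_rpc=False, use_apc=False), seed=0)
        assert baseline.forward(coords).logits.scores.shape == (64, 3)
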