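import numpy as np
import pytest

from greensentry.model import (
    DiseaseWarningModel,
    desk_config,
    env_guided_attention,
    paper_config,
    spatial_attention,
    temporal_attention,
)
from greensentry.model import attention as attn_mod
from greensentry.model.config import ModelConfig
from greensentry.model.network import embed_environment, forward, init_params, visual_backbone
from greensentry.nn import functional as F
from greensentry.nn import init as nninit


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@pytest.fixture(scope="module")
def paper_model():
    return DiseaseWarningModel(paper_config(T=2))


@pytest.fixture(scope="module")
def desk_model():
    return DiseaseWarningModel(desk_config(T=3))


class TestModelConfig:
    def test_embed_dim_head_divisibility(self):
        with pytest.raises(ValueError):
            ModelConfig(embed_dim=250, n_heads=8)

    def test_image_size_divisibility(self):
        with pytest.raises(ValueError):
            ModelConfig(image_size=50)

    def test_stage_lists_equal_length(self):
        with pytest.raises(ValueError):
            ModelConfig(stage_channels=(96, 192), stage_downsamples=(8, 16, 32))


class TestBackbone:
    def test_stage_shapes_64(self, paper_model):
        images = np.random.default_rng(0).random((2, 64, 64, 3))
        feats = visual_backbone(paper_model.params, paper_model.config, images)
        assert feats[0].shape == (2, 8, 8, 96)
        assert feats[1].shape == (2, 4, 4, 192)
        assert feats[2].shape == (2, 2, 2, 384)

    def test_stage_shape_contract_other_sizes(self):
        cfg = desk_config(image_size=96)
        model = DiseaseWarningModel(cfg)
        images = np.zeros((1, 96, 96, 3))
        feats = visual_backbone(model.params, cfg, images)
        for f, ds, c in zip(feats, cfg.stage_downsamples, cfg.stage_channels):
            assert f.shape == (1, 96 // ds, 96 // ds, c)

    def test_not_constant_map(self, desk_model):
        rng = np.random.default_rng(1)
        a = visual_backbone(desk_model.params, desk_model.config, rng.random((1, 64, 64, 3)))
        b = visual_backbone(desk_model.params, desk_model.config, rng.random((1, 64, 64, 3)))
        assert not np.allclose(a[0], b[0])

    def test_deterministic(self, desk_model):
        images = np.random.default_rng(2).random((1, 64, 64, 3))
        a = visual_backbone(desk_model.params, desk_model.config, images)
        b = visual_backbone(desk_model.params, desk_model.config, images)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)


class TestEnvGuidedAttention:
    def _params(self, rng, C=8, E=6):
        return attn_mod.init_env_guided_params(rng, C, E)

    def test_zero_features_zero_output(self, rng):
        p = self._params(rng)
        out = env_guided_attention(p, np.zeros((2, 4, 4, 8)), rng.normal(size=(2, 6)))
        assert np.allclose(out["output"], 0.0)
        assert np.allclose(out["modulated"], 0.0)

    def test_zero_env_mapping_gives_half_gate(self, rng):
        p = self._params(rng)
        p["env_fc2"]["W"] = np.zeros_like(p["env_fc2"]["W"])
        p["env_fc2"]["b"] = np.zeros_like(p["env_fc2"]["b"])
        feat = rng.normal(size=(2, 4, 4, 8))
        out = env_guided_attention(p, feat, rng.normal(size=(2, 6)))
        assert np.allclose(out["m_c"], 0.5)
        expected = feat * (out["a_c"] * 0.5)[:, None, None, :]
        assert np.allclose(out["modulated"], expected, atol=1e-9)

    def test_matches_elementwise_loop_oracle(self, rng):
        # triple-loop recomputation of the channel modulation
        p = self._params(rng)
        feat = rng.normal(size=(1, 4, 4, 8))
        s = rng.normal(size=(1, 6))
        out = env_guided_attention(p, feat, s)
        f_avg = feat[0].mean(axis=(0, 1))
        f_max = feat[0].max(axis=(0, 1))
        a_c = _sigmoid(np.concatenate([f_avg, f_max]) @ p["channel"]["W"]
                       + p["channel"]["b"])
        h = np.maximum(s[0] @ p["env_fc1"]["W"] + p["env_fc1"]["b"], 0)
        m_c = _sigmoid(h @ p["env_fc2"]["W"] + p["env_fc2"]["b"])
        expected = np.empty_like(feat[0])
        for x in range(4):
            for y in range(4):
                for c in range(8):
                    expected[x, y, c] = feat[0, x, y, c] * a_c[c] * m_c[c]
        assert np.allclose(out["modulated"][0], expected, atol=1e-6)

    def test_gating_attenuates(self, rng):
        # |modulated| <= |F| entrywise: product of two sigmoids < 1
        p = self._params(rng)
        feat = rng.normal(size=(3, 4, 4, 8))
        out = env_guided_attention(p, feat, rng.normal(size=(3, 6)))
        assert np.all(np.abs(out["modulated"]) <= np.abs(feat) + 1e-12)

    def test_factors_in_unit_interval(self, rng):
        p = self._params(rng)
        out = env_guided_attention(p, rng.normal(size=(2, 4, 4, 8)),
                                   rng.normal(size=(2, 6)))
        for key in ("a_c", "m_c", "A_s"):
            assert np.all(out[key] > 0) and np.all(out[key] < 1)

    def test_ablation_unit_gate(self, rng):
        p = self._params(rng)
        feat = rng.normal(size=(2, 4, 4, 8))
        out = env_guided_attention(p, feat, rng.normal(size=(2, 6)),
                                   use_env_guidance=False)
        assert np.allclose(out["m_c"], 1.0)

    def test_channel_mismatch_raises(self, rng):
        p = self._params(rng)
        with pytest.raises(ValueError):
            env_guided_attention(p, rng.normal(size=(1, 4, 4, 5)),
                                 rng.normal(size=(1, 6)))


class TestSpatialAttention:
    def test_zero_conv_gives_half_map(self, rng):
        p = attn_mod.init_spatial_params(rng)
        p["conv"]["W"] = np.zeros_like(p["conv"]["W"])
        feat = rng.normal(size=(2, 6, 6, 8))
        s_t, a_t = spatial_attention(p, feat)
        assert np.allclose(a_t, 0.5)
        assert np.allclose(s_t, 0.5 * feat)

    def test_map_strictly_in_unit_interval(self, rng):
        p = attn_mod.init_spatial_params(rng)
        _, a_t = spatial_attention(p, rng.normal(size=(2, 6, 6, 8)))
        assert np.all(a_t > 0) and np.all(a_t < 1)

    def test_matches_loop_oracle(self, rng):
        # direct loop: channel pools -> 3x3 conv -> sigmoid -> reweight
        p = attn_mod.init_spatial_params(rng)
        feat = rng.normal(size=(1, 6, 6, 8))
        s_t, a_t = spatial_attention(p, feat)
        f = feat[0]
        desc = np.stack([f.mean(axis=-1), f.max(axis=-1)], axis=-1)  # (6,6,2)
        padded = np.zeros((8, 8, 2))
        padded[1:7, 1:7] = desc
        W, b = p["conv"]["W"], p["conv"]["b"]
        expected_map = np.empty((6, 6))
        for x in range(6):
            for y in range(6):
                acc = b[0]
                for di in range(3):
                    for dj in range(3):
                        for ch in range(2):
                            acc += padded[x + di, y + dj, ch] * W[di, dj, ch, 0]
                expected_map[x, y] = _sigmoid(acc)
        assert np.allclose(a_t[0], expected_map, atol=1e-6)
        expected = f * expected_map[:, :, None]
        assert np.allclose(s_t[0], expected, atol=1e-6)


def _identity_proj(p, d):
    p["proj"]["W"] = np.eye(d)
    p["proj"]["b"] = np.zeros(d)
    return p


class TestTemporalAttention:
    def test_T1_singleton_softmax(self, rng):
        # single step: attention weight 1, core output = V_1 (identity proj)
        d = 8
        p = _identity_proj(nninit.attention_params(rng, d), d)
        z = rng.normal(size=(1, 1, d))
        out, attn = F.multi_head_attention(p, z, n_heads=1)
        v = z[0] @ p["v"]["W"] + p["v"]["b"]
        assert np.allclose(attn, 1.0)
        assert np.allclose(out[0], v, atol=1e-9)

    def test_identical_steps_uniform_weights(self, rng):
        d, T = 8, 5
        p = nninit.attention_params(rng, d)
        z = np.tile(rng.normal(size=(1, 1, d)), (1, T, 1))
        _, attn = F.multi_head_attention(p, z, n_heads=1)
        assert np.allclose(attn, 1.0 / T, atol=1e-9)

    def test_core_matches_loop_oracle(self, rng):
        # explicit softmax-weighted sum, single head
        d, T = 8, 4
        p = _identity_proj(nninit.attention_params(rng, d), d)
        z = rng.normal(size=(1, T, d))
        out, _ = F.multi_head_attention(p, z, n_heads=1)
        q = z[0] @ p["q"]["W"] + p["q"]["b"]
        k = z[0] @ p["k"]["W"] + p["k"]["b"]
        v = z[0] @ p["v"]["W"] + p["v"]["b"]
        expected = np.empty((T, d))
        for t in range(T):
            scores = np.array([q[t] @ k[tau] / np.sqrt(d) for tau in range(T)])
            w = np.exp(scores - scores.max())
            w = w / w.sum()
            expected[t] = sum(w[tau] * v[tau] for tau in range(T))
        assert np.allclose(out[0], expected, atol=1e-6)

    def test_attention_rows_sum_to_one(self, rng):
        d = 16
        p = nninit.attention_params(rng, d)
        z = rng.normal(size=(2, 6, d))
        _, attn = F.multi_head_attention(p, z, n_heads=4)
        assert np.allclose(attn.sum(axis=-1), 1.0, atol=1e-6)

    def test_bidirectional_output_shape(self, rng):
        d = 16
        p = attn_mod.init_temporal_params(rng, d, n_blocks=2, ffn_mult=4)
        z = rng.normal(size=(2, 5, d))
        h, attn = temporal_attention(p, z, n_heads=4)
        assert h.shape == (2, 5, d)
        assert attn.shape == (2, 4, 5, 5)

    def test_empty_sequence_raises(self, rng):
        d = 8
        p = attn_mod.init_temporal_params(rng, d, n_blocks=1, ffn_mult=2)
        with pytest.raises(ValueError):
            temporal_attention(p, np.zeros((1, 0, d)), n_heads=1)


class TestEnvironmentEmbedding:
    def test_zero_input_zero_base_embedding(self, desk_model):
        p = {k: dict(v) for k, v in desk_model.params.items()
             if k in ("env_embed",)}
        p["env_embed"] = dict(desk_model.params["env_embed"])
        p["env_embed"]["b"] = np.zeros_like(p["env_embed"]["b"])
        p["env_hierarchy"] = desk_model.params["env_hierarchy"]
        s, _ = embed_environment(p, np.zeros((2, 4)), desk_model.config)
        assert np.allclose(s, 0.0)

    def test_hierarchy_depth_matches_stages(self, desk_model):
        _, hier = embed_environment(desk_model.params, np.zeros((1, 4)),
                                    desk_model.config)
        assert len(hier) == desk_model.config.n_stages

    def test_env_mapping_dimension_matches_stage_channels(self, desk_model):
        cfg = desk_model.config
        for l, c in enumerate(cfg.stage_channels):
            assert desk_model.params["guided"][l]["env_fc2"]["W"].shape == (cfg.env_hidden, c)


class TestForward:
    def test_probs_sum_to_one(self, desk_model, rng):
        cfg = desk_model.config
        out = desk_model.forward(rng.random((2, cfg.T, 64, 64, 3)),
                                 rng.normal(size=(2, cfg.T, 4)))
        assert np.allclose(out.stage_probs.sum(axis=1), 1.0, atol=1e-6)
        for aux in out.aux_outputs.values():
            assert np.allclose(aux.sum(axis=1), 1.0, atol=1e-6)

    def test_alignment_embeddings_same_dim(self, desk_model, rng):
        cfg = desk_model.config
        out = desk_model.forward(rng.random((1, cfg.T, 64, 64, 3)),
                                 rng.normal(size=(1, cfg.T, 4)))
        assert out.z_env.shape == out.z_vis.shape == (1, cfg.align_dim)

    def test_eval_determinism(self, desk_model, rng):
        cfg = desk_model.config
        images = rng.random((1, cfg.T, 64, 64, 3))
        envs = rng.normal(size=(1, cfg.T, 4))
        a = desk_model.forward(images, envs)
        b = desk_model.forward(images, envs)
        assert np.array_equal(a.stage_probs, b.stage_probs)

    def test_env_sensitivity_guidance_live(self, desk_model, rng):
        # the guidance path must be live: changing env changes the prediction
        cfg = desk_model.config
        images = rng.random((1, cfg.T, 64, 64, 3))
        e1 = rng.normal(size=(1, cfg.T, 4))
        out1 = desk_model.forward(images, e1)
        out2 = desk_model.forward(images, e1 + 1.0)
        assert not np.allclose(out1.stage_probs, out2.stage_probs)

    def test_ablation_env_insensitive(self, desk_model, rng):
        cfg = desk_model.config
        images = rng.random((1, cfg.T, 64, 64, 3))
        e1 = rng.normal(size=(1, cfg.T, 4))
        a = desk_model.forward(images, e1, use_env_guidance=False)
        b = desk_model.forward(images, e1 + 5.0, use_env_guidance=False)
        assert np.allclose(a.stage_probs, b.stage_probs, atol=1e-12)

    def test_spatial_head_shape_and_range(self, rng):
        cfg = desk_config(T=2, use_spatial_head=True)
        model = DiseaseWarningModel(cfg)
        out = model.forward(rng.random((1, 2, 64, 64, 3)), rng.normal(size=(1, 2, 4)))
        assert out.spatial_map.shape == (1, 8, 8)
        assert np.all(out.spatial_map > 0) and np.all(out.spatial_map < 1)


class TestCheckpoint:
    def test_save_load_roundtrip(self, desk_model, rng, tmp_path):
        cfg = desk_model.config
        path = str(tmp_path / "ckpt.npz")
        desk_model.save(path, extra={"note": "test"})
        loaded = DiseaseWarningModel.load(path)
        images = rng.random((1, cfg.T, 64, 64, 3))
        envs = rng.normal(size=(1, cfg.T, 4))
        a = desk_model.forward(images, envs)
        b = loaded.forward(images, envs)
        assert np.allclose(a.stage_probs, b.stage_probs, atol=1e-12)
        assert loaded.checkpoint_extra["note"] == "test"
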