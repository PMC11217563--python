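"""Architecture assembly, presets, parameter counting, checkpoints."""

import dataclasses

import numpy as np
import pytest

from rvit import models
from rvit.nn import Linear


def random_images(rng, n, cfg):
    return rng.random((n, cfg.image_size, cfg.image_size, cfg.in_channels),
                      dtype=np.float32)


class TestPresets:
    def test_rvit_preset_hyperparameters(self):
        cfg = models.PRESETS["rvit"]
        assert (cfg.image_size, cfg.patch_size) == (224, 16)
        assert (cfg.embed_dim, cfg.depth, cfg.heads, cfg.mlp_size) == \
            (142, 10, 10, 480)
        assert cfg.attention_dropout == 0.1
        assert cfg.rotations == 4 and cfg.use_rotated_embedding
        assert cfg.use_depthwise_stem

    def test_base_vit_preset_hyperparameters(self):
        cfg = models.PRESETS["base_vit"]
        assert (cfg.embed_dim, cfg.depth, cfg.heads, cfg.mlp_size) == \
            (768, 12, 12, 1024)
        assert not cfg.use_rotated_embedding and not cfg.use_depthwise_stem

    def test_variants_toggle_one_component_each(self):
        v1 = models.PRESETS["rvit_variant1"]
        v2 = models.PRESETS["rvit_variant2"]
        assert not v1.use_rotated_embedding and v1.use_depthwise_stem
        assert v2.use_rotated_embedding and not v2.use_depthwise_stem

    def test_base_vit_grid_has_196_tokens(self):
        assert models.PRESETS["base_vit"].num_patches == 196

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="unknown preset"):
            models.build_model("vit_base")


class TestConfigValidation:
    def test_indivisible_image_size_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            models.ModelConfig(image_size=100, patch_size=16)

    def test_bad_rotation_count_rejected(self):
        with pytest.raises(ValueError, match="rotations"):
            models.ModelConfig(rotations=3)

    def test_config_round_trips_through_dict(self, tiny_config):
        assert models.ModelConfig.from_dict(tiny_config.to_dict()) == tiny_config


class TestForward:
    def test_logit_shape_and_finiteness(self, tiny_model, rng):
        x = random_images(rng, 3, tiny_model.config)
        logits = tiny_model.forward(x)
        assert logits.shape == (3, 2)
        assert np.all(np.isfinite(logits))

    def test_wrong_input_shape_rejected(self, tiny_model, rng):
        with pytest.raises(ValueError, match="expected input"):
            tiny_model.forward(rng.random((2, 8, 8, 1)))

    def test_k1_forced_rvit_equals_variant1_bit_exactly(self, tiny_config, rng):
        cfg_k1 = dataclasses.replace(tiny_config, rotations=1)
        cfg_v1 = dataclasses.replace(tiny_config, use_rotated_embedding=False)
        m_k1 = models.build_model(cfg_k1, seed=5)
        m_v1 = models.build_model(cfg_v1, seed=5)
        x = random_images(rng, 10, cfg_k1)
        assert np.array_equal(m_k1.forward(x), m_v1.forward(x))

    def test_predict_proba_rows_sum_to_one(self, tiny_model, rng):
        x = random_images(rng, 4, tiny_model.config)
        probs = tiny_model.predict_proba(x)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)


class TestRotationInvariance:
    @pytest.mark.parametrize("variant_kwargs", [
        {},                                     # rotation averaging + stem
        {"use_depthwise_stem": False},          # averaging only
    ])
    def test_averaged_variants_are_invariant(self, tiny_config, rng,
                                             variant_kwargs):
        cfg = dataclasses.replace(tiny_config, **variant_kwargs)
        model = models.build_model(cfg, seed=2)
        x = random_images(rng, 5, cfg)
        base = model.forward(x)
        for turns in (1, 2, 3):
            rot = np.ascontiguousarray(np.rot90(x, turns, axes=(1, 2)))
            assert np.max(np.abs(model.forward(rot) - base)) <= 1e-4

    @pytest.mark.parametrize("variant_kwargs", [
        {"use_rotated_embedding": False},       # variant1-style
        {"use_rotated_embedding": False, "use_depthwise_stem": False},
    ])
    def test_unaveraged_variants_are_not_invariant(self, tiny_config, rng,
                                                   variant_kwargs):
        cfg = dataclasses.replace(tiny_config, **variant_kwargs)
        model = models.build_model(cfg, seed=2)
        x = random_images(rng, 5, cfg)
        base = model.forward(x)
        rot = np.ascontiguousarray(np.rot90(x, 1, axes=(1, 2)))
        assert np.max(np.abs(model.forward(rot) - base)) > 1e-3


class TestParameterCounts:
    def test_rotation_averaging_adds_no_parameters(self, tiny_config):
        cfg_v1 = dataclasses.replace(tiny_config, use_rotated_embedding=False)
        n_rvit = models.count_parameters(models.build_model(tiny_config, 0))
        n_v1 = models.count_parameters(models.build_model(cfg_v1, 0))
        assert n_rvit == n_v1

    def test_doubling_k_never_changes_count(self, tiny_config):
        counts = set()
        for k in (1, 2, 4):
            cfg = dataclasses.replace(tiny_config, rotations=k)
            counts.add(models.count_parameters(models.build_model(cfg, 0)))
        assert len(counts) == 1

    def test_removing_stem_reduces_count(self, tiny_config):
        cfg_v2 = dataclasses.replace(tiny_config, use_depthwise_stem=False)
        assert models.count_parameters(models.build_model(cfg_v2, 0)) < \
            models.count_parameters(models.build_model(tiny_config, 0))

    def test_random_configs_preserve_count_equality(self, rng):
        for _ in range(5):
            p = int(rng.choice([4, 8]))
            cfg = models.ModelConfig(
                image_size=p * int(rng.integers(2, 5)), patch_size=p,
                in_channels=int(rng.integers(1, 4)),
                embed_dim=int(rng.integers(8, 40)),
                depth=int(rng.integers(1, 4)), heads=int(rng.integers(1, 5)),
                mlp_size=int(rng.integers(8, 64)),
                stem_channels=int(rng.integers(1, 6)), rotations=4)
            cfg_v1 = dataclasses.replace(cfg, use_rotated_embedding=False)
            assert models.count_parameters(models.build_model(cfg, 0)) == \
                models.count_parameters(models.build_model(cfg_v1, 0))

    def test_affine_map_count_closed_form(self):
        layer = Linear(13, 7, np.random.default_rng(0))
        assert layer.count_parameters() == 13 * 7 + 7


class TestCheckpoint:
    def test_round_trip_preserves_config_and_logits(self, tiny_model, rng,
                                                    tmp_path):
        path = tmp_path / "model.npz"
        models.save_checkpoint(tiny_model, path)
        restored = models.load_checkpoint(path)
        assert restored.config == tiny_model.config
        x = random_images(rng, 3, tiny_model.config)
        assert np.array_equal(tiny_model.forward(x), restored.forward(x))

    def test_state_dict_shape_mismatch_rejected(self, tiny_model):
        state = tiny_model.state_dict()
        name = next(iter(state))
        state[name] = np.zeros((1, 1))
        with pytest.raises(ValueError, match="shape mismatch"):
            tiny_model.load_state_dict(state)
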