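"""Model assembly: RViT, the baseline ViT, and the two ablation variants.

Four presets cover the architecture family:

================  ==============  ===================  ==================
preset            hyperparameters  rotation averaging   depth-wise stem
================  ==============  ===================  ==================
``rvit``          small (D=142)    on (k=4)             on
``base_vit``      large (D=768)    off                  off
``rvit_variant1`` small (D=142)    off                  on
``rvit_variant2`` small (D=142)    on (k=4)             off
================  ==============  ===================  ==================

``rvit`` and ``rvit_variant2`` are exactly invariant to quarter rotations
of the input (in eval mode, up to float summation order); the other two are
not. Rotation averaging adds no parameters, so ``rvit`` and
``rvit_variant1`` always have identical parameter counts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

from . import rotations
from .nn import (
    DTYPE,
    Adam,  # noqa: F401  (re-exported for training code)
    DepthwiseStem,
    EncoderBlock,
    LayerNorm,
    Linear,
    Module,
    Parameter,
    softmax,
)

__all__ = ["ModelConfig", "RViT", "build_model", "count_parameters",
           "save_checkpoint", "load_checkpoint", "PRESETS"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters for the RViT family.

    The defaults are the small configuration used by the
    rotation-invariant presets: 224x224 inputs, 16-pixel patches,
    142-dimensional tokens, 10 encoder layers with 10 heads, feed-forward
    width 480, attention dropout 0.1, and averaging over k=4 quarter
    rotations. Since 142 is not divisible by 10, each head gets
    floor(142/10)=14 dimensions and the attention output projection maps
    140 back to 142.
    """

    image_size: int = 224
    patch_size: int = 16
    in_channels: int = 3
    embed_dim: int = 142
    depth: int = 10
    heads: int = 10
    mlp_size: int = 480
    attention_dropout: float = 0.1
    rotations: int = 4
    use_rotated_embedding: bool = True
    use_depthwise_stem: bool = True
    stem_channels: int = 8
    num_classes: int = 2
    # fixed input standardization (applied inside forward; pointwise, so it
    # does not disturb rotation invariance). [0,1] inputs become ~[-2, 2].
    input_mean: float = 0.5
    input_std: float = 0.25

    def __post_init__(self) -> None:
        if self.image_size % self.patch_size != 0:
            raise ValueError(
                f"image size {self.image_size} not divisible by patch "
                f"size {self.patch_size}"
            )
        if self.rotations not in rotations.ALLOWED_ROTATION_COUNTS:
            raise ValueError(
                f"rotations must be one of {rotations.ALLOWED_ROTATION_COUNTS}, "
                f"got {self.rotations}"
            )
        if self.depth < 1 or self.heads < 1:
            raise ValueError("depth and heads must be at least 1")
        if not 0.0 <= self.attention_dropout < 1.0:
            raise ValueError("attention dropout must be in [0, 1)")
        if self.num_classes != 2:
            raise ValueError("this classifier family is binary (2 classes)")

    @property
    def effective_rotations(self) -> int:
        return self.rotations if self.use_rotated_embedding else 1

    @property
    def grid(self) -> int:
        return self.image_size // self.patch_size

    @property
    def num_patches(self) -> int:
        return self.grid * self.grid

    @property
    def patch_channels(self) -> int:
        return self.stem_channels if self.use_depthwise_stem else self.in_channels

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


#: preset name -> config. Small presets share one hyperparameter block and
#: differ only in which of the two ablated components is enabled.
_SMALL = dict(image_size=224, patch_size=16, embed_dim=142, depth=10, heads=10,
              mlp_size=480, attention_dropout=0.1, rotations=4)
PRESETS: dict[str, ModelConfig] = {
    "rvit": ModelConfig(**_SMALL, use_rotated_embedding=True,
                        use_depthwise_stem=True),
    "base_vit": ModelConfig(image_size=224, patch_size=16, embed_dim=768,
                            depth=12, heads=12, mlp_size=1024,
                            attention_dropout=0.1, rotations=1,
                            use_rotated_embedding=False,
                            use_depthwise_stem=False),
    "rvit_variant1": ModelConfig(**_SMALL, use_rotated_embedding=False,
                                 use_depthwise_stem=True),
    "rvit_variant2": ModelConfig(**_SMALL, use_rotated_embedding=True,
                                 use_depthwise_stem=False),
}


def small_study_config(**overrides) -> ModelConfig:
    """The scaled-down architecture used for desk-scale training studies.

    64x64 single-channel inputs, 8-pixel patches, 64-dim tokens, 4 layers
    with 4 heads and feed-forward width 256; rotation averaging and the
    depth-wise stem are on unless overridden.
    """
    base = dict(image_size=64, patch_size=8, in_channels=1, embed_dim=64,
                depth=4, heads=4, mlp_size=256, attention_dropout=0.1,
                rotations=4)
    base.update(overrides)
    return ModelConfig(**base)


class RViT(Module):
    """Rotation-averaged Vision Transformer classifier.

    Forward pass: [optional depth-wise stem applied to each rotated copy]
    -> patch extraction -> shared linear projection -> elementwise average
    over the k rotation branches -> class token + position embeddings ->
    L pre-norm encoder blocks -> final layer norm -> linear head on the
    class token -> 2 logits.
    """

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        c = config
        self.stem = (
            DepthwiseStem(c.in_channels, c.stem_channels, rng)
            if c.use_depthwise_stem else None
        )
        patch_dim = c.patch_size * c.patch_size * c.patch_channels
        self.projector = Linear(patch_dim, c.embed_dim, rng)
        self.cls_token = Parameter(rng.normal(0.0, 0.02, size=(c.embed_dim,)))
        self.pos_embed = Parameter(
            rng.normal(0.0, 0.02, size=(c.num_patches + 1, c.embed_dim))
        )
        self.blocks = [
            EncoderBlock(c.embed_dim, c.heads, c.mlp_size, rng,
                         attn_dropout=c.attention_dropout)
            for _ in range(c.depth)
        ]
        self.norm = LayerNorm(c.embed_dim)
        self.head = Linear(c.embed_dim, c.num_classes, rng)
        # populated by forward(); used by backward() and Grad-CAM
        self._cache: dict | None = None
        self.last_encoder_tokens: np.ndarray | None = None
        self.last_encoder_grad: np.ndarray | None = None

    # -- forward -----------------------------------------------------------

    def forward(self, images: np.ndarray, training: bool = False) -> np.ndarray:
        """Images (B, H, W, C) in [0, 1] -> logits (B, num_classes)."""
        self.clear_caches()  # a new forward invalidates any previous one
        images = np.asarray(images, dtype=DTYPE)
        if images.ndim == 3:
            images = images[None]
        b, h, w, c = images.shape
        cfg = self.config
        if (h, w, c) != (cfg.image_size, cfg.image_size, cfg.in_channels):
            raise ValueError(
                f"expected input ({cfg.image_size}, {cfg.image_size}, "
                f"{cfg.in_channels}), got ({h}, {w}, {c})"
            )
        images = (images - cfg.input_mean) / cfg.input_std
        k = cfg.effective_rotations
        step = 4 // k
        z_sum = None
        for j in range(k):
            xj = images if j == 0 else np.ascontiguousarray(
                np.rot90(images, j * step, axes=(1, 2)))
            fj = self.stem(xj) if self.stem is not None else xj
            pj = rotations.extract_patches_batch(fj, cfg.patch_size)
            zj = self.projector(pj)
            z_sum = zj if z_sum is None else z_sum + zj
        z = z_sum / k
        tokens = np.concatenate(
            [np.broadcast_to(self.cls_token.value, (b, 1, cfg.embed_dim)), z],
            axis=1,
        ) + self.pos_embed.value
        x = tokens
        for i, blk in enumerate(self.blocks):
            if i == len(self.blocks) - 1:
                # saliency target: the tokens feeding the last block. The
                # logit reads only the class token downstream of the last
                # block (per-token norm + head), so gradients w.r.t. the
                # last block's *output* patch tokens vanish identically;
                # at its input they are carried by the final attention.
                self.last_encoder_tokens = x
            x = blk(x, training)
        xn = self.norm(x)
        logits = self.head(xn[:, 0, :])
        self._cache = {"k": k, "step": step, "training": training,
                       "batch": b, "tokens": x.shape[1]}
        return logits

    __call__ = forward

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        return softmax(self.forward(images, training=False), axis=-1)

    # -- backward ----------------------------------------------------------

    def backward(self, dlogits: np.ndarray) -> None:
        """Accumulate parameter gradients from d(loss)/d(logits).

        Must follow a ``forward`` call; gradients of the stem, projector,
        tokens and encoder are all populated. Gradients with respect to the
        input image are not needed for training and are discarded.
        """
        if self._cache is None:
            raise RuntimeError("backward() called before forward()")
        cache = self._cache
        self._cache = None
        b, t = cache["batch"], cache["tokens"]
        d_cls_state = self.head.backward(dlogits)
        dxn = np.zeros((b, t, self.config.embed_dim), dtype=DTYPE)
        dxn[:, 0, :] = d_cls_state
        dx = self.norm.backward(dxn)
        for i, blk in enumerate(reversed(self.blocks)):
            dx = blk.backward(dx)
            if i == 0:  # gradient at the last block's input
                self.last_encoder_grad = dx
        self.pos_embed.grad += dx.sum(axis=0)
        self.cls_token.grad += dx[:, 0, :].sum(axis=0)
        dz = dx[:, 1:, :] / cache["k"]
        cfg = self.config
        for _ in range(cache["k"]):
            dpj = self.projector.backward(dz)
            if self.stem is not None:
                dfj = rotations.scatter_patches_batch(
                    dpj, cfg.image_size, cfg.patch_size, cfg.patch_channels)
                self.stem.backward(dfj)

    # -- state -------------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.value.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise ValueError(f"state dict mismatch: {sorted(missing)[:5]} ...")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=DTYPE)
            if arr.shape != p.value.shape:
                raise ValueError(
                    f"shape mismatch for {name}: {arr.shape} vs {p.value.shape}"
                )
            p.value[...] = arr

    def reseed_dropout(self, seed: int) -> None:
        rng = np.random.default_rng(seed)
        for blk in self.blocks:
            blk.attn.drop.reseed(int(rng.integers(0, 2**31 - 1)))


def build_model(config: ModelConfig | str, seed: int = 0) -> RViT:
    """Build a model from a config or a preset name, seeding initialization."""
    if isinstance(config, str):
        if config not in PRESETS:
            raise ValueError(
                f"unknown preset {config!r}; choose from {sorted(PRESETS)}"
            )
        config = PRESETS[config]
    return RViT(config, np.random.default_rng(seed))


def count_parameters(model: RViT) -> int:
    """Total number of trainable scalars in the model."""
    return model.count_parameters()


def save_checkpoint(model: RViT, path) -> None:
    """Write a self-describing checkpoint (config JSON + all weights)."""
    state = model.state_dict()
    state["__config__"] = np.array(json.dumps(model.config.to_dict()))
    np.savez(path, **state)


def load_checkpoint(path) -> RViT:
    with np.load(path, allow_pickle=False) as data:
        config = ModelConfig.from_dict(json.loads(str(data["__config__"])))
        model = RViT(config, np.random.default_rng(0))
        model.load_state_dict(
            {k: data[k] for k in data.files if k != "__config__"}
        )
    return model
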