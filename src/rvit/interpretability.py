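"""Grad-CAM saliency over the transformer patch grid.

Grad-CAM is adapted to token sequences by treating the embedding
dimensions as channels and the non-class tokens as spatial locations: the
gradient of the target-class logit with respect to the token activations
entering the last encoder layer is global-average-pooled over tokens to
give per-channel weights, the weighted activations are rectified, reshaped
to the patch grid, normalized to [0, 1] and bilinearly upsampled to image
size. (Attribution targets the last layer's *input* tokens: downstream of
the last block only the class token reaches the logit, so gradients with
respect to the block's output patch tokens vanish identically.)

For the rotation-averaged models the class logit itself is invariant to
quarter rotations, so the scalar being explained is the same for all four
orientations of an input; the *map* is by default drawn in the unrotated
frame (each token indexes a grid cell of the unrotated image). The
``branch_average`` mode instead averages the map re-expressed in each
rotation branch's own frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

from .models import RViT

__all__ = ["SaliencyMap", "gradcam", "save_overlay"]


@dataclass(frozen=True)
class SaliencyMap:
    """Patch-grid saliency in [0, 1] plus its bilinear upsampling."""

    grid: np.ndarray        # (H/P, W/P), values in [0, 1]
    upsampled: np.ndarray   # (H, W), values in [0, 1]
    target_class: int

    def __post_init__(self) -> None:
        for arr in (self.grid, self.upsampled):
            if arr.min() < 0 or arr.max() > 1 + 1e-6:
                raise ValueError("saliency values must lie in [0, 1]")


def _upsample_bilinear(grid: np.ndarray, size: int) -> np.ndarray:
    im = Image.fromarray(grid.astype(np.float32), mode="F")
    up = np.asarray(im.resize((size, size), Image.BILINEAR), dtype=np.float64)
    return np.clip(up, 0.0, 1.0)


def gradcam(model: RViT, image: np.ndarray, target_class: int,
            mode: str = "unrotated") -> SaliencyMap:
    """Saliency of ``target_class``'s logit for one (H, W, C) image.

    The model is run in eval mode; gradients flow from the raw logit (not
    the softmax) to the last encoder layer's token activations.

    ``mode`` is ``"unrotated"`` (default: the grid is read in the input
    frame) or ``"branch_average"`` (mean of the map re-oriented into each
    rotation branch's frame).
    """
    if target_class not in (0, 1):
        raise ValueError("target_class must be 0 or 1")
    if mode not in ("unrotated", "branch_average"):
        raise ValueError(f"unknown Grad-CAM mode {mode!r}")
    cfg = model.config
    image = np.asarray(image)
    logits = model.forward(image[None], training=False)
    dlogits = np.zeros_like(logits)
    dlogits[0, target_class] = 1.0
    model.zero_grad()
    model.backward(dlogits)
    acts = model.last_encoder_tokens[0]   # (N+1, D)
    grads = model.last_encoder_grad[0]    # (N+1, D)
    weights = grads[1:, :].mean(axis=0)   # GAP over non-class tokens
    cam = np.maximum(acts[1:, :] @ weights, 0.0)
    g = cfg.grid
    grid = cam.reshape(g, g).astype(np.float64)

    if mode == "branch_average":
        k = cfg.effective_rotations
        step = 4 // k
        grid = np.mean(
            [np.rot90(grid, -(j * step)) for j in range(k)], axis=0)

    peak = grid.max()
    if peak > 0:
        grid = grid / peak
    up = _upsample_bilinear(grid, cfg.image_size)
    return SaliencyMap(grid=grid, upsampled=up,
                       target_class=target_class)


def save_overlay(image: np.ndarray, saliency: SaliencyMap, path,
                 alpha: float = 0.45) -> None:
    """Write a PNG with the heatmap alpha-blended onto the input image."""
    from matplotlib import colormaps

    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 3 and image.shape[2] == 1:
        image = np.repeat(image, 3, axis=2)
    elif image.ndim == 2:
        image = np.repeat(image[:, :, None], 3, axis=2)
    heat = colormaps["jet"](saliency.upsampled)[:, :, :3]
    blended = (1.0 - alpha) * image + alpha * heat
    arr = (np.clip(blended, 0, 1) * 255).round().astype(np.uint8)
    Image.fromarray(arr).save(path)
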