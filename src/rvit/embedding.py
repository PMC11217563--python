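"""Patch embedding, rotation averaging, class token and position embeddings.

The invariance trick lives here: one linear projector ``E`` (shared across
all k rotation branches) embeds the flattened patches of each rotated copy
of the image, and the per-branch token sequences are averaged elementwise.
Because rotating the input merely permutes the set of rotated copies, the
average — and everything downstream of it — is exactly invariant to quarter
rotations.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np

from .nn import DepthwiseStem, Linear

__all__ = [
    "PatchProjector",
    "embed_patches",
    "average_rotated_embeddings",
    "add_class_and_positions",
    "depthwise_stem",
]


class PatchProjector(Linear):
    """Linear map from flattened patches (P*P*C) to D-dimensional tokens.

    A single instance is shared by all rotation branches of one model, so
    rotation averaging adds no parameters.
    """

    def __init__(self, patch_dim: int, embed_dim: int,
                 rng: np.random.Generator | None = None):
        super().__init__(patch_dim, embed_dim, rng or np.random.default_rng(0))


def embed_patches(patches: np.ndarray, projector: PatchProjector) -> np.ndarray:
    """Project an (N, P*P*C) patch sequence to an (N, D) token sequence."""
    patches = np.asarray(patches)
    if patches.ndim != 2:
        raise ValueError(f"expected an (N, patch_dim) array, got shape {patches.shape}")
    if patches.shape[1] != projector.d_in:
        raise ValueError(
            f"patch length {patches.shape[1]} does not match projector "
            f"input size {projector.d_in}"
        )
    out = patches @ projector.weight.value
    if projector.bias is not None:
        out = out + projector.bias.value
    return out


def average_rotated_embeddings(per_rotation: Sequence[np.ndarray]) -> np.ndarray:
    """Elementwise arithmetic mean of k same-shape token sequences.

    No renormalization is applied; with k = 1 the input is returned
    unchanged (up to dtype).
    """
    if len(per_rotation) == 0:
        raise ValueError("need at least one embedding sequence to average")
    first = np.asarray(per_rotation[0])
    for seq in per_rotation[1:]:
        if np.asarray(seq).shape != first.shape:
            raise ValueError(
                f"embedding shapes differ: {first.shape} vs {np.asarray(seq).shape}"
            )
    return np.mean(np.stack([np.asarray(s) for s in per_rotation]), axis=0)


def add_class_and_positions(
    tokens: np.ndarray, class_token: np.ndarray, positions: np.ndarray
) -> np.ndarray:
    """Prepend the class token, then add position embeddings elementwise.

    ``tokens`` is (N, D) without a class token; ``positions`` must be
    (N+1, D) — index 0 is the class-token position. Output is (N+1, D).
    """
    tokens = np.asarray(tokens)
    class_token = np.asarray(class_token).reshape(1, -1)
    positions = np.asarray(positions)
    n, d = tokens.shape
    if class_token.shape[1] != d:
        raise ValueError(f"class token dim {class_token.shape[1]} != token dim {d}")
    if positions.shape != (n + 1, d):
        raise ValueError(
            f"position table must be {(n + 1, d)}, got {positions.shape}"
        )
    return np.concatenate([class_token, tokens], axis=0) + positions


def depthwise_stem(image: np.ndarray, stem: DepthwiseStem) -> np.ndarray:
    """Apply the depth-wise + pointwise convolution stem to one (H, W, C) image.

    Spatial size is preserved so patch extraction downstream is unchanged.
    Inside the model this runs independently on each rotated copy.
    """
    image = np.asarray(image)
    if image.ndim != 3:
        raise ValueError(f"expected an (H, W, C) image, got shape {image.shape}")
    out = stem(image[None])
    stem.clear_caches()  # inference-only entry point
    return out[0]
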