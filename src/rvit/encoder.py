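"""Transformer encoder stack and the two-class softmax head."""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np

from .nn import EncoderBlock, Linear, softmax

__all__ = ["ClassifierHead", "encoder_forward", "classify"]


class ClassifierHead(Linear):
    """Linear map from the final class-token state to the two class logits."""

    def __init__(self, dim: int, num_classes: int = 2,
                 rng: np.random.Generator | None = None):
        super().__init__(dim, num_classes, rng or np.random.default_rng(0))


def encoder_forward(
    tokens: np.ndarray,
    layers: Sequence[EncoderBlock],
    training: bool = False,
) -> np.ndarray:
    """Run an (N+1, D) or (B, N+1, D) token sequence through L pre-norm blocks.

    Each block is LN -> multi-head attention -> residual, then
    LN -> feed-forward -> residual; shape is preserved. Dropout (on the
    attention weights) is active only when ``training`` is True.
    """
    if len(layers) < 1:
        raise ValueError("encoder needs at least one layer")
    x = np.asarray(tokens)
    squeeze = x.ndim == 2
    if squeeze:
        x = x[None]
    for blk in layers:
        x = blk(x, training)
    if not training:
        for blk in layers:
            blk.clear_caches()
    return x[0] if squeeze else x


def classify(encoded: np.ndarray, head: ClassifierHead) -> np.ndarray:
    """Softmax class probabilities from the class token (index 0).

    Accepts (N+1, D) or (B, N+1, D); returns (2,) or (B, 2) probabilities
    that are positive and sum to one.
    """
    encoded = np.asarray(encoded)
    squeeze = encoded.ndim == 2
    if squeeze:
        encoded = encoded[None]
    cls_state = encoded[:, 0, :]
    logits = cls_state @ head.weight.value + (
        head.bias.value if head.bias is not None else 0.0
    )
    probs = softmax(logits, axis=-1)
    return probs[0] if squeeze else probs
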