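"""Lossless quarter-turn rotations and image-to-patch decomposition.

All rotations here are exact pixel permutations (multiples of 90 degrees,
counter-clockwise); no interpolation ever happens, which is what makes the
rotation-averaged embedding of the classifier *exactly* invariant rather
than approximately so. Arbitrary-angle rotation is deliberately unsupported.

Conventions, fixed so every example in the test suite is reproducible:

* images are ``(H, W, C)`` (or batched ``(B, H, W, C)``) float arrays,
* quarter turns are counter-clockwise (the ``numpy.rot90`` convention),
* the patch grid is row-major with a top-left origin, and each patch is
  flattened in row-major pixel order with the channel axis last.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RotationSet",
    "rotate_quarter",
    "make_rotation_set",
    "extract_patches",
    "reassemble_patches",
    "grid_side",
]

#: rotation counts that divide the 4-fold rotation group
ALLOWED_ROTATION_COUNTS = (1, 2, 4)


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3:
        raise ValueError(
            f"expected an (H, W, C) image array, got shape {image.shape}"
        )
    return image


def rotate_quarter(image: np.ndarray, quarter_turns: int) -> np.ndarray:
    """Rotate a square image by ``quarter_turns`` * 90 degrees counter-clockwise.

    The rotation is a pure permutation of pixels: applying it four times
    returns the input bit-exactly.

    Parameters
    ----------
    image
        ``(H, W, C)`` array with ``H == W``.
    quarter_turns
        Any integer; taken modulo 4.

    Returns
    -------
    numpy.ndarray
        The rotated image (a copy, same shape and dtype).
    """
    image = _check_image(image)
    h, w = image.shape[:2]
    if h != w:
        raise ValueError(f"rotation requires a square image, got {h}x{w}")
    return np.ascontiguousarray(np.rot90(image, int(quarter_turns) % 4, axes=(0, 1)))


@dataclass(frozen=True)
class RotationSet:
    """An ordered set of quarter-rotated copies of one image.

    ``images[j]`` is the source rotated by ``angles[j]`` quarter turns
    counter-clockwise; ``images[0]`` is the unrotated source.
    """

    images: tuple[np.ndarray, ...]
    angles: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.images) < 1:
            raise ValueError("a rotation set needs at least one image")
        shape = self.images[0].shape
        for im in self.images:
            if im.shape != shape:
                raise ValueError("all rotated copies must share one shape")

    def __len__(self) -> int:
        return len(self.images)

    def __iter__(self):
        return iter(self.images)


def make_rotation_set(image: np.ndarray, k: int = 4) -> RotationSet:
    """Generate the ``k`` quarter-rotated versions of a square image.

    Element ``j`` is the source rotated by ``j * (4 // k)`` quarter turns, so
    ``k=4`` gives 0/90/180/270 degrees, ``k=2`` gives 0/180 and ``k=1`` only
    the source. Only divisors of the 4-fold rotation group are allowed:
    averaging over a *subgroup* of rotations is what yields exact invariance.
    """
    if k not in ALLOWED_ROTATION_COUNTS:
        raise ValueError(
            f"rotation count k must be one of {ALLOWED_ROTATION_COUNTS}, got {k}"
        )
    step = 4 // k
    angles = tuple(j * step for j in range(k))
    images = tuple(
        image if j == 0 else rotate_quarter(image, a)
        for j, a in enumerate(angles)
    )
    return RotationSet(images=images, angles=angles)


def grid_side(image_size: int, patch_size: int) -> int:
    """Number of patches along one image side; errors if not divisible."""
    if image_size % patch_size != 0:
        raise ValueError(
            f"image side {image_size} is not divisible by patch size {patch_size}"
        )
    return image_size // patch_size


def extract_patches(image: np.ndarray, patch_size: int) -> np.ndarray:
    """Cut an image into a row-major grid of flattened patches.

    Returns an ``(N, P*P*C)`` array with ``N = (H/P) * (W/P)``. The first row
    is the top-left patch; the grid scans left-to-right, then top-to-bottom.
    Each patch is flattened pixel-row-major with channels last.
    """
    image = _check_image(image)
    h, w, c = image.shape
    gh = grid_side(h, patch_size)
    gw = grid_side(w, patch_size)
    p = patch_size
    blocks = image.reshape(gh, p, gw, p, c).transpose(0, 2, 1, 3, 4)
    return np.ascontiguousarray(blocks.reshape(gh * gw, p * p * c))


def reassemble_patches(
    patches: np.ndarray, image_size: int, patch_size: int, channels: int
) -> np.ndarray:
    """Inverse of :func:`extract_patches` for a square image."""
    g = grid_side(image_size, patch_size)
    p = patch_size
    patches = np.asarray(patches)
    if patches.shape != (g * g, p * p * channels):
        raise ValueError(
            f"expected {(g * g, p * p * channels)} patch array, got {patches.shape}"
        )
    blocks = patches.reshape(g, g, p, p, channels).transpose(0, 2, 1, 3, 4)
    return np.ascontiguousarray(blocks.reshape(image_size, image_size, channels))


# ---------------------------------------------------------------------------
# batched helpers used by the model forward/backward pass


def extract_patches_batch(images: np.ndarray, patch_size: int) -> np.ndarray:
    """(B, H, W, C) -> (B, N, P*P*C), same ordering as :func:`extract_patches`."""
    b, h, w, c = images.shape
    gh = grid_side(h, patch_size)
    gw = grid_side(w, patch_size)
    p = patch_size
    blocks = images.reshape(b, gh, p, gw, p, c).transpose(0, 1, 3, 2, 4, 5)
    return np.ascontiguousarray(blocks.reshape(b, gh * gw, p * p * c))


def scatter_patches_batch(
    grads: np.ndarray, image_size: int, patch_size: int, channels: int
) -> np.ndarray:
    """Adjoint of :func:`extract_patches_batch` (a pure reshape, so its own inverse)."""
    b = grads.shape[0]
    g = grid_side(image_size, patch_size)
    p = patch_size
    blocks = grads.reshape(b, g, g, p, p, channels).transpose(0, 1, 3, 2, 4, 5)
    return np.ascontiguousarray(blocks.reshape(b, image_size, image_size, channels))
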