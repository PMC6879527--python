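"""Teeth-region (ROI) segmentation, mask post-processing and crop extraction.

A panoramic radiograph contains a lot of anatomy that is irrelevant to
periodontal bone loss; only the arch-shaped band containing the teeth
matters.  This module trains a U-shaped segmenter for that band with a
binary cross-entropy + L2 loss, cleans the predicted mask (hole filling
followed by convex hull), and extracts a normalized crop of the mask's
bounding box that downstream networks consume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage.transform import resize

from . import _losses, nn
from .networks import UNet

__all__ = [
    "SegmenterConfig",
    "RoiCrop",
    "bce_l2_loss",
    "train_roi_segmenter",
    "postprocess_mask",
    "extract_roi",
    "dice",
]

#: below this in-mask standard deviation a crop is treated as constant and
#: z-scoring returns zeros instead of dividing by ~0
STD_FLOOR = 1e-8


@dataclass
class SegmenterConfig:
    """Hyperparameters for a U-shaped segmenter training run.

    ``input_shape`` must be divisible by ``2 ** depth``.  The defaults are
    the full-scale settings (512x1024, lambda 1e-4, learning rate 1e-4,
    50 epochs); desk-scale runs pass smaller shapes and epoch counts.
    """

    input_shape: tuple = (512, 1024)
    depth: int = 4
    base_channels: int = 16
    lambda_l2: float = 1e-4
    learning_rate: float = 1e-4
    epochs: int = 50
    batch_size: int = 4
    gamma: float = 2.0  # used only by focal-loss training (lesion net)

    def __post_init__(self):
        h, w = self.input_shape
        if h % 2 ** self.depth or w % 2 ** self.depth:
            raise ValueError(
                f"input_shape {self.input_shape} not divisible by "
                f"2**depth = {2 ** self.depth}")


@dataclass
class RoiCrop:
    """A post-processed, cropped and z-scored teeth-region image.

    ``image`` is z-scored over in-mask pixels (mean ~0, std ~1) with
    out-of-mask pixels set to 0; ``bbox`` is the axis-aligned, 0-based,
    half-open bounding box in source coordinates.
    """

    image: np.ndarray
    bbox: tuple
    mask: np.ndarray


def bce_l2_loss(pred, target, weights=(), lambda_l2: float = 0.0):
    """Pixel binary cross-entropy plus an L2 weight penalty.

    ``-(1/n) sum_i [y_i log p_i + (1-y_i) log(1-p_i)] + (lam/2n) sum_k w_k^2``
    with n the number of pixels.  Probabilities are clamped to
    [1e-7, 1 - 1e-7] before the logarithm.  Accepts plain arrays (returns a
    float) or autograd tensors (returns a scalar tensor).
    """
    elements = _losses.bce_elements(pred, target)
    n = pred.data.size if isinstance(pred, nn.Tensor) else np.asarray(pred).size
    return _losses.mean_loss(elements,
                             _losses.l2_penalty(weights, lambda_l2, n))


def _as_batches(n, batch_size, rng):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def _prepare_pairs(dataset, shape):
    """Stack (image, mask) pairs, resizing to ``shape`` when needed."""
    images, masks = [], []
    for img, msk in dataset:
        img = np.asarray(img, dtype=np.float64)
        msk = np.asarray(msk)
        if img.shape != tuple(shape):
            img = resize(img, shape, order=1, preserve_range=True,
                         anti_aliasing=False)
            msk = resize(msk.astype(float), shape, order=0,
                         preserve_range=True, anti_aliasing=False)
        images.append(img)
        masks.append((msk > 0.5).astype(np.float64))
    return np.stack(images), np.stack(masks)


def train_roi_segmenter(dataset, config: SegmenterConfig, seed: int = 0,
                        log=None):
    """Train the teeth-region segmenter with Adam on the BCE + L2 loss.

    ``dataset`` is a sequence of (image, roi_mask) pairs; pairs are resized
    to ``config.input_shape`` if needed.  Returns the trained ``UNet``.
    Deterministic for a fixed seed and dataset.
    """
    if len(dataset) == 0:
        raise ValueError("cannot train the ROI segmenter on an empty dataset")
    rng = np.random.default_rng(seed)
    images, masks = _prepare_pairs(dataset, config.input_shape)
    model = UNet(in_ch=1, base=config.base_channels, depth=config.depth,
                 rng=rng)
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    weights = [p for name, p in model.named_parameters()
               if name.endswith(".w")]
    for epoch in range(config.epochs):
        epoch_loss = 0.0
        n_batches = 0
        for idx in _as_batches(len(images), config.batch_size, rng):
            x = nn.Tensor(images[idx][:, None])
            pred = model(x)
            loss = bce_l2_loss(pred, masks[idx][:, None], weights,
                               config.lambda_l2)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.item()
            n_batches += 1
        if log is not None:
            log.append({"epoch": epoch, "loss": epoch_loss / n_batches})
    return model


# --------------------------------------------------------------------------
# mask post-processing


def _convex_hull_mask(mask: np.ndarray) -> np.ndarray:
    """Rasterize the convex hull of a binary mask's foreground pixel centers.

    A pixel belongs to the output when its center lies in the closed convex
    hull (half-space inequalities satisfied up to 1e-9).  Degenerate
    foregrounds (collinear or fewer than 3 points) are returned unchanged.
    """
    pts = np.argwhere(mask)
    if len(pts) < 3:
        return mask.copy()
    try:
        hull = ConvexHull(pts.astype(float))
    except QhullError:  # collinear foreground
        return mask.copy()
    rows = np.arange(mask.shape[0])
    cols = np.arange(mask.shape[1])
    grid = np.stack(np.meshgrid(rows, cols, indexing="ij"), axis=-1).astype(float)
    # hull.equations: A @ x + b <= 0 inside
    a, b = hull.equations[:, :2], hull.equations[:, 2]
    inside = (grid @ a.T + b <= 1e-9).all(axis=-1)
    return inside.astype(mask.dtype)


def postprocess_mask(raw_mask: np.ndarray) -> np.ndarray:
    """Fill holes in a predicted mask, then take its convex hull.

    The output is a superset of the input foreground.  An all-zero mask is
    returned unchanged with a warning.
    """
    raw_mask = np.asarray(raw_mask)
    if raw_mask.size == 0:
        raise ValueError("empty image")
    binary = (raw_mask > 0).astype(np.uint8)
    if not binary.any():
        warnings.warn("postprocess_mask received an all-zero mask",
                      stacklevel=2)
        return binary
    filled = ndimage.binary_fill_holes(binary).astype(np.uint8)
    return _convex_hull_mask(filled)


def extract_roi(image: np.ndarray, processed_mask: np.ndarray,
                out_shape=(512, 1024)) -> RoiCrop:
    """Crop the mask's bounding box, resize, zero the background, z-score.

    The z-score statistics are computed over in-mask pixels only; a crop
    that is constant inside the mask comes back as all zeros rather than
    dividing by a vanishing standard deviation.
    """
    image = np.asarray(image, dtype=np.float64)
    processed_mask = np.asarray(processed_mask)
    if image.shape != processed_mask.shape:
        raise ValueError(
            f"image {image.shape} and mask {processed_mask.shape} differ")
    fg = np.argwhere(processed_mask > 0)
    if len(fg) == 0:
        raise ValueError("cannot extract an ROI from an empty mask")
    r0, c0 = fg.min(axis=0)
    r1, c1 = fg.max(axis=0) + 1
    bbox = (int(r0), int(c0), int(r1), int(c1))
    crop = image[r0:r1, c0:c1]
    mask_crop = (processed_mask[r0:r1, c0:c1] > 0)
    crop = resize(crop, out_shape, order=1, preserve_range=True,
                  anti_aliasing=False)
    mask_out = resize(mask_crop.astype(float), out_shape, order=0,
                      preserve_range=True, anti_aliasing=False) > 0.5
    inside = crop[mask_out]
    mu, sigma = inside.mean(), inside.std()
    out = np.zeros(out_shape, dtype=np.float64)
    if sigma > STD_FLOOR:
        out[mask_out] = (inside - mu) / sigma
    return RoiCrop(image=out, bbox=bbox, mask=mask_out.astype(np.uint8))


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|); two empty masks give 1.0."""
    a = np.asarray(a) > 0
    b = np.asarray(b) > 0
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom
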