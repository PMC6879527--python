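"""Lesion-segmentation pre-training for encoder transfer.

Positive tooth-level examples are scarce and imbalanced, so the tooth
classifier is not trained from random weights: a lesion segmentation
network with the same U-shaped architecture is first trained on
union-aggregated annotator masks with a pixel focal loss (gamma = 2), and
its encoder weights initialize the classifier.  The focal term
(1 - p)^gamma down-weights well-classified pixels so the rare lesion
pixels dominate the gradient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import _losses, nn
from .networks import UNet
from .roi import RoiCrop, SegmenterConfig, _as_batches, dice

__all__ = [
    "AugmentParams",
    "pixel_focal_loss",
    "augment",
    "train_lesion_segmenter",
]


@dataclass
class AugmentParams:
    """Bounds for the random training augmentations.

    Geometry (rotation up to ``max_rotation_deg`` degrees, shifts up to
    ``max_shift_frac`` of each dimension) is applied identically to image
    and mask; photometric jitter (brightness, sharpness, contrast within
    ``max_photometric_frac``) touches the image only.
    """

    max_rotation_deg: float = 10.0
    max_shift_frac: float = 0.10
    max_photometric_frac: float = 0.15

    def __post_init__(self):
        if min(self.max_rotation_deg, self.max_shift_frac,
               self.max_photometric_frac) < 0:
            raise ValueError("augmentation bounds must be nonnegative")


def pixel_focal_loss(pred, target, gamma: float = 2.0):
    """Mean pixel focal loss.

    ``-(1/n) sum_i [(1-p_i)^g y_i log p_i + p_i^g (1-y_i) log(1-p_i)]``
    with probabilities clamped to [1e-7, 1-1e-7].  At gamma = 0 this is
    exactly the unweighted binary cross-entropy.  Accepts arrays or
    autograd tensors.
    """
    return _losses.mean_loss(_losses.focal_elements(pred, target, gamma))


def _affine(image, angle_deg, shift_rc, order, cval=0.0):
    """Rotate about the center then shift, in one resampling pass."""
    theta = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]])
    center = (np.asarray(image.shape) - 1) / 2.0
    # output coords -> input coords: inverse rotation, then undo the shift
    offset = center - rot.T @ (center + np.asarray(shift_rc))
    return ndimage.affine_transform(image, rot.T, offset=offset, order=order,
                                    mode="constant", cval=cval)


def augment(image, mask, params: AugmentParams, rng):
    """One random augmentation draw applied jointly to image and mask.

    All parameters are drawn uniformly within the configured bounds from
    ``rng``; with all bounds zero the pair is returned unchanged.
    """
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask)
    angle = rng.uniform(-params.max_rotation_deg, params.max_rotation_deg)
    shift = (rng.uniform(-params.max_shift_frac, params.max_shift_frac)
             * image.shape[0],
             rng.uniform(-params.max_shift_frac, params.max_shift_frac)
             * image.shape[1])
    f = params.max_photometric_frac
    brightness = rng.uniform(-f, f)
    contrast = 1.0 + rng.uniform(-f, f)
    sharpness = rng.uniform(-f, f)

    if angle != 0.0 or any(shift):
        out_img = _affine(image, angle, shift, order=1)
        out_mask = _affine(mask.astype(float), angle, shift, order=0)
        out_mask = (out_mask > 0.5).astype(mask.dtype)
    else:
        out_img, out_mask = image.copy(), mask.copy()

    if f > 0:
        scale = out_img.std() or 1.0
        out_img = (out_img - out_img.mean()) * contrast + out_img.mean()
        out_img = out_img + brightness * scale
        # "sharpness" as unsharp-mask blending
        blurred = ndimage.gaussian_filter(out_img, sigma=1.0)
        out_img = out_img + sharpness * (out_img - blurred)
    return out_img, out_mask


def train_lesion_segmenter(dataset, config: SegmenterConfig,
                           gamma: float = 2.0,
                           augment_params: AugmentParams | None = None,
                           seed: int = 0, log=None):
    """Train the lesion segmenter on (crop, union-mask) pairs.

    ``dataset`` holds (RoiCrop-or-array, aggregated lesion mask) pairs.
    Returns ``(model, encoder_state)`` where ``encoder_state`` is the
    ordered name -> array mapping of the encoder weights used for transfer.
    """
    if len(dataset) == 0:
        raise ValueError("cannot pre-train on an empty dataset")
    if gamma < 0:
        raise ValueError(f"gamma must be nonnegative, got {gamma}")
    rng = np.random.default_rng(seed)
    images = np.stack([
        crop.image if isinstance(crop, RoiCrop) else np.asarray(crop, float)
        for crop, _ in dataset])
    masks = np.stack([np.asarray(m, dtype=np.float64) for _, m in dataset])
    model = UNet(in_ch=1, base=config.base_channels, depth=config.depth,
                 rng=rng)
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    for epoch in range(config.epochs):
        epoch_loss, n_batches = 0.0, 0
        for idx in _as_batches(len(images), config.batch_size, rng):
            if augment_params is not None:
                pairs = [augment(images[i], masks[i], augment_params, rng)
                         for i in idx]
                xb = np.stack([p[0] for p in pairs])
                yb = np.stack([p[1].astype(np.float64) for p in pairs])
            else:
                xb, yb = images[idx], masks[idx]
            pred = model(nn.Tensor(xb[:, None]))
            loss = pixel_focal_loss(pred, yb[:, None], gamma)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.item()
            n_batches += 1
        if log is not None:
            entry = {"epoch": epoch, "loss": epoch_loss / n_batches}
            log.append(entry)
    return model, model.encoder_state()


def heldout_lesion_dice(model, dataset, threshold: float = 0.5) -> float:
    """Mean dice between thresholded predictions and reference masks."""
    scores = []
    for crop, mask in dataset:
        img = crop.image if isinstance(crop, RoiCrop) else np.asarray(crop)
        prob = model.predict(img[None])[0]
        scores.append(dice(prob >= threshold, np.asarray(mask) > 0))
    return float(np.mean(scores))
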