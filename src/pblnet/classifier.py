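"""Tooth-level multi-label classification with co-occurrence regularization.

Two classifiers are trained jointly from the transferred lesion-segmenter
encoder: a generalist ``f_a`` that sees the whole ROI crop and predicts all
32 teeth, and a premolar/molar specialist ``f_b`` that sees a vertical half
of the crop (doubling the effective sample count) with incisor and canine
labels zeroed.  At inference the two are blended: incisor/canine scores come
from ``f_a`` alone and premolar/molar scores are the convex combination
``alpha * f_a + (1 - alpha) * f_b`` with ``f_b`` evaluated on the half that
contains the tooth.

The training loss adds to the per-tooth focal loss a small auxiliary
penalty pulling the 16 scores of each jaw toward the co-occurrence target
derived from that jaw's co-occurrence matrix, encoding the clinical prior
that periodontal bone loss clusters on horizontally adjacent teeth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _resize

from . import _losses, nn
from .labels import (LEFT_HALF_INDICES, RIGHT_HALF_INDICES,
                     PREMOLAR_MOLAR_INDICES, INCISOR_CANINE_INDICES,
                     N_TEETH, cooccurrence_target,
                     mask_labels_premolar_molar)
from .networks import ToothClassifier
from .pretrain import AugmentParams, augment
from .roi import RoiCrop, _as_batches

__all__ = [
    "ClassifierConfig",
    "build_classifier",
    "tooth_focal_loss",
    "aux_cooccurrence_loss",
    "final_loss",
    "vertical_split",
    "mask_labels_premolar_molar",
    "train_tooth_classifiers",
    "run_training_steps",
    "ensemble_predict",
    "gradcam",
]


@dataclass
class ClassifierConfig:
    """Hyperparameters for the tooth-level classifiers.

    ``beta`` weighs the auxiliary co-occurrence loss and ``alpha`` the
    generalist's share in the premolar/molar ensemble.  Full-scale defaults
    are epochs=100 and learning rate 1e-5; desk-scale runs shrink both.
    """

    gamma: float = 2.0
    lambda_l2: float = 1e-4
    beta: float = 0.01
    alpha: float = 0.1
    learning_rate: float = 1e-5
    epochs: int = 100
    batch_size: int = 8
    base_channels: int = 8
    depth: int = 3

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta must lie in [0, 1], got {self.beta}")


def build_classifier(encoder, config: ClassifierConfig, input_shape,
                     seed: int = 0) -> ToothClassifier:
    """Instantiate a classifier, optionally transfer-initializing its encoder.

    ``encoder`` is a name -> array mapping from a segmenter's
    ``encoder_state()`` (or ``None`` for random initialization, the
    ablation control).  Shape incompatibility raises with the offending
    layer named.
    """
    h, w = input_shape
    if h % 2 ** config.depth or w % 2 ** config.depth:
        raise ValueError(
            f"input_shape {input_shape} not divisible by 2**depth")
    model = ToothClassifier(in_ch=1, base=config.base_channels,
                            depth=config.depth,
                            rng=np.random.default_rng(seed))
    if encoder is not None:
        model.load_encoder_state(encoder)
    return model


def tooth_focal_loss(pred, target, gamma: float = 2.0,
                     lambda_l2: float = 0.0, weights=()):
    """Focal loss averaged over all (sample, tooth) entries, plus L2.

    Reduces to the mean binary cross-entropy at gamma = 0 and lambda = 0.
    """
    elements = _losses.focal_elements(pred, target, gamma)
    n = pred.data.size if isinstance(pred, nn.Tensor) else np.asarray(pred).size
    return _losses.mean_loss(elements,
                             _losses.l2_penalty(weights, lambda_l2, n))


def _aux_targets(y, matrix):
    y = np.atleast_2d(np.asarray(y))
    return np.stack([cooccurrence_target(row, matrix) for row in y])


def aux_cooccurrence_loss(pred, y, matrix):
    """Squared distance between scores and the co-occurrence target.

    For one jaw: sum over the 16 teeth of (c_j - p_j)^2, averaged over the
    batch, with the target c derived from the binary labels and the jaw's
    co-occurrence matrix (all-negative labels give c = 0).
    """
    c = _aux_targets(y, matrix)
    if isinstance(pred, nn.Tensor):
        p = pred if pred.ndim == 2 else pred.reshape(1, -1)
        diff = p - c
        return (diff * diff).sum(axis=1).mean()
    p = np.atleast_2d(np.asarray(pred, dtype=float))
    return float(np.mean(np.sum((c - p) ** 2, axis=1)))


def final_loss(pred, target, c_upper, c_lower, config: ClassifierConfig,
               weights=()):
    """Total training loss: focal + L2 + beta * per-jaw auxiliary losses.

    The upper 16 outputs are regularized with the upper-jaw co-occurrence
    matrix, the lower 16 with the lower-jaw matrix.  At beta = 0 this is
    exactly ``tooth_focal_loss``.
    """
    base = tooth_focal_loss(pred, target, config.gamma, config.lambda_l2,
                            weights)
    if config.beta == 0.0:
        return base
    target = np.atleast_2d(np.asarray(target))
    if isinstance(pred, nn.Tensor):
        p = pred if pred.ndim == 2 else pred.reshape(1, -1)
        upper = aux_cooccurrence_loss(p[:, :16], target[:, :16], c_upper)
        lower = aux_cooccurrence_loss(p[:, 16:], target[:, 16:], c_lower)
    else:
        p = np.atleast_2d(np.asarray(pred))
        upper = aux_cooccurrence_loss(p[:, :16], target[:, :16], c_upper)
        lower = aux_cooccurrence_loss(p[:, 16:], target[:, 16:], c_lower)
    return base + config.beta * (upper + lower)


def vertical_split(image):
    """Split an (H, W) crop into its left and right column halves."""
    image = np.asarray(image)
    w = image.shape[-1]
    if w % 2:
        raise ValueError(f"vertical_split needs an even width, got {w}")
    return image[..., : w // 2], image[..., w // 2:]


# sides: half index 0 = left (FDI quadrants 1 and 4), 1 = right (2 and 3)
_SIDE_INDICES = (LEFT_HALF_INDICES, RIGHT_HALF_INDICES)


def _half_target(y, side):
    """f_b target for one half: premolar/molar labels of that half only."""
    out = mask_labels_premolar_molar(y)
    absent = _SIDE_INDICES[1 - side]
    out[..., absent] = 0
    return out


def _crop_image(crop):
    return crop.image if isinstance(crop, RoiCrop) else np.asarray(crop, float)


def run_training_steps(model, images, targets, c_upper, c_lower,
                       config: ClassifierConfig, rng, steps: int,
                       opt=None) -> float:
    """Run a fixed number of minibatch updates; returns the last batch loss."""
    if opt is None:
        opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    weights = [p for name, p in model.named_parameters()
               if name.endswith(".w")]
    n = len(images)
    last = float("nan")
    done = 0
    while done < steps:
        for idx in _as_batches(n, config.batch_size, rng):
            pred = model(nn.Tensor(images[idx][:, None]))
            loss = final_loss(pred, targets[idx], c_upper, c_lower, config,
                              weights)
            opt.zero_grad()
            loss.backward()
            opt.step()
            last = loss.item()
            done += 1
            if done >= steps:
                break
    return last


def train_tooth_classifiers(dataset, encoder, c_upper, c_lower,
                            config: ClassifierConfig, seed: int = 0,
                            augment_params: AugmentParams | None = None,
                            log=None):
    """Jointly train the generalist f_a and the half-image specialist f_b.

    ``dataset`` holds (RoiCrop-or-array, 32-length label vector) pairs; the
    co-occurrence matrices must be built from training labels only.  Joint
    training alternates per batch: f_a updates on the full crops, then f_b
    updates on both vertical halves of the same batch with incisor/canine
    (and absent-half) labels zeroed.  Both start from the transferred
    encoder when one is given.  Deterministic per seed.
    """
    if len(dataset) == 0:
        raise ValueError("cannot train classifiers on an empty dataset")
    rng = np.random.default_rng(seed)
    images = np.stack([_crop_image(c) for c, _ in dataset])
    labels = np.stack([np.asarray(y, dtype=np.float64) for _, y in dataset])
    if labels.shape[1] != N_TEETH:
        raise ValueError("labels must be 32-length vectors")
    h, w = images.shape[1:]
    fa = build_classifier(encoder, config, (h, w), seed=seed)
    fb = build_classifier(encoder, config, (h, w // 2), seed=seed + 1)
    opt_a = nn.Adam(fa.parameters(), lr=config.learning_rate)
    opt_b = nn.Adam(fb.parameters(), lr=config.learning_rate)
    weights_a = [p for nme, p in fa.named_parameters() if nme.endswith(".w")]
    weights_b = [p for nme, p in fb.named_parameters() if nme.endswith(".w")]

    half_targets = [np.stack([_half_target(y, side) for y in labels])
                    for side in (0, 1)]

    for epoch in range(config.epochs):
        ep_a, ep_b, n_b = 0.0, 0.0, 0
        for idx in _as_batches(len(images), config.batch_size, rng):
            xb, yb = images[idx], labels[idx]
            if augment_params is not None:
                aug = [augment(x, np.zeros_like(x), augment_params, rng)[0]
                       for x in xb]
                xb = np.stack(aug)
            # generalist update on full crops
            pred = fa(nn.Tensor(xb[:, None]))
            loss_a = final_loss(pred, yb, c_upper, c_lower, config, weights_a)
            opt_a.zero_grad()
            loss_a.backward()
            opt_a.step()
            # specialist update on both halves (2x effective samples)
            halves = vertical_split(xb)
            xh = np.concatenate([halves[0], halves[1]])
            yh = np.concatenate([half_targets[0][idx], half_targets[1][idx]])
            pred_b = fb(nn.Tensor(xh[:, None]))
            loss_b = final_loss(pred_b, yh, c_upper, c_lower, config,
                                weights_b)
            opt_b.zero_grad()
            loss_b.backward()
            opt_b.step()
            ep_a += loss_a.item()
            ep_b += loss_b.item()
            n_b += 1
        if log is not None:
            log.append({"epoch": epoch, "loss_a": ep_a / n_b,
                        "loss_b": ep_b / n_b})
    return fa, fb


def ensemble_predict(fa, fb, roi, alpha: float = 0.1) -> np.ndarray:
    """Blend the generalist and specialist into one 32-score vector.

    Incisor/canine scores are the generalist's; premolar/molar scores are
    ``alpha * f_a + (1 - alpha) * f_b`` with the specialist evaluated on
    the vertical half containing the tooth.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    img = _crop_image(roi)
    scores_a = fa.predict(img[None])[0]
    left, right = vertical_split(img)
    scores_b_left = fb.predict(left[None])[0]
    scores_b_right = fb.predict(right[None])[0]
    out = scores_a.copy()
    for side, sb in ((0, scores_b_left), (1, scores_b_right)):
        idx = np.intersect1d(_SIDE_INDICES[side], PREMOLAR_MOLAR_INDICES)
        out[idx] = alpha * scores_a[idx] + (1.0 - alpha) * sb[idx]
    return out


def gradcam(model: ToothClassifier, roi, tooth_index: int) -> np.ndarray:
    """Grad-CAM heatmap for one tooth's score, aligned to the input crop.

    Channel weights are the spatially averaged gradients of the chosen
    tooth score at the last head convolution; the ReLU-rectified weighted
    sum is max-normalized to [0, 1] and bilinearly upsampled to the crop
    shape.  A map with zero gradient everywhere comes back all-zero with a
    warning.
    """
    if not 0 <= tooth_index < N_TEETH:
        raise ValueError(f"tooth index {tooth_index} outside [0, 31]")
    img = _crop_image(roi)
    x = nn.Tensor(img[None, None])
    model(x)
    act = model._cam_act
    # backpropagate from the pre-sigmoid logit: the sigmoid saturates for
    # confident scores and would shrink the gradients to numerical noise
    model._logits[0, tooth_index].backward()
    if act.grad is None or not np.any(act.grad):
        warnings.warn("Grad-CAM gradients vanish; returning an all-zero map",
                      stacklevel=2)
        return np.zeros(img.shape)
    channel_w = act.grad[0].mean(axis=(1, 2))
    cam = np.maximum((channel_w[:, None, None] * act.data[0]).sum(axis=0), 0.0)
    if cam.max() > 0:
        cam = cam / cam.max()
    else:
        warnings.warn("Grad-CAM map is nonpositive everywhere",
                      stacklevel=2)
        return np.zeros(img.shape)
    return _resize(cam, img.shape, order=1, preserve_range=True,
                   anti_aliasing=False)
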