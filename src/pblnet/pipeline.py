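"""Desk-scale end-to-end experiments over the full multi-phase pipeline.

These helpers wire the stages together at the package's reduced problem
sizes (64x128 images, U-nets with 8 base channels, a few hundred synthetic
cases) so that the whole framework - ROI segmentation, lesion pre-training,
transfer-initialized classification with the auxiliary co-occurrence loss,
specialist/generalist ensembling, operating-point evaluation - runs in
minutes on one CPU.  Paper-scale settings remain reachable through the
config objects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from . import nn
from .classifier import (ClassifierConfig, build_classifier, ensemble_predict,
                         gradcam, run_training_steps, train_tooth_classifiers)
from .evaluation import (auroc, clinician_performance, confusion_metrics,
                         select_operating_point)
from .labels import (aggregate_lesion_mask, aggregate_tooth_labels,
                     build_cooccurrence)
from .pretrain import AugmentParams, heldout_lesion_dice, train_lesion_segmenter
from .roi import RoiCrop, SegmenterConfig, dice, extract_roi, postprocess_mask
from .roi import train_roi_segmenter
from .synthetic import SyntheticConfig, generate_case

DESK_SHAPE = (64, 128)


def desk_synthetic_config(seed: int = 0) -> SyntheticConfig:
    return SyntheticConfig(image_shape=DESK_SHAPE, seed=seed)


def desk_roi_config(epochs: int = 10) -> SegmenterConfig:
    return SegmenterConfig(input_shape=DESK_SHAPE, depth=2, base_channels=8,
                           learning_rate=1e-3, epochs=epochs, batch_size=4)


def desk_lesion_config(epochs: int = 15) -> SegmenterConfig:
    # depth must match the classifier encoder for weight transfer
    return SegmenterConfig(input_shape=DESK_SHAPE, depth=3, base_channels=8,
                           learning_rate=1e-3, epochs=epochs, batch_size=4)


def desk_classifier_config(epochs: int = 30) -> ClassifierConfig:
    return ClassifierConfig(learning_rate=1e-3, epochs=epochs, batch_size=8,
                            base_channels=8, depth=3)


def make_cases(n: int, config: SyntheticConfig, seed: int):
    rng = np.random.default_rng(seed)
    return [generate_case(config, rng) for _ in range(n)]


def crop_companion_mask(crop: RoiCrop, mask: np.ndarray) -> np.ndarray:
    """Apply a crop's bounding box + resize to an aligned binary mask."""
    r0, c0, r1, c1 = crop.bbox
    piece = np.asarray(mask)[r0:r1, c0:c1].astype(float)
    out = resize(piece, crop.image.shape, order=0, preserve_range=True,
                 anti_aliasing=False)
    return (out > 0.5).astype(np.uint8)


def roi_experiment(seed: int, n_train: int = 40, n_val: int = 8,
                   epochs: int = 10):
    """Train the ROI segmenter on synthetic pairs; report held-out dice.

    Returns (model, mean raw dice, mean post-processed dice).
    """
    syn = desk_synthetic_config(seed)
    cases = make_cases(n_train + n_val, syn, seed)
    pairs = [(c.image, c.roi_mask) for c in cases]
    model = train_roi_segmenter(pairs[:n_train], desk_roi_config(epochs),
                                seed=seed)
    raw_scores, post_scores = [], []
    for c in cases[n_train:]:
        prob = model.predict(c.image[None])[0]
        pred = (prob >= 0.5).astype(np.uint8)
        raw_scores.append(dice(pred, c.roi_mask))
        if pred.any():
            post_scores.append(dice(postprocess_mask(pred), c.roi_mask))
        else:
            post_scores.append(0.0)
    return model, float(np.mean(raw_scores)), float(np.mean(post_scores))


def build_crop_dataset(cases, out_shape=DESK_SHAPE, with_lesions=True):
    """Extract ROI crops (from true ROI masks) plus aligned lesion data.

    Returns a list of dicts with the crop, the union-aggregated lesion
    mask in crop coordinates, the majority-vote tooth labels and the
    per-annotator votes.
    """
    out = []
    for c in cases:
        crop = extract_roi(c.image, c.roi_mask, out_shape)
        entry = {"crop": crop,
                 "labels": aggregate_tooth_labels(c.annotator_labels, 3),
                 "votes": c.annotator_labels,
                 "true_labels": c.true_tooth_labels}
        if with_lesions:
            union = aggregate_lesion_mask(c.annotator_masks, 1)
            entry["lesion_mask"] = crop_companion_mask(crop, union)
            entry["true_lesion_mask"] = crop_companion_mask(
                crop, c.true_lesion_mask)
        out.append(entry)
    return out


def pretrain_experiment(seed: int, n_train: int = 60, n_val: int = 12,
                        epochs: int = 15, augment: bool = True):
    """Lesion-segmentation pre-training; returns (model, encoder, val dice)."""
    syn = desk_synthetic_config(seed)
    cases = make_cases(n_train + n_val, syn, seed + 1000)
    data = build_crop_dataset(cases)
    pairs = [(d["crop"], d["lesion_mask"]) for d in data]
    params = AugmentParams() if augment else None
    model, encoder = train_lesion_segmenter(
        pairs[:n_train], desk_lesion_config(epochs), gamma=2.0,
        augment_params=params, seed=seed)
    val = heldout_lesion_dice(model, pairs[n_train:])
    return model, encoder, val


def classifier_experiment(seed: int, encoder, n_train: int = 200,
                          n_test: int = 40, epochs: int = 30):
    """Train f_a/f_b from a transferred encoder and evaluate the ensemble.

    Returns a dict with the models, the co-occurrence matrices (built from
    training labels only), ensembled test scores/labels, the test votes,
    and the micro-AUROC.
    """
    syn = desk_synthetic_config(seed)
    cases = make_cases(n_train + n_test, syn, seed + 2000)
    data = build_crop_dataset(cases[:n_train], with_lesions=False)
    train = data
    test = build_crop_dataset(cases[n_train:], with_lesions=True)
    train_labels = np.stack([d["labels"] for d in train])
    comat = build_cooccurrence(train_labels)
    cfg = desk_classifier_config(epochs)
    # no geometric augmentation here: at desk scale a 10% shift moves a
    # tooth by ~2 tooth pitches while its label index stays fixed, which
    # destroys the position-label correspondence the head must learn
    fa, fb = train_tooth_classifiers(
        [(d["crop"], d["labels"]) for d in train], encoder,
        comat.upper, comat.lower, cfg, seed=seed, augment_params=None)
    scores = np.stack([ensemble_predict(fa, fb, d["crop"], cfg.alpha)
                       for d in test])
    labels = np.stack([d["labels"] for d in test])
    votes = np.stack([d["votes"] for d in test])
    return {
        "fa": fa, "fb": fb, "cooccurrence": comat, "config": cfg,
        "test_data": test, "scores": scores, "labels": labels,
        "votes": votes, "micro_auroc": auroc(scores, labels),
    }


def transfer_ablation(seed: int, encoder, n_train: int = 64,
                      steps: int = 40):
    """Training loss after a fixed step budget: transferred vs random init.

    Returns (loss_transfer, loss_random); the transferred encoder is
    expected to reach the lower loss.
    """
    syn = desk_synthetic_config(seed)
    cases = make_cases(n_train, syn, seed + 3000)
    data = build_crop_dataset(cases, with_lesions=False)
    images = np.stack([d["crop"].image for d in data])
    labels = np.stack([d["labels"].astype(float) for d in data])
    comat = build_cooccurrence(np.stack([d["labels"] for d in data]))
    cfg = desk_classifier_config()
    losses = {}
    for name, enc in (("transfer", encoder), ("random", None)):
        model = build_classifier(enc, cfg, DESK_SHAPE, seed=seed)
        rng = np.random.default_rng(seed + 99)
        losses[name] = run_training_steps(model, images, labels, comat.upper,
                                          comat.lower, cfg, rng, steps)
    return losses["transfer"], losses["random"]


def gradcam_localization(fa, seed: int = 0, n_cases: int = 5,
                         dilate_px: int = 16, out_shape=DESK_SHAPE):
    """Grad-CAM argmax vs the dilated lesion box on single-lesion cases.

    Generates cases with exactly one unmistakable lesion (low independent
    prevalence, large severity guaranteed by rejection sampling on lesion
    area) and counts how often the heatmap argmax for the affected tooth
    falls inside the lesion's bounding box dilated by ``dilate_px``.
    Returns (hits, tried).

    The heatmap is computed on a feature map downsampled by 2**depth
    (8 px cells at the desk scale), so localization finer than one cell is
    not expressible; the default dilation is two feature-map strides.
    """
    syn = desk_synthetic_config(seed)
    syn.lesion_prevalence = 0.04
    syn.adjacency_coupling = 0.0
    rng = np.random.default_rng(seed + 4000)
    hits, tried = 0, 0
    while tried < n_cases:
        case = generate_case(syn, rng)
        if case.true_tooth_labels.sum() != 1:
            continue
        crop = extract_roi(case.image, case.roi_mask, out_shape)
        lesion = crop_companion_mask(crop, case.true_lesion_mask)
        if lesion.sum() < 10:  # not an obvious lesion at this resolution
            continue
        j = int(case.true_tooth_labels.argmax())
        cam = gradcam(fa, crop, j)
        rows, cols = np.nonzero(lesion)
        r0 = max(0, rows.min() - dilate_px)
        r1 = min(lesion.shape[0], rows.max() + dilate_px + 1)
        c0 = max(0, cols.min() - dilate_px)
        c1 = min(lesion.shape[1], cols.max() + dilate_px + 1)
        r, c = np.unravel_index(np.argmax(cam), cam.shape)
        hits += int(r0 <= r < r1 and c0 <= c < c1)
        tried += 1
    return hits, tried


def operating_point_summary(scores, labels, votes, mode: str = "balanced"):
    """Clinician stats plus the model's metrics at a selected threshold."""
    clinicians = clinician_performance(votes.transpose(1, 0, 2))
    stats = [c.as_dict() for c in clinicians]
    op = select_operating_point(scores, labels, mode,
                                clinician_stats=stats)
    report = confusion_metrics(scores, labels, op.threshold)
    report.auroc = auroc(scores, labels)
    return op, report, clinicians
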