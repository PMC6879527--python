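"""Synthetic panoramic-style radiographs with full ground truth.

Clinical panoramic radiographs cannot be redistributed, so every stage of
the pipeline is exercised on generated images that reproduce the structural
properties the pipeline depends on, without claiming anatomical realism:

* an arch-shaped teeth band inside a larger noisy background whose field of
  view varies from case to case (random collimation margins, intensity
  jitter);
* 32 bright tooth-like shapes laid out in the FDI quadrant convention
  (patient right, i.e. quadrants 1 and 4, on the image's left half);
* focal dark wedge lesions at the necks of affected teeth, with per-tooth
  labels drawn from an autologistic chain along each jaw so that lesions
  co-occur on horizontally adjacent teeth (the chain is damped at the
  third molars, which co-occur weakly with their neighbours);
* L imperfect annotators: tooth labels flipped at a configurable rate and
  lesion masks perturbed by omission, jitter, dilation/erosion and spurious
  additions.

All randomness flows through an explicit ``numpy.random.Generator``; a
fixed seed reproduces a case or a dataset bit for bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.draw import polygon as draw_polygon

from .labels import N_TEETH, aggregate_tooth_labels

__all__ = [
    "SyntheticConfig",
    "SyntheticCase",
    "sample_labels",
    "generate_case",
    "simulate_annotators",
    "generate_dataset",
    "load_dataset",
]


@dataclass
class SyntheticConfig:
    """Generation parameters; defaults are the package's study conditions."""

    image_shape: tuple = (128, 256)
    n_annotators: int = 5
    lesion_prevalence: float = 0.25
    adjacency_coupling: float = 1.0       # log-odds boost from a positive neighbour
    end_damping: float = 0.3              # coupling multiplier at third molars
    annotator_flip_rate: float = 0.1      # per-tooth label flip probability
    mask_jitter_px: int = 1               # max |shift| and dilation/erosion radius
    mask_omit_rate: float = 0.1           # chance an annotator misses a lesion
    mask_spurious_rate: float = 0.05      # chance of one spurious blob
    background_margin_frac: float = 0.08  # max collimation margin per side
    noise_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for name in ("lesion_prevalence", "annotator_flip_rate",
                     "mask_omit_rate", "mask_spurious_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.adjacency_coupling < 0:
            raise ValueError("adjacency_coupling must be nonnegative")
        h, w = self.image_shape
        if h < 32 or w < 64:
            raise ValueError(
                f"image_shape {self.image_shape} too small to place 32 teeth")


@dataclass
class SyntheticCase:
    """One generated radiograph with complete ground truth."""

    image: np.ndarray
    roi_polygon: np.ndarray       # (V, 2) row/col vertices, TMJ-to-TMJ order
    roi_mask: np.ndarray
    true_tooth_labels: np.ndarray
    true_lesion_mask: np.ndarray
    annotator_masks: np.ndarray = field(default=None)
    annotator_labels: np.ndarray = field(default=None)
    tooth_centers: np.ndarray = field(default=None)


# --------------------------------------------------------------------------
# geometry

#: left-to-right chain order of vector indices per jaw (patient right first)
UPPER_CHAIN = np.array([7 - k if k < 8 else k for k in range(16)])
LOWER_CHAIN = np.array([31 - k if k < 8 else k + 8 for k in range(16)])


def _layout(shape):
    """Tooth centers, sizes and the arch-band geometry for an image shape."""
    h, w = shape
    margin = 0.07 * w
    usable = w - 2 * margin
    xs = margin + (np.arange(16) + 0.5) * usable / 16
    t = (xs - w / 2) / (w / 2 - margin)          # arch parameter in [-1, 1]
    gap = 0.55 * h - 0.10 * h * t ** 2           # occlusal "smile" curve
    tooth_h = 0.16 * h
    tooth_w = 0.8 * usable / 16
    centers = np.zeros((N_TEETH, 2))
    sep = 0.012 * h
    for k in range(16):
        centers[UPPER_CHAIN[k]] = (gap[k] - sep - tooth_h / 2, xs[k])
        centers[LOWER_CHAIN[k]] = (gap[k] + sep + tooth_h / 2, xs[k])
    band_half = 0.24 * h
    return centers, tooth_h, tooth_w, xs, gap, band_half


def _band_mask(shape):
    h, w = shape
    _, _, _, xs, gap, band_half = _layout(shape)
    cols = np.arange(w)
    t = np.clip((cols - w / 2) / (w / 2 - 0.07 * w), -1.0, 1.0)
    gap_c = 0.55 * h - 0.10 * h * t ** 2
    rows = np.arange(h)[:, None]
    inside_cols = (cols >= 0.05 * w) & (cols <= 0.95 * w)
    mask = (np.abs(rows - gap_c[None, :]) <= band_half) & inside_cols[None, :]
    return mask.astype(np.uint8)


def _band_polygon(mask):
    """Boundary vertices ordered right TMJ -> mandible -> left TMJ ring."""
    cols = np.flatnonzero(mask.any(axis=0))
    step = max(1, len(cols) // 40)
    sampled = cols[::step]
    if sampled[-1] != cols[-1]:
        sampled = np.append(sampled, cols[-1])
    tops = np.array([mask[:, c].argmax() for c in sampled])
    bottoms = np.array([mask.shape[0] - 1 - mask[::-1, c].argmax()
                        for c in sampled])
    down_left = [(tops[0], sampled[0]), (bottoms[0], sampled[0])]
    bottom_edge = list(zip(bottoms[1:], sampled[1:]))
    up_right = [(tops[-1], sampled[-1])]
    top_edge = list(zip(tops[-2:0:-1], sampled[-2:0:-1]))
    return np.array(down_left + bottom_edge + up_right + top_edge)


def sample_labels(config: SyntheticConfig, rng, n: int = 1) -> np.ndarray:
    """Draw n 32-length label vectors from the autologistic arch chains.

    Within each jaw, teeth are visited left to right; the conditional
    log-odds of a lesion are the base log-odds of ``lesion_prevalence``
    shifted by ``+/- adjacency_coupling`` depending on the previous tooth's
    state (damped by ``end_damping`` at steps touching a third molar).
    With zero coupling all teeth are independent Bernoulli draws.
    """
    base_logit = np.log(config.lesion_prevalence
                        / (1 - config.lesion_prevalence)) \
        if 0 < config.lesion_prevalence < 1 else None
    out = np.zeros((n, N_TEETH), dtype=np.int64)
    if config.lesion_prevalence in (0.0, 1.0):
        out[:] = int(config.lesion_prevalence)
        return out
    for chain in (UPPER_CHAIN, LOWER_CHAIN):
        prev = (rng.random(n) < config.lesion_prevalence).astype(float)
        out[:, chain[0]] = prev
        for k in range(1, 16):
            c = config.adjacency_coupling
            if k == 1 or k == 15:  # step touches a third molar
                c *= config.end_damping
            p = 1.0 / (1.0 + np.exp(-(base_logit + c * (2 * prev - 1))))
            cur = (rng.random(n) < p).astype(float)
            out[:, chain[k]] = cur
            prev = cur
    return out


def _render_lesion(image, lesion_mask, center, tooth_h, tooth_w, upper,
                   severity, side, rng):
    """Darken a wedge at the tooth neck; returns nothing, edits in place."""
    h, w = image.shape
    neck_row = center[0] + (tooth_h / 2 if upper else -tooth_h / 2)
    apex_dir = 1.0 if upper else -1.0      # wedge opens toward the gap
    wd = tooth_w * (0.6 + 0.6 * severity)
    ht = tooth_h * (0.45 + 0.5 * severity)
    cx = center[1] + side * tooth_w * 0.45
    rr = [neck_row - apex_dir * ht * 0.35,
          neck_row - apex_dir * ht * 0.35,
          neck_row + apex_dir * ht * 0.65]
    cc = [cx - wd / 2, cx + wd / 2, cx]
    rows, cols = draw_polygon(np.clip(rr, 0, h - 1), np.clip(cc, 0, w - 1),
                              shape=image.shape)
    image[rows, cols] -= 0.45 * (0.6 + 0.4 * severity)
    lesion_mask[rows, cols] = 1


def generate_case(config: SyntheticConfig, rng) -> SyntheticCase:
    """Render one synthetic radiograph with its complete ground truth."""
    h, w = config.image_shape
    centers, tooth_h, tooth_w, xs, gap, _ = _layout(config.image_shape)

    image = 0.22 + 0.08 * ndimage.gaussian_filter(
        rng.standard_normal((h, w)), sigma=max(2, h // 16))
    image += config.noise_sigma * rng.standard_normal((h, w))

    band = _band_mask(config.image_shape)
    image[band > 0] += 0.12  # bone is brighter than soft tissue

    labels = sample_labels(config, rng, n=1)[0]
    lesion_mask = np.zeros((h, w), dtype=np.uint8)

    rows_g, cols_g = np.mgrid[0:h, 0:w]
    for j in range(N_TEETH):
        cr, cc = centers[j]
        ell = (((rows_g - cr) / (tooth_h / 2)) ** 2
               + ((cols_g - cc) / (tooth_w / 2)) ** 2) <= 1.0
        image[ell] = 0.72 + 0.06 * rng.random()

    for j in range(N_TEETH):
        if labels[j]:
            upper = j < 16
            severity = rng.uniform(0.4, 1.0)
            side = rng.choice([-1.0, 1.0])
            _render_lesion(image, lesion_mask, centers[j], tooth_h, tooth_w,
                           upper, severity, side, rng)

    # variable field of view: random collimation margins per side
    mf = config.background_margin_frac
    top, bottom = rng.integers(0, max(1, int(mf * h)), size=2)
    left, right = rng.integers(0, max(1, int(mf * w)), size=2)
    if top:
        image[:top] = 0.02
    if bottom:
        image[h - bottom:] = 0.02
    if left:
        image[:, :left] = 0.02
    if right:
        image[:, w - right:] = 0.02
    image = np.clip(image * rng.uniform(0.9, 1.1), 0.0, 1.0)

    case = SyntheticCase(
        image=image,
        roi_polygon=_band_polygon(band),
        roi_mask=band,
        true_tooth_labels=labels,
        true_lesion_mask=lesion_mask,
        tooth_centers=centers,
    )
    masks, votes = simulate_annotators(case, config, rng)
    case.annotator_masks = masks
    case.annotator_labels = votes
    return case


def simulate_annotators(case: SyntheticCase, config: SyntheticConfig, rng):
    """Imperfect annotator masks and labels for one case's ground truth.

    Labels are the truth flipped independently per (annotator, tooth) at
    ``annotator_flip_rate``; masks are the true lesion components, each
    possibly omitted, shifted, dilated or eroded, plus occasional spurious
    blobs.  Flip rates of 0.5 or more void the majority-vote recovery
    guarantee and are rejected.
    """
    if config.annotator_flip_rate >= 0.5:
        raise ValueError(
            "annotator_flip_rate must be < 0.5 for aggregation to recover "
            "the truth")
    n_a = config.n_annotators
    truth = case.true_tooth_labels
    flips = rng.random((n_a, N_TEETH)) < config.annotator_flip_rate
    votes = np.where(flips, 1 - truth, truth).astype(np.int64)

    comp_labels, n_comp = ndimage.label(case.true_lesion_mask)
    masks = np.zeros((n_a,) + case.true_lesion_mask.shape, dtype=np.uint8)
    j = config.mask_jitter_px
    band_pts = np.argwhere(case.roi_mask > 0)
    for a in range(n_a):
        m = np.zeros_like(case.true_lesion_mask)
        for comp in range(1, n_comp + 1):
            if rng.random() < config.mask_omit_rate:
                continue
            piece = (comp_labels == comp)
            if j > 0:
                shift = rng.integers(-j, j + 1, size=2)
                piece = np.roll(piece, shift, axis=(0, 1))
                morph = rng.integers(-j, j + 1)
                if morph > 0:
                    piece = ndimage.binary_dilation(piece, iterations=morph)
                elif morph < 0:
                    piece = ndimage.binary_erosion(piece, iterations=-morph)
            m |= piece.astype(np.uint8)
        if config.mask_spurious_rate > 0 and \
                rng.random() < config.mask_spurious_rate and len(band_pts):
            cr, cc = band_pts[rng.integers(len(band_pts))]
            rad = int(rng.integers(1, 3))
            rr, cc_g = np.ogrid[:m.shape[0], :m.shape[1]]
            m |= ((rr - cr) ** 2 + (cc_g - cc) ** 2 <= rad ** 2).astype(np.uint8)
        masks[a] = m
    return masks, votes


# --------------------------------------------------------------------------
# on-disk datasets


def _write_png(path, array):
    import imageio.v3 as iio
    if array.dtype != np.uint8:
        array = np.clip(np.asarray(array, dtype=float), 0, 1)
        array = (array * 255).round().astype(np.uint8)
    iio.imwrite(path, array)


def _split_indices(n, rng):
    order = rng.permutation(n)
    n_val = max(1, int(round(0.15 * n))) if n >= 3 else 0
    n_test = n_val
    test = order[:n_test]
    val = order[n_test:n_test + n_val]
    train = order[n_test + n_val:]
    return {"train": sorted(int(i) for i in train),
            "val": sorted(int(i) for i in val),
            "test": sorted(int(i) for i in test)}


def generate_dataset(n: int, config: SyntheticConfig, seed: int,
                     out_dir) -> Path:
    """Write n synthetic cases to disk in the package's exchange formats.

    Layout: ``images/{id}.png``, ``roi_masks/{id}.png``,
    ``lesion_masks/{id}_{annotator}.png`` (annotator masks, nonzero =
    lesion), ``lesion_truth/{id}.png``, ``labels.csv`` with columns
    image_id, annotator_id, fdi_tooth, label, and ``manifest.json``
    recording the config, the train/val/test split and file checksums.
    Deterministic per seed.
    """
    import pandas as pd
    from .labels import index_to_fdi

    if n < 1:
        raise ValueError("n must be at least 1")
    out_dir = Path(out_dir)
    rng = np.random.default_rng(seed)
    for sub in ("images", "roi_masks", "lesion_masks", "lesion_truth"):
        (out_dir / sub).mkdir(parents=True, exist_ok=True)

    rows = []
    ids = []
    for i in range(n):
        case = generate_case(config, rng)
        image_id = f"case{i:04d}"
        ids.append(image_id)
        _write_png(out_dir / "images" / f"{image_id}.png", case.image)
        _write_png(out_dir / "roi_masks" / f"{image_id}.png",
                   case.roi_mask * 255)
        _write_png(out_dir / "lesion_truth" / f"{image_id}.png",
                   case.true_lesion_mask * 255)
        for a in range(config.n_annotators):
            _write_png(out_dir / "lesion_masks" / f"{image_id}_{a}.png",
                       case.annotator_masks[a] * 255)
            for j in range(N_TEETH):
                rows.append({"image_id": image_id, "annotator_id": a,
                             "fdi_tooth": index_to_fdi(j).code,
                             "label": int(case.annotator_labels[a, j])})
    pd.DataFrame(rows).to_csv(out_dir / "labels.csv", index=False)

    split = _split_indices(n, np.random.default_rng(seed + 1))
    checksums = {}
    for path in sorted(out_dir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            checksums[str(path.relative_to(out_dir))] = hashlib.sha256(
                path.read_bytes()).hexdigest()
    manifest = {
        "n": n,
        "seed": seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "image_ids": ids,
        "split": {k: [ids[i] for i in v] for k, v in split.items()},
        "checksums": checksums,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out_dir


def load_dataset(dataset_dir):
    """Read a generated dataset back into memory.

    Returns (cases, manifest) where each case is a dict with the image,
    ROI mask, true lesion mask, per-annotator masks and the (L, 32) vote
    matrix in the fixed FDI index order.
    """
    import imageio.v3 as iio
    from .dataio import read_labels_csv

    dataset_dir = Path(dataset_dir)
    with open(dataset_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    votes_by_id = read_labels_csv(dataset_dir / "labels.csv")
    n_annot = manifest["config"]["n_annotators"]
    cases = []
    for image_id in manifest["image_ids"]:
        image = iio.imread(dataset_dir / "images" / f"{image_id}.png") / 255.0
        roi = (iio.imread(dataset_dir / "roi_masks" / f"{image_id}.png")
               > 127).astype(np.uint8)
        lesion = (iio.imread(dataset_dir / "lesion_truth" / f"{image_id}.png")
                  > 127).astype(np.uint8)
        masks = np.stack([
            (iio.imread(dataset_dir / "lesion_masks" / f"{image_id}_{a}.png")
             > 127).astype(np.uint8)
            for a in range(n_annot)])
        cases.append({
            "image_id": image_id,
            "image": image,
            "roi_mask": roi,
            "true_lesion_mask": lesion,
            "annotator_masks": masks,
            "annotator_labels": votes_by_id[image_id],
            "tooth_labels": aggregate_tooth_labels(votes_by_id[image_id], 3),
        })
    return cases, manifest
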