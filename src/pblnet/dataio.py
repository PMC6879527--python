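"""Readers and writers for the package's exchange formats.

Tooth labels travel as CSV with columns ``image_id, annotator_id,
fdi_tooth, label`` (two-digit FDI code, label in {0, 1}); masks are 8-bit
PNGs with nonzero = lesion, named ``{image_id}_{annotator_id}.png``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .labels import N_TEETH, fdi_to_index, index_to_fdi

LABEL_COLUMNS = ["image_id", "annotator_id", "fdi_tooth", "label"]


def write_labels_csv(path, votes_by_id):
    """Write {image_id: (L, 32) vote matrix} to the CSV label schema."""
    rows = []
    for image_id, votes in votes_by_id.items():
        votes = np.asarray(votes)
        for a in range(votes.shape[0]):
            for j in range(N_TEETH):
                rows.append({"image_id": image_id, "annotator_id": a,
                             "fdi_tooth": index_to_fdi(j).code,
                             "label": int(votes[a, j])})
    pd.DataFrame(rows, columns=LABEL_COLUMNS).to_csv(path, index=False)


def read_labels_csv(path):
    """Read the label CSV into {image_id: (L, 32) int array}.

    Annotators are ordered by their sorted ids; missing (annotator, tooth)
    entries default to 0.
    """
    df = pd.read_csv(path, dtype={"image_id": str})
    missing = set(LABEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"label CSV missing columns: {sorted(missing)}")
    if not df["label"].isin([0, 1]).all():
        raise ValueError("labels must be 0 or 1")
    out = {}
    for image_id, group in df.groupby("image_id", sort=True):
        annotators = sorted(group["annotator_id"].unique())
        votes = np.zeros((len(annotators), N_TEETH), dtype=np.int64)
        a_index = {a: i for i, a in enumerate(annotators)}
        for _, row in group.iterrows():
            j = fdi_to_index(int(row["fdi_tooth"]))
            votes[a_index[row["annotator_id"]], j] = int(row["label"])
        out[str(image_id)] = votes
    return out


def read_mask(path) -> np.ndarray:
    import imageio.v3 as iio
    return (iio.imread(Path(path)) > 0).astype(np.uint8)


def write_mask(path, mask):
    import imageio.v3 as iio
    iio.imwrite(Path(path), ((np.asarray(mask) > 0) * 255).astype(np.uint8))


def read_image(path) -> np.ndarray:
    import imageio.v3 as iio
    arr = iio.imread(Path(path)).astype(np.float64)
    if arr.max() > 1.0:
        arr /= 255.0
    return arr
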