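"""FDI tooth numbering, multi-annotator aggregation, and co-occurrence.

Teeth are indexed by the FDI (ISO-3950) two-digit code: the first digit is
the quadrant (1 upper-right, 2 upper-left, 3 lower-left, 4 lower-right, all
from the patient's point of view) and the second the position 1-8 counted
from the midline.  The package uses one fixed bijection between the 32 FDI
codes and vector indices 0-31:

    quadrant 1 -> indices 0-7   (positions 1..8)
    quadrant 2 -> indices 8-15
    quadrant 3 -> indices 16-23
    quadrant 4 -> indices 24-31

so indices 0-15 are maxillary (upper jaw) and 16-31 mandibular (lower jaw).
Positions 1-2 are incisors, 3 canines, 4-5 premolars and 6-8 molars, giving
8 incisors, 4 canines, 8 premolars and 12 molars in a full dentition.

Tooth-level annotations from L annotators are combined by vote thresholding:
a tooth is positive when at least ``c_r`` annotators marked it (``c_r = 3``
of 5 is majority voting).  Pixel-level lesion masks are combined the same
way with threshold ``c_s``; ``c_s = 1`` is the union of the annotators'
masks and ``c_s = L`` their intersection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_TEETH = 32
N_PER_JAW = 16
QUADRANTS = (1, 2, 3, 4)
POSITIONS = tuple(range(1, 9))

#: tooth type by within-quadrant position
POSITION_TYPE = {1: "incisor", 2: "incisor", 3: "canine",
                 4: "premolar", 5: "premolar",
                 6: "molar", 7: "molar", 8: "molar"}

#: FDI quadrants that appear on the LEFT half of a panoramic image
#: (patient's right side; standard radiographic orientation).
LEFT_HALF_QUADRANTS = (1, 4)


@dataclass(frozen=True)
class FDIToothId:
    """One tooth in FDI notation."""

    quadrant: int
    position: int

    def __post_init__(self):
        if self.quadrant not in QUADRANTS:
            raise ValueError(
                f"invalid FDI quadrant {self.quadrant!r}: must be 1, 2, 3 or 4")
        if self.position not in POSITIONS:
            raise ValueError(
                f"invalid FDI position {self.position!r}: must be in 1..8")

    @classmethod
    def from_code(cls, code) -> "FDIToothId":
        """Parse a two-digit FDI code such as 36 or "36"."""
        code = int(code)
        return cls(code // 10, code % 10)

    @property
    def code(self) -> int:
        return 10 * self.quadrant + self.position

    @property
    def tooth_type(self) -> str:
        return POSITION_TYPE[self.position]

    @property
    def is_upper(self) -> bool:
        return self.quadrant in (1, 2)


def fdi_to_index(tooth: FDIToothId) -> int:
    """Map an FDI tooth id to its fixed vector index in [0, 31]."""
    if not isinstance(tooth, FDIToothId):
        tooth = FDIToothId(*tooth) if isinstance(tooth, tuple) \
            else FDIToothId.from_code(tooth)
    return (tooth.quadrant - 1) * 8 + (tooth.position - 1)


def index_to_fdi(index: int) -> FDIToothId:
    if not 0 <= index < N_TEETH:
        raise ValueError(f"tooth index {index} outside [0, 31]")
    return FDIToothId(index // 8 + 1, index % 8 + 1)


ALL_TEETH = tuple(index_to_fdi(i) for i in range(N_TEETH))

#: tooth type of each vector index
INDEX_TYPE = tuple(t.tooth_type for t in ALL_TEETH)

TYPE_INDICES = {
    kind: np.array([i for i, t in enumerate(INDEX_TYPE) if t == kind])
    for kind in ("incisor", "canine", "premolar", "molar")
}

UPPER_INDICES = np.arange(0, N_PER_JAW)
LOWER_INDICES = np.arange(N_PER_JAW, N_TEETH)
PREMOLAR_MOLAR_INDICES = np.sort(
    np.concatenate([TYPE_INDICES["premolar"], TYPE_INDICES["molar"]]))
INCISOR_CANINE_INDICES = np.sort(
    np.concatenate([TYPE_INDICES["incisor"], TYPE_INDICES["canine"]]))

LEFT_HALF_INDICES = np.array(
    [i for i, t in enumerate(ALL_TEETH) if t.quadrant in LEFT_HALF_QUADRANTS])
RIGHT_HALF_INDICES = np.array(
    [i for i, t in enumerate(ALL_TEETH) if t.quadrant not in LEFT_HALF_QUADRANTS])


@dataclass
class AnnotationSet:
    """Per-annotator lesion masks and tooth labels for one radiograph."""

    masks: np.ndarray          # (L, H, W) binary
    tooth_votes: np.ndarray    # (L, 32) binary
    image_id: str = ""

    def __post_init__(self):
        self.masks = np.asarray(self.masks)
        self.tooth_votes = np.asarray(self.tooth_votes)
        if self.masks.ndim != 3:
            raise ValueError("masks must be a (L, H, W) stack")
        if self.tooth_votes.shape != (self.masks.shape[0], N_TEETH):
            raise ValueError("tooth_votes must be (L, 32) aligned with masks")

    @property
    def n_annotators(self) -> int:
        return self.masks.shape[0]


@dataclass
class CooccurrenceMatrix:
    """Joint-occurrence frequency of positive labels, one matrix per jaw.

    Entry (j, j') is the fraction of cases in which teeth j and j' of the
    same jaw are both positive; the diagonal is the per-tooth prevalence.
    """

    upper: np.ndarray = field(default_factory=lambda: np.zeros((16, 16)))
    lower: np.ndarray = field(default_factory=lambda: np.zeros((16, 16)))

    def __post_init__(self):
        self.upper = np.asarray(self.upper, dtype=float)
        self.lower = np.asarray(self.lower, dtype=float)
        for name, m in (("upper", self.upper), ("lower", self.lower)):
            if m.shape != (N_PER_JAW, N_PER_JAW):
                raise ValueError(f"{name} matrix must be 16x16, got {m.shape}")


def _check_binary(arr, what):
    arr = np.asarray(arr)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{what} must be binary (0/1)")
    return arr.astype(np.int64)


def aggregate_tooth_labels(votes, c_r: int = 3) -> np.ndarray:
    """Combine per-annotator tooth labels by vote thresholding.

    Tooth j is positive when at least ``c_r`` of the L annotators voted
    positive; ``c_r = 3`` of L = 5 is majority voting.
    """
    votes = _check_binary(votes, "votes")
    if votes.ndim != 2:
        raise ValueError("votes must be (L, T)")
    n_annot = votes.shape[0]
    if not 1 <= c_r <= n_annot:
        raise ValueError(f"c_r must be in [1, {n_annot}], got {c_r}")
    return (votes.sum(axis=0) >= c_r).astype(np.int64)


def aggregate_lesion_mask(masks, c_s: int = 1) -> np.ndarray:
    """Combine per-annotator lesion masks by per-pixel vote thresholding.

    ``c_s = 1`` keeps every pixel any annotator marked (mask union), which
    favours recall when the combined mask supervises lesion segmentation.
    """
    masks = np.asarray(masks)
    if masks.ndim != 3:
        raise ValueError("masks must be a (L, H, W) stack of equal shapes")
    masks = _check_binary(masks, "masks")
    n_annot = masks.shape[0]
    if not 1 <= c_s <= n_annot:
        raise ValueError(f"c_s must be in [1, {n_annot}], got {c_s}")
    return (masks.sum(axis=0) >= c_s).astype(np.int64)


def build_cooccurrence(labels) -> CooccurrenceMatrix:
    """Joint-occurrence frequency matrices from N 32-length label vectors.

    For each jaw, C[j, j'] = #{cases with both j and j' positive} / N.
    """
    labels = _check_binary(labels, "labels")
    if labels.ndim != 2 or labels.shape[1] != N_TEETH:
        raise ValueError("labels must be (N, 32)")
    n = labels.shape[0]
    if n == 0:
        raise ValueError("cannot build a co-occurrence matrix from 0 cases")
    upper = labels[:, UPPER_INDICES].astype(float)
    lower = labels[:, LOWER_INDICES].astype(float)
    return CooccurrenceMatrix(upper=upper.T @ upper / n,
                              lower=lower.T @ lower / n)


def cooccurrence_target(y, matrix) -> np.ndarray:
    """Soft per-tooth target induced by the co-occurrence structure.

    c_j is the co-occurrence-weighted sum of the positive labels,
    max-normalized so all entries lie in [0, 1] with max exactly 1.  An
    all-negative label vector maps to the all-zero target (a lesion-free
    mouth predicts no lesions anywhere).
    """
    y = _check_binary(y, "labels")
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("matrix must be square")
    if y.shape != (matrix.shape[0],):
        raise ValueError(
            f"label vector length {y.shape} does not match matrix "
            f"{matrix.shape}")
    if (matrix < 0).any():
        raise ValueError("co-occurrence matrix entries must be nonnegative")
    raw = matrix @ y
    z = raw.max()
    if z <= 0:
        return np.zeros_like(raw)
    return raw / z


def mask_labels_premolar_molar(y) -> np.ndarray:
    """Zero the incisor and canine entries of a 32-length label vector."""
    y = np.array(y)
    if y.shape[-1] != N_TEETH:
        raise ValueError("expected a length-32 label vector")
    out = y.copy()
    out[..., INCISOR_CANINE_INDICES] = 0
    return out
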