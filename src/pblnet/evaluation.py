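"""Tooth-level metrics, operating-point selection and per-type reports.

All headline metrics are micro-averaged: every (image, tooth) decision is
pooled into one confusion table before computing sensitivity, specificity,
PPV, NPV and F1.  Ratios with a zero denominator are reported as ``None``
(absent) rather than coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from .labels import TYPE_INDICES, aggregate_tooth_labels

__all__ = [
    "MetricsReport",
    "OperatingPoint",
    "confusion_metrics",
    "auroc",
    "select_operating_point",
    "clinician_performance",
    "per_tooth_type_report",
]


@dataclass
class MetricsReport:
    """Confusion counts and derived metrics; undefined ratios are None."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float | None = None
    specificity: float | None = None
    ppv: float | None = None
    npv: float | None = None
    f1: float | None = None
    auroc: float | None = None

    @classmethod
    def from_counts(cls, tp, fp, tn, fn, auroc_value=None):
        def ratio(num, den):
            return num / den if den > 0 else None

        sens = ratio(tp, tp + fn)
        spec = ratio(tn, tn + fp)
        ppv = ratio(tp, tp + fp)
        npv = ratio(tn, tn + fn)
        if sens is not None and ppv is not None:
            f1 = 0.0 if sens + ppv == 0 else 2 * ppv * sens / (ppv + sens)
        else:
            f1 = None
        return cls(tp=int(tp), fp=int(fp), tn=int(tn), fn=int(fn),
                   sensitivity=sens, specificity=spec, ppv=ppv, npv=npv,
                   f1=f1, auroc=auroc_value)

    def as_dict(self):
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "ppv": self.ppv, "npv": self.npv, "f1": self.f1,
            "auroc": self.auroc,
        }


@dataclass
class OperatingPoint:
    """A decision threshold plus the selection mode that produced it."""

    mode: str
    threshold: float
    reference: dict | None = None


def _check_labels(labels):
    labels = np.asarray(labels)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary (0/1)")
    return labels.astype(int)


def confusion_metrics(scores, labels, threshold: float) -> MetricsReport:
    """Micro-pooled confusion metrics at decision rule score >= threshold."""
    scores = np.asarray(scores, dtype=float).ravel()
    labels = _check_labels(labels).ravel()
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    pred = scores >= threshold
    pos = labels == 1
    tp = int(np.sum(pred & pos))
    fp = int(np.sum(pred & ~pos))
    fn = int(np.sum(~pred & pos))
    tn = int(np.sum(~pred & ~pos))
    return MetricsReport.from_counts(tp, fp, tn, fn)


def auroc(scores, labels) -> float:
    """Area under the ROC curve over the pooled decisions.

    Equals the Mann-Whitney probability that a random positive outscores a
    random negative, with ties counted as 1/2.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = _check_labels(labels).ravel()
    if labels.min() == labels.max():
        raise ValueError(
            "AUROC is undefined when only one class is present in the pool")
    return float(roc_auc_score(labels, scores))


def _sweep_grid(scores):
    return np.unique(np.concatenate([np.asarray(scores, float).ravel(),
                                     [0.0, 1.0]]))


def select_operating_point(val_scores, val_labels, mode: str,
                           clinician_stats=None) -> OperatingPoint:
    """Pick a decision threshold on validation data.

    ``balanced`` maximizes validation F1.  ``high_sensitivity`` picks the
    threshold whose validation specificity is nearest the worst (minimum)
    clinician specificity; ``high_specificity`` matches the worst clinician
    sensitivity instead.  The sweep grid is the set of observed scores plus
    {0, 1}; ties break toward the higher threshold.
    """
    scores = np.asarray(val_scores, dtype=float).ravel()
    labels = _check_labels(val_labels).ravel()
    if labels.min() == labels.max():
        raise ValueError("validation pool must contain both classes")
    grid = _sweep_grid(scores)
    reports = [confusion_metrics(scores, labels, t) for t in grid]

    if mode == "balanced":
        f1s = np.array([-np.inf if r.f1 is None else r.f1 for r in reports])
        best = np.flatnonzero(f1s == f1s.max())[-1]
        return OperatingPoint(mode=mode, threshold=float(grid[best]))

    if mode not in ("high_sensitivity", "high_specificity"):
        raise ValueError(f"unknown operating-point mode {mode!r}")
    if not clinician_stats:
        raise ValueError(f"mode {mode!r} requires clinician_stats")

    if mode == "high_sensitivity":
        ref = min(s["specificity"] if isinstance(s, dict) else s.specificity
                  for s in clinician_stats)
        values = np.array([np.inf if r.specificity is None else r.specificity
                           for r in reports])
        refname = "worst_clinician_specificity"
    else:
        ref = min(s["sensitivity"] if isinstance(s, dict) else s.sensitivity
                  for s in clinician_stats)
        values = np.array([np.inf if r.sensitivity is None else r.sensitivity
                           for r in reports])
        refname = "worst_clinician_sensitivity"
    gap = np.abs(values - ref)
    best = np.flatnonzero(gap == gap.min())[-1]
    return OperatingPoint(mode=mode, threshold=float(grid[best]),
                          reference={refname: float(ref)})


def clinician_performance(votes, reference=None, c_r: int = 3):
    """Per-annotator confusion metrics against the majority-vote reference.

    ``votes`` is (L, N, 32) or (L, n_decisions); the reference defaults to
    vote aggregation at threshold ``c_r`` over the same annotators.
    """
    votes = np.asarray(votes)
    if votes.ndim < 2:
        raise ValueError("votes must be (L, ...) with L annotators")
    flat = votes.reshape(votes.shape[0], -1)
    if reference is None:
        reference = aggregate_tooth_labels(flat, c_r)
    else:
        reference = _check_labels(reference).ravel()
        if reference.shape != flat.shape[1:]:
            raise ValueError("reference does not align with the votes")
    return [confusion_metrics(flat[l].astype(float), reference, 0.5)
            for l in range(flat.shape[0])]


def per_tooth_type_report(scores, labels, threshold: float):
    """Metrics pooled within each tooth-type subset plus the full pool.

    ``scores`` and ``labels`` are (N, 32) with the fixed FDI index order;
    subsets hold 8 incisors, 4 canines, 8 premolars and 12 molars per
    image.  AUROC is included where both classes are present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_labels(labels)
    if scores.ndim != 2 or scores.shape[1] != 32:
        raise ValueError("scores must be (N, 32)")
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    report = {}
    subsets = dict(TYPE_INDICES)
    subsets["all"] = np.arange(32)
    for kind, idx in subsets.items():
        s, y = scores[:, idx], labels[:, idx]
        rep = confusion_metrics(s, y, threshold)
        if y.min() != y.max():
            rep.auroc = auroc(s, y)
        report[kind] = rep
    return report
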