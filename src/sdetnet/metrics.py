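"""Evaluation metrics for both pipeline stages.

Segmentation: per-volume precision, recall, Jaccard index and F1 from
voxel-wise counts, aggregated as cohort mean +/- SD.  Classification:
accuracy, sensitivity, specificity, Brier score, ROC AUC, and the polygon
area metric (PAM) — the area of the hexagon whose radii are ACC, SEN, SPE,
AUC, JI and F-measure placed on the axes of a regular hexagon, normalized
by the unit hexagon's area 3*sqrt(3)/2 = 2.59807... so that a perfect
classifier scores 1.  Female = 0 = negative, male = 1 = positive, and a
probability >= 0.5 is called male.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .core import BinaryMask

#: area of the regular hexagon with unit radii: 6 * (1/2) * sin(60 deg)
PAM_NORMALIZER = 2.59807


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class SegScores:
    ji: float
    f1: float
    pr: float
    rc: float
    degenerate: bool = False  # empty gt and empty prediction


@dataclass
class ClassificationReport:
    acc: float
    sen: float
    spe: float
    auc: float
    br: float
    ji: float
    fm: float
    pam: float
    counts: ConfusionCounts

    def as_dict(self) -> dict[str, float]:
        return {"ACC": self.acc, "SEN": self.sen, "SPE": self.spe,
                "AUC": self.auc, "BR": self.br, "JI": self.ji,
                "FM": self.fm, "PAM": self.pam}


def seg_metrics(gt: BinaryMask | np.ndarray, pred: BinaryMask | np.ndarray
                ) -> SegScores:
    """Voxel-wise JI, F1, precision and recall for one volume.

    Empty ground truth with empty prediction counts as perfect (all 1,
    flagged); undefined ratios with a nonempty counterpart fall to 0.
    """
    g = (gt.data if isinstance(gt, BinaryMask) else np.asarray(gt)).astype(bool)
    p = (pred.data if isinstance(pred, BinaryMask) else np.asarray(pred)).astype(bool)
    if g.shape != p.shape:
        raise ValueError(f"shape mismatch: {g.shape} vs {p.shape}")
    tp = int((g & p).sum())
    fp = int((~g & p).sum())
    fn = int((g & ~p).sum())
    if tp + fp + fn == 0:
        return SegScores(1.0, 1.0, 1.0, 1.0, degenerate=True)
    pr = tp / (tp + fp) if tp + fp else 0.0
    rc = tp / (tp + fn) if tp + fn else 0.0
    ji = tp / (tp + fp + fn)
    f1 = 2 * pr * rc / (pr + rc) if pr + rc else 0.0
    return SegScores(ji, f1, pr, rc)


def segmentation_report(pairs: list[tuple[BinaryMask, BinaryMask]]) -> pd.DataFrame:
    """Per-volume scores plus a mean +/- SD summary row."""
    rows = [vars(seg_metrics(g, p)) for g, p in pairs]
    df = pd.DataFrame(rows)
    summary = df[["ji", "f1", "pr", "rc"]].agg(["mean", "std"])
    df.attrs["summary"] = summary
    return df


def confusion_from_probs(labels: np.ndarray, probs: np.ndarray,
                         threshold: float = 0.5) -> ConfusionCounts:
    """Confusion counts with male (1) positive and a >= threshold call."""
    labels = np.asarray(labels).ravel()
    probs = np.asarray(probs, dtype=float).ravel()
    if labels.shape != probs.shape:
        raise ValueError("labels and probabilities differ in length")
    if not np.all(np.isin(np.unique(labels), (0, 1))):
        raise ValueError("labels must be 0 (female) or 1 (male)")
    pred = probs >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int((pos & pred).sum()), tn=int((~pos & ~pred).sum()),
        fp=int((~pos & pred).sum()), fn=int((pos & ~pred).sum()))


def brier(labels: np.ndarray, probs: np.ndarray) -> float:
    """Mean squared difference between probabilities and outcomes."""
    labels = np.asarray(labels, dtype=float).ravel()
    probs = np.asarray(probs, dtype=float).ravel()
    if labels.size == 0:
        raise ValueError("empty input")
    if labels.shape != probs.shape:
        raise ValueError("labels and probabilities differ in length")
    return float(np.mean((labels - probs) ** 2))


def auc(labels: np.ndarray, probs: np.ndarray) -> float:
    """Trapezoidal ROC area (ties handled by midrank)."""
    labels = np.asarray(labels).ravel()
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(probs, dtype=float).ravel()))


def pam(acc: float, sen: float, spe: float, auc_: float, ji: float,
        fm: float) -> float:
    """Polygon area metric over the fixed vertex order (ACC,SEN,SPE,AUC,JI,FM).

    The six values are radii along the axes of a regular hexagon; adjacent
    pairs span triangles of area r_i * r_j * sin(60 deg) / 2 and the summed
    area is normalized by 2.59807 (the unit hexagon).  The vertex order is
    pinned because the area is not permutation-invariant.
    """
    r = np.array([acc, sen, spe, auc_, ji, fm], dtype=float)
    if r.min() < 0 or r.max() > 1:
        raise ValueError("all six metrics must lie in [0, 1]")
    pa = 0.5 * np.sin(np.pi / 3.0) * float(np.sum(r * np.roll(r, -1)))
    return pa / PAM_NORMALIZER


def evaluate_classifier(labels: np.ndarray, probs: np.ndarray,
                        threshold: float = 0.5) -> ClassificationReport:
    """Full classification report; JI and FM come from the confusion counts."""
    c = confusion_from_probs(labels, probs, threshold)
    acc = (c.tp + c.tn) / c.total
    sen = c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0
    spe = c.tn / (c.tn + c.fp) if c.tn + c.fp else 0.0
    a = auc(labels, probs)
    br = brier(labels, probs)
    ji = c.tp / (c.tp + c.fp + c.fn) if c.tp + c.fp + c.fn else 0.0
    fm = 2 * c.tp / (2 * c.tp + c.fp + c.fn) if 2 * c.tp + c.fp + c.fn else 0.0
    return ClassificationReport(acc, sen, spe, a, br, ji, fm,
                                pam(acc, sen, spe, a, ji, fm), c)


def classification_table(reports: dict[str, ClassificationReport]) -> pd.DataFrame:
    """One row per configuration, columns AUC/ACC/BR/SPE/SEN/PAM."""
    rows = []
    for name, r in reports.items():
        rows.append({"configuration": name, "AUC": r.auc, "ACC": r.acc,
                     "BR": r.br, "SPE": r.spe, "SEN": r.sen, "PAM": r.pam})
    return pd.DataFrame(rows)
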