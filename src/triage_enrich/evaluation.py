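"""Precision / recall / F1 scoring, confusion matrices and ED-vs-BD comparison.

Per-class one-versus-rest precision P = TP/(TP+FP), recall
R = TP/(TP+FN) and F1 = 2PR/(P+R) are computed from the confusion
matrix; "the" F1 of a 4-class model is the unweighted macro mean over
classes (micro and support-weighted means are reported alongside).
A class with P + R = 0 gets F1 = 0 by convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TRIAGE_CLASSES",
    "ConfusionMatrix",
    "ScoreReport",
    "confusion",
    "f1_from_confusion",
    "average_runs",
    "compare_conditions",
    "plot_confusion",
]

log = logging.getLogger(__name__)

#: 0 other / minimal intervention, 1 rehabilitation, 2 anesthesiology, 3 neurosurgery
TRIAGE_CLASSES: tuple[int, ...] = (0, 1, 2, 3)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts[i][j] = rows with annotated (true) class i predicted as class j."""

    counts: np.ndarray
    classes: tuple[int, ...] = TRIAGE_CLASSES

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (len(self.classes), len(self.classes)) or (c < 0).any():
            raise ValueError("confusion matrix must be square, non-negative, one row per class")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=[f"true_{c}" for c in self.classes],
            columns=[f"pred_{c}" for c in self.classes],
        )


def confusion(
    true: Sequence[int], pred: Sequence[int], classes: Sequence[int] = TRIAGE_CLASSES
) -> ConfusionMatrix:
    """Cross-tabulate annotated vs predicted labels."""
    true = np.asarray(true, dtype=int)
    pred = np.asarray(pred, dtype=int)
    if true.shape != pred.shape:
        raise ValueError(f"length mismatch: {len(true)} true vs {len(pred)} predicted")
    classes = tuple(classes)
    pos = {c: i for i, c in enumerate(classes)}
    unknown = (set(true.tolist()) | set(pred.tolist())) - set(classes)
    if unknown:
        raise ValueError(f"labels outside {classes}: {sorted(unknown)}")
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(true, pred):
        counts[pos[t], pos[p]] += 1
    return ConfusionMatrix(counts=counts, classes=classes)


@dataclass
class ScoreReport:
    """Per-class P/R/F1 plus macro, micro and weighted aggregates.

    ``run_f1s`` holds the macro F1 of each training run that went into
    this report and ``mean_f1`` their arithmetic mean; for a single-run
    report both reduce to ``macro_f1``.
    """

    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    macro_f1: float
    micro_f1: float
    weighted_f1: float
    classes: tuple[int, ...] = TRIAGE_CLASSES
    model: str = ""
    condition: str = ""
    run_f1s: list[float] = field(default_factory=list)

    @property
    def mean_f1(self) -> float:
        return float(np.mean(self.run_f1s)) if self.run_f1s else self.macro_f1


def _safe_div(a: float, b: float) -> float:
    return a / b if b > 0 else 0.0


def f1_from_confusion(
    cm: ConfusionMatrix, model: str = "", condition: str = ""
) -> ScoreReport:
    """Per-class one-vs-rest scores from a confusion matrix."""
    c = cm.counts.astype(float)
    tp = np.diag(c)
    fp = c.sum(axis=0) - tp
    fn = c.sum(axis=1) - tp
    precision = np.array([_safe_div(t, t + f) for t, f in zip(tp, fp)])
    recall = np.array([_safe_div(t, t + f) for t, f in zip(tp, fn)])
    f1 = np.array(
        [_safe_div(2 * p * r, p + r) for p, r in zip(precision, recall)]
    )
    zero = (tp + fp + fn) == 0
    if zero.any():
        log.warning(
            "classes %s have no true or predicted rows; F1=0 by convention",
            [cm.classes[i] for i in np.flatnonzero(zero)],
        )
    support = c.sum(axis=1)
    macro = float(f1.mean())
    micro_p = _safe_div(tp.sum(), c.sum())  # multiclass: micro P = R = accuracy
    weighted = float((f1 * support).sum() / support.sum()) if support.sum() else 0.0
    return ScoreReport(
        precision=precision,
        recall=recall,
        f1=f1,
        macro_f1=macro,
        micro_f1=float(micro_p),
        weighted_f1=weighted,
        classes=cm.classes,
        model=model,
        condition=condition,
        run_f1s=[macro],
    )


def average_runs(reports: Sequence[ScoreReport]) -> ScoreReport:
    """Average per-class scores over independent training runs.

    ``run_f1s`` collects each run's macro F1; the headline figure of a
    model/condition pair is their mean.
    """
    if not reports:
        raise ValueError("no reports to average")
    first = reports[0]
    if any(r.classes != first.classes for r in reports):
        raise ValueError("reports score different class sets")
    run_f1s = [r.macro_f1 for r in reports]
    return ScoreReport(
        precision=np.mean([r.precision for r in reports], axis=0),
        recall=np.mean([r.recall for r in reports], axis=0),
        f1=np.mean([r.f1 for r in reports], axis=0),
        macro_f1=float(np.mean(run_f1s)),
        micro_f1=float(np.mean([r.micro_f1 for r in reports])),
        weighted_f1=float(np.mean([r.weighted_f1 for r in reports])),
        classes=first.classes,
        model=first.model,
        condition=first.condition,
        run_f1s=run_f1s,
    )


def compare_conditions(
    ed_reports: Mapping[str, ScoreReport], bd_reports: Mapping[str, ScoreReport]
) -> pd.DataFrame:
    """Tabulate mean F1 per model for the enriched (ED) vs basic (BD) tables.

    The headline quantity is the per-model difference in percentage
    points of F1 x 100 (``diff_pp``); the frame's ``attrs['max_diff_pp']``
    holds the maximum over models.
    """
    if set(ed_reports) != set(bd_reports):
        raise ValueError(
            f"model lists differ: ED={sorted(ed_reports)} BD={sorted(bd_reports)}"
        )
    rows = []
    for model in ed_reports:
        ed, bd = ed_reports[model], bd_reports[model]
        rows.append(
            {
                "model": model,
                "mean_f1_ed": ed.mean_f1,
                "mean_f1_bd": bd.mean_f1,
                "diff_pp": 100.0 * (ed.mean_f1 - bd.mean_f1),
                "weighted_f1_ed": ed.weighted_f1,
                "weighted_f1_bd": bd.weighted_f1,
            }
        )
    df = pd.DataFrame(rows).sort_values("model").reset_index(drop=True)
    df.attrs["max_diff_pp"] = float(df["diff_pp"].max())
    return df


def plot_confusion(cm: ConfusionMatrix, title: str, path: str) -> None:
    """Write a heatmap image of one confusion matrix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3.5))
    im = ax.imshow(cm.counts, cmap="viridis")
    ax.set_xticks(range(len(cm.classes)), [str(c) for c in cm.classes])
    ax.set_yticks(range(len(cm.classes)), [str(c) for c in cm.classes])
    ax.set_xlabel("predicted")
    ax.set_ylabel("annotated")
    ax.set_title(title)
    for i in range(len(cm.classes)):
        for j in range(len(cm.classes)):
            ax.text(j, i, str(cm.counts[i, j]), ha="center", va="center", color="w")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
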