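"""Decision-outcome ROC curves: procalcitonin as the score, the prescribing
decision (full course vs not) as the reference label.

Unlike a conventional diagnostic ROC, the "positive" state here is a
*clinical decision*, so the AUC measures how strongly the lab value drives
prescribing, not how well it detects infection. Orientation is fixed —
higher PCT predicts a full course — and an AUC below 0.5 is reported as-is,
never auto-flipped.

Curve points come from the classic threshold sweep (predict full when
score >= threshold, ties grouped), AUC from the rank statistic (equal to
the normalized Mann-Whitney U with ties counted half). Pre-specified
cut-points are annotated with the exact (FPR, TPR) of the rule
``score >= cut-point``, and a chord-slope summary between adjacent
annotated cut-points quantifies the "visual inflection" read of the curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "RocCurve",
    "DEFAULT_ANNOTATED_CUTPOINTS",
    "roc_points",
    "annotate_cutpoints",
    "chord_slopes",
    "stratified_roc",
    "plot_curves",
]

#: Decision thresholds annotated on every curve (ng/mL).
DEFAULT_ANNOTATED_CUTPOINTS = (0.1, 0.25, 0.5, 1.0, 5.0)


@dataclass
class RocCurve:
    """One ROC curve with its annotations.

    ``thresholds`` descend from +inf to -inf (sentinels included);
    ``fpr``/``tpr`` trace the stepped curve from (0,0) to (1,1).
    ``annotations`` maps a cut-point to the (FPR, TPR) of ``score >= c``.
    """

    stratum: str
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_pos: int
    n_neg: int
    annotations: dict[float, tuple[float, float]] = field(default_factory=dict)
    _scores: np.ndarray | None = None
    _labels: np.ndarray | None = None

    def summary(self) -> dict:
        out = {
            "stratum": self.stratum,
            "auc": self.auc,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "annotations": {
                str(c): {"fpr": fp, "tpr": tp}
                for c, (fp, tp) in sorted(self.annotations.items())
            },
        }
        if len(self.annotations) >= 2:
            out["chord_slope_change"] = chord_slopes(self)
        return out

    def points_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )


def roc_points(scores, labels, stratum: str = "all") -> RocCurve:
    """Build the ROC curve for one set of scores and binary labels.

    Raises ``ValueError`` naming the missing class when labels are
    single-class (an ROC needs at least one positive and one negative).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0:
        raise ValueError("ROC undefined: no positive (full-course) labels")
    if n_neg == 0:
        raise ValueError("ROC undefined: no negative (not-full) labels")
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    # sklearn opens the sweep at +inf; close it with a -inf sentinel so the
    # threshold list spans the whole "score >= t" family.
    thr = np.append(thr.astype(float), -np.inf)
    thr[0] = np.inf
    fpr = np.append(fpr, 1.0)
    tpr = np.append(tpr, 1.0)
    auc = float(roc_auc_score(labels, scores))
    return RocCurve(
        stratum=stratum,
        thresholds=thr,
        fpr=fpr,
        tpr=tpr,
        auc=auc,
        n_pos=n_pos,
        n_neg=n_neg,
        _scores=scores,
        _labels=labels,
    )


def annotate_cutpoints(
    curve: RocCurve, cutpoints: Sequence[float] = DEFAULT_ANNOTATED_CUTPOINTS
) -> RocCurve:
    """Attach the operating point of ``score >= c`` for each cut-point.

    A cut-point below every observed score maps to (1,1); above every score,
    to (0,0) — the degenerate always/never-treat rules.
    """
    s, y = curve._scores, curve._labels
    if s is None or y is None:
        raise ValueError("curve carries no raw scores to annotate")
    for c in cutpoints:
        pred = s >= c
        tpr = float(pred[y].mean())
        fpr = float(pred[~y].mean())
        curve.annotations[float(c)] = (fpr, tpr)
    return curve


def chord_slopes(curve: RocCurve) -> dict:
    """Chord slopes of the ROC between adjacent annotated cut-points, and
    the slope change at each interior cut-point.

    An exploratory stand-in for reading inflections off the plotted curve: a
    large slope change at a cut-point is the numeric signature of a visible
    kink there. Slopes are d(TPR)/d(FPR) between the annotated operating
    points, ordered by descending cut-point (the curve runs (0,0) -> (1,1)
    as the threshold falls).
    """
    pts = sorted(curve.annotations.items(), key=lambda kv: -kv[0])
    slopes = {}
    prev = (0.0, 0.0)
    prev_c = np.inf
    seq = []
    for c, (fp, tp) in pts + [(-np.inf, (1.0, 1.0))]:
        dx, dy = fp - prev[0], tp - prev[1]
        slope = dy / dx if dx > 0 else np.inf
        seq.append(((prev_c, c), slope))
        prev, prev_c = (fp, tp), c
    for i in range(1, len(seq)):
        c = seq[i][0][0]
        s_in, s_out = seq[i - 1][1], seq[i][1]
        change = (
            s_out - s_in if np.isfinite(s_in) and np.isfinite(s_out) else np.nan
        )
        slopes[str(c)] = {
            "slope_above": s_in,
            "slope_below": s_out,
            "change": change,
        }
    return slopes


def stratified_roc(
    cohort: pd.DataFrame,
    by: str = "loc",
    score_col: str = "pct_value",
    label_col: str = "outcome_full",
    cutpoints: Sequence[float] = DEFAULT_ANNOTATED_CUTPOINTS,
) -> tuple[list[RocCurve], list[str]]:
    """Pooled curve plus one per stratum, each annotated.

    Strata lacking one of the classes are skipped and returned in the second
    element rather than raising.
    """
    curves: list[RocCurve] = []
    skipped: list[str] = []
    curves.append(
        annotate_cutpoints(
            roc_points(cohort[score_col], cohort[label_col], "all"), cutpoints
        )
    )
    for stratum, sub in cohort.groupby(by, sort=True):
        try:
            curves.append(
                annotate_cutpoints(
                    roc_points(sub[score_col], sub[label_col], str(stratum)),
                    cutpoints,
                )
            )
        except ValueError:
            skipped.append(str(stratum))
    return curves, skipped


def plot_curves(curves: Sequence[RocCurve], path) -> None:
    """Render curves with labelled cut-points to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    for curve in curves:
        ax.plot(curve.fpr, curve.tpr, label=f"{curve.stratum} (AUC {curve.auc:.2f})")
        for c, (fp, tp) in sorted(curve.annotations.items()):
            ax.plot([fp], [tp], marker="o", ms=3, color="black")
            if curve is curves[0]:
                ax.annotate(f"{c:g}", (fp, tp), fontsize=7,
                            textcoords="offset points", xytext=(4, -8))
    ax.plot([0, 1], [0, 1], ls=":", color="grey", lw=0.8)
    ax.set_xlabel("False positive rate (full course given | not full)")
    ax.set_ylabel("True positive rate (full course given | full)")
    ax.set_title("Procalcitonin vs antibiotic-course decision")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
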