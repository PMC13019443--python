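"""T-score prediction from spectra and WHO bone-health classification.

A PLS regression maps one representative spectrum per subject (by
convention the second digit's proximal phalanx at the midshaft, D2P1-MM00)
to the subject's distal-radius DXA T-score, evaluated leave-one-subject-out
(LOSO).  Model rank is searched over 1-15 by the LOSO root-mean-square
error of cross-validation (RMSE_CV), with ties broken toward the smaller
rank.  Predicted T-scores are thresholded with the WHO rule —

    Normal        T > −1
    Osteopenia    −2.5 < T ≤ −1
    Osteoporosis  T ≤ −2.5

— and summarized by a 3×3 confusion matrix, one-vs-rest per-class
precision / sensitivity / specificity / accuracy, and pairwise ROC curves
whose AUC equals the Mann-Whitney U statistic normalized by n1·n2 with
half credit for ties.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import stats

from ._exceptions import RankError, RocError, StatTestError
from .pls_engine import fit_pls2, predict

logger = logging.getLogger(__name__)

CLASS_ORDER = ("Normal", "Osteopenia", "Osteoporosis")

WHOClass = Literal["Normal", "Osteopenia", "Osteoporosis"]


@dataclass(frozen=True)
class WHORule:
    """WHO diagnostic cutoffs on the T-score axis.

    The osteopenia band is the half-open interval (−2.5, −1]: a T-score of
    exactly −1 is Osteopenia and exactly −2.5 is Osteoporosis.
    """

    normal_cutoff: float = -1.0
    op_cutoff: float = -2.5

    @property
    def band_width(self) -> float:
        """Width of the osteopenia band in T-score units (1.5 by default)."""
        return self.normal_cutoff - self.op_cutoff


def classify_who(t: float, rule: WHORule | None = None) -> str:
    """Map a T-score to its WHO class; total over finite reals."""
    rule = rule or WHORule()
    if not np.isfinite(t):
        raise ValueError(f"T-score must be finite, got {t}")
    if t > rule.normal_cutoff:
        return "Normal"
    if t > rule.op_cutoff:
        return "Osteopenia"
    return "Osteoporosis"


@dataclass(frozen=True)
class SubjectRecord:
    """One donor: identifier, DXA T-score, WHO class, optional demographics."""

    subject_id: str
    tscore: float
    who_class: str
    age: float | None = None
    bmi: float | None = None
    bmd: float | None = None

    def __post_init__(self) -> None:
        expected = classify_who(self.tscore)
        if self.who_class != expected:
            raise ValueError(
                f"{self.subject_id}: who_class {self.who_class!r} "
                f"inconsistent with T-score {self.tscore} ({expected})"
            )


@dataclass
class TScoreCVResult:
    """LOSO T-score predictions at the selected rank."""

    subject_ids: list[str]
    true_tscores: np.ndarray
    predicted_tscores: np.ndarray
    chosen_rank: int
    pearson_r: float
    rmse_cv: float
    rmse_by_rank: dict[int, float]


def _loso_predictions(
    X: np.ndarray, y: np.ndarray, rank: int
) -> np.ndarray:
    n = X.shape[0]
    preds = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        model = fit_pls2(X[mask], y[mask], rank)
        preds[i] = float(predict(model, X[i : i + 1])[0, 0])
    return preds


def fit_tscore_loso(
    X: np.ndarray,
    records: Sequence[SubjectRecord],
    ranks: Sequence[int] = range(1, 16),
) -> TScoreCVResult:
    """LOSO PLS regression of T-scores on one spectrum per subject.

    For each candidate rank a full LOSO pass is run; the reported rank
    minimizes the pooled RMSE_CV (smallest-rank tie-break) and the
    reported Pearson r and RMSE_CV come from that rank's LOSO predictions.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 4:
        raise RankError("need at least 4 subjects for LOSO rank search")
    if len(records) != n:
        raise ValueError("one record per spectrum row required")
    y = np.array([r.tscore for r in records], dtype=float)
    max_feasible = min(n - 2, X.shape[1])  # LOSO training split has n−1 rows
    cand = sorted(set(int(r) for r in ranks if 1 <= int(r) <= max_feasible))
    if not cand:
        raise RankError(
            f"no feasible candidate rank (max feasible is {max_feasible})"
        )
    rmse_by_rank: dict[int, float] = {}
    preds_by_rank: dict[int, np.ndarray] = {}
    for r in cand:
        preds = _loso_predictions(X, y, r)
        preds_by_rank[r] = preds
        rmse_by_rank[r] = float(np.sqrt(np.mean((preds - y) ** 2)))
    chosen = min(cand, key=lambda r: (rmse_by_rank[r], r))
    preds = preds_by_rank[chosen]
    r_val = float(stats.pearsonr(y, preds).statistic)
    return TScoreCVResult(
        subject_ids=[rec.subject_id for rec in records],
        true_tscores=y,
        predicted_tscores=preds,
        chosen_rank=chosen,
        pearson_r=r_val,
        rmse_cv=rmse_by_rank[chosen],
        rmse_by_rank=rmse_by_rank,
    )


# ---------------------------------------------------------------------------
# Confusion matrix and per-class metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """3×3 counts; rows are true classes, columns predicted (WHO order)."""

    counts: np.ndarray
    classes: tuple[str, ...] = CLASS_ORDER

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.classes),) * 2:
            raise ValueError("counts must be square over the class list")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, cls: str) -> tuple[int, int, int, int]:
        """(TP, FP, TN, FN) for one class against the rest."""
        i = self.classes.index(cls)
        tp = int(self.counts[i, i])
        fp = int(self.counts[:, i].sum() - tp)
        fn = int(self.counts[i, :].sum() - tp)
        tn = self.total - tp - fp - fn
        return tp, fp, tn, fn


def confusion(
    true_classes: Sequence[str],
    predicted_classes: Sequence[str],
    classes: tuple[str, ...] = CLASS_ORDER,
) -> ConfusionMatrix:
    """Count (true, predicted) pairs with the fixed WHO class order."""
    if len(true_classes) != len(predicted_classes):
        raise ValueError("true and predicted class lists must align")
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(true_classes, predicted_classes):
        if t not in index or p not in index:
            raise ValueError(f"unknown class label: {t!r} / {p!r}")
        counts[index[t], index[p]] += 1
    if counts.sum() == 0:
        warnings.warn("empty input: confusion matrix is all zeros")
    return ConfusionMatrix(counts, classes)


@dataclass
class ClassMetrics:
    """One-vs-rest precision/sensitivity/specificity/accuracy per class.

    An undefined ratio (0/0, e.g. precision of a never-predicted class) is
    reported as None with a warning — never silently as 0.
    """

    per_class: dict[str, dict[str, float | None]]


def class_metrics(cm: ConfusionMatrix) -> ClassMetrics:
    """Per-class metrics from one-vs-rest reductions of the full matrix.

    Accuracy uses the full cohort denominator, (TP+TN)/(TP+FP+TN+FN).
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")

    def ratio(num: int, den: int, what: str) -> float | None:
        if den == 0:
            warnings.warn(f"{what} undefined (0/0); reported as None")
            return None
        return num / den

    out: dict[str, dict[str, float | None]] = {}
    for cls in cm.classes:
        tp, fp, tn, fn = cm.one_vs_rest(cls)
        out[cls] = {
            "precision": ratio(tp, tp + fp, f"{cls} precision"),
            "sensitivity": ratio(tp, tp + fn, f"{cls} sensitivity"),
            "specificity": ratio(tn, tn + fp, f"{cls} specificity"),
            "accuracy": (tp + tn) / cm.total,
        }
    return ClassMetrics(per_class=out)


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

def pairwise_roc(
    scores: Mapping[str, float],
    records: Sequence[SubjectRecord],
    pair: tuple[str, str],
) -> tuple[np.ndarray, float]:
    """ROC curve and AUC for one class pair.

    ``scores`` maps subject → decision score with higher meaning more
    diseased (the pipeline uses the negated LOSO-predicted T-score).  The
    second class of ``pair`` is treated as positive (more diseased).  The
    curve is a threshold sweep over the unique scores; the AUC equals the
    Mann-Whitney U statistic normalized by n1·n2, counting tied
    positive/negative pairs at half weight.
    """
    neg_cls, pos_cls = pair
    by_class = {neg_cls: [], pos_cls: []}
    for rec in records:
        if rec.who_class in by_class and rec.subject_id in scores:
            by_class[rec.who_class].append(float(scores[rec.subject_id]))
    neg = np.asarray(by_class[neg_cls])
    pos = np.asarray(by_class[pos_cls])
    if neg.size == 0 or pos.size == 0:
        raise RocError(f"empty class among scored subjects: {pair}")

    # AUC by pair enumeration semantics, computed via mid-ranks
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    auc = float((greater + 0.5 * ties) / (pos.size * neg.size))

    thresholds = np.concatenate(([np.inf], np.unique(np.concatenate([pos, neg]))[::-1]))
    curve = np.array(
        [
            [(neg >= thr).mean(), (pos >= thr).mean()]  # (FPR, TPR)
            for thr in thresholds
        ]
    )
    return curve, auc


# ---------------------------------------------------------------------------
# End-to-end report
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Everything the T-score pipeline reports for one cohort."""

    cv: TScoreCVResult
    cm: ConfusionMatrix
    metrics: ClassMetrics
    aucs: dict[str, float]


def evaluate_tscore_pipeline(
    X: np.ndarray,
    records: Sequence[SubjectRecord],
    ranks: Sequence[int] = range(1, 16),
    rule: WHORule | None = None,
) -> EvalReport:
    """LOSO T-score regression, WHO classification, and ROC in one pass."""
    rule = rule or WHORule()
    cv = fit_tscore_loso(X, records, ranks)
    true_cls = [r.who_class for r in records]
    pred_cls = [classify_who(t, rule) for t in cv.predicted_tscores]
    cm = confusion(true_cls, pred_cls)
    scores = {
        rec.subject_id: -float(p)
        for rec, p in zip(records, cv.predicted_tscores)
    }
    aucs = {}
    for a, b in (("Normal", "Osteopenia"), ("Normal", "Osteoporosis"),
                 ("Osteopenia", "Osteoporosis")):
        try:
            _, auc = pairwise_roc(scores, records, (a, b))
            aucs[f"{a}_vs_{b}"] = auc
        except RocError:
            logger.warning("skipping ROC for empty pair %s vs %s", a, b)
    return EvalReport(cv=cv, cm=cm, metrics=class_metrics(cm), aucs=aucs)
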