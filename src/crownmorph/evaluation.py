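"""Classification diagnostics, ROC/AUC, repeatability and size dimorphism.

The confusion-matrix panel follows the conventions of caret's
``confusionMatrix``: exact (Clopper-Pearson) binomial confidence interval for
accuracy, a one-sided exact binomial test of accuracy against the
no-information rate, Cohen's kappa from the marginals, and McNemar's
chi-square test on the discordant counts with continuity correction.
Repeatability decomposes Procrustes-aligned shape variance into
among-specimen and within-specimen (between digitization rounds) components
by a two-level Procrustes ANOVA.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
from scipy import stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

from .errors import InvalidInputError, PairingError
from .procrustes import AlignedSample, generalized_procrustes
from .types import LandmarkConfiguration


@dataclass
class ConfusionMatrix:
    """2x2 confusion counts with a declared positive class."""

    tp: int
    fp: int
    fn: int
    tn: int
    positive_class: str = "F"

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be >= 0")
        if self.total == 0:
            raise InvalidInputError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_predictions(cls, reference, predicted, positive: str = "F") -> "ConfusionMatrix":
        ref = np.asarray(reference).astype(str)
        pred = np.asarray(predicted).astype(str)
        if ref.shape != pred.shape:
            raise InvalidInputError("reference/prediction lengths differ")
        return cls(
            tp=int(np.sum((pred == positive) & (ref == positive))),
            fp=int(np.sum((pred == positive) & (ref != positive))),
            fn=int(np.sum((pred != positive) & (ref == positive))),
            tn=int(np.sum((pred != positive) & (ref != positive))),
            positive_class=positive,
        )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


@dataclass
class ClassificationReport:
    """The full metric panel computed from a confusion matrix."""

    cm: ConfusionMatrix
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    prevalence: float
    detection_rate: float
    detection_prevalence: float
    balanced_accuracy: float
    kappa: float
    nir: float
    accuracy_ci: Tuple[float, float]
    p_acc_gt_nir: float
    p_mcnemar: float

    def to_dict(self) -> Dict:
        d = {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "prevalence": self.prevalence,
            "detection_rate": self.detection_rate,
            "detection_prevalence": self.detection_prevalence,
            "balanced_accuracy": self.balanced_accuracy,
            "kappa": self.kappa,
            "nir": self.nir,
            "accuracy_ci_low": self.accuracy_ci[0],
            "accuracy_ci_high": self.accuracy_ci[1],
            "p_acc_gt_nir": self.p_acc_gt_nir,
            "p_mcnemar": self.p_mcnemar,
        }
        return d

    def to_json(self) -> str:
        return json.dumps(
            {k: (None if isinstance(v, float) and math.isnan(v) else v)
             for k, v in self.to_dict().items()},
            indent=1,
        )

    def __str__(self) -> str:
        cm = self.cm
        lines = [
            f"Confusion matrix ('{cm.positive_class}' positive)",
            f"  predicted +: {cm.tp:4d} {cm.fp:4d}",
            f"  predicted -: {cm.fn:4d} {cm.tn:4d}",
            f"Accuracy (Acc)                  {self.accuracy:.4f}",
            f"95% CI                          ({self.accuracy_ci[0]:.4f}, {self.accuracy_ci[1]:.4f})",
            f"No information rate             {self.nir:.4f}",
            f"p-value (Acc > NIR)             {self.p_acc_gt_nir:.4g}",
            f"Kappa                           {self.kappa:.4f}",
            f"McNemar's test p-value          {self.p_mcnemar:.4g}",
            f"Sensitivity (Se)                {self.sensitivity:.4f}",
            f"Specificity (Sp)                {self.specificity:.4f}",
            f"Positive predictive value (PPV) {self.ppv:.4f}",
            f"Negative predictive value (NPV) {self.npv:.4f}",
            f"Prevalence                      {self.prevalence:.4f}",
            f"Detection rate                  {self.detection_rate:.4f}",
            f"Detection prevalence            {self.detection_prevalence:.4f}",
            f"Balanced accuracy               {self.balanced_accuracy:.4f}",
        ]
        return "\n".join(lines)


def classification_report(cm: ConfusionMatrix) -> ClassificationReport:
    """Compute the caret-style metric panel from a confusion matrix.

    Undefined ratios (zero denominators) are reported as NaN, never as 0.
    """
    n = cm.total
    correct = cm.tp + cm.tn
    pos = cm.tp + cm.fn
    neg = cm.fp + cm.tn
    accuracy = correct / n
    prevalence = pos / n
    nir = max(pos, neg) / n

    po = accuracy
    pe = (pos / n) * ((cm.tp + cm.fp) / n) + (neg / n) * ((cm.fn + cm.tn) / n)
    kappa = (po - pe) / (1 - pe) if pe < 1 else math.nan

    ci = stats.binomtest(correct, n).proportion_ci(confidence_level=0.95, method="exact")
    p_nir = stats.binomtest(correct, n, p=nir, alternative="greater").pvalue

    b, c = cm.fp, cm.fn
    if b + c > 0:
        chi2 = (abs(b - c) - 1) ** 2 / (b + c)
        p_mcnemar = float(stats.chi2.sf(chi2, df=1))
    else:
        p_mcnemar = math.nan

    se = _ratio(cm.tp, pos)
    sp = _ratio(cm.tn, neg)
    return ClassificationReport(
        cm=cm,
        accuracy=accuracy,
        sensitivity=se,
        specificity=sp,
        ppv=_ratio(cm.tp, cm.tp + cm.fp),
        npv=_ratio(cm.tn, cm.tn + cm.fn),
        prevalence=prevalence,
        detection_rate=cm.tp / n,
        detection_prevalence=(cm.tp + cm.fp) / n,
        balanced_accuracy=(se + sp) / 2,
        kappa=kappa,
        nir=nir,
        accuracy_ci=(float(ci.low), float(ci.high)),
        p_acc_gt_nir=float(p_nir),
        p_mcnemar=p_mcnemar,
    )


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_auc(scores, labels, positive: str = "F") -> RocCurve:
    """ROC curve (threshold sweep over unique scores) and trapezoid AUC."""
    s = np.asarray(scores, dtype=float)
    y = (np.asarray(labels).astype(str) == positive).astype(int)
    if len(np.unique(y)) < 2:
        raise InvalidInputError("both classes must be present for a ROC curve")
    fpr, tpr, thr = _roc_curve(y, s, drop_intermediate=False)
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=float(_trapezoid_auc(fpr, tpr)))


@dataclass
class RepeatabilityReport:
    """Procrustes-ANOVA decomposition of repeat-digitization variance."""

    agreement: float
    error_variance_fraction: float
    among_variance: float
    within_variance: float
    n_specimens: int
    n_rounds: int = 2


def repeatability(
    round1: AlignedSample,
    round2: AlignedSample,
    pairing: Optional[Mapping[str, str]] = None,
) -> RepeatabilityReport:
    """Digitization repeatability from two measurement rounds.

    The two rounds are jointly re-superimposed (one GPA over all 2n
    digitizations) and the shape variance is split into among-specimen and
    within-specimen (between-round) components by a two-level Procrustes
    ANOVA.  ``error_variance_fraction`` is the within share of the total;
    ``agreement`` is the complementary intraclass-style coefficient.
    """
    ids1 = list(round1.specimen_ids)
    ids2 = list(round2.specimen_ids)
    pairing = dict(pairing) if pairing is not None else {s: s for s in ids1}
    missing = [s for s in ids1 if pairing.get(s) not in set(ids2)]
    if missing or len(ids1) != len(ids2):
        raise PairingError(f"unpaired specimens: {missing or 'count mismatch'}")
    if round1.n_points != round2.n_points:
        raise PairingError("rounds have differing landmark counts")

    # joint superimposition of all digitizations in a common frame
    configs = []
    for i, sid in enumerate(ids1):
        configs.append(round1.aligned[i])
        configs.append(round2.aligned[ids2.index(pairing[sid])])
    joint = generalized_procrustes(
        [LandmarkConfiguration(str(i), round1.tooth, c,
                               ["fixed"] * round1.n_points)
         for i, c in enumerate(configs)]
    )
    x = joint.flattened().reshape(len(ids1), 2, -1)

    spec_means = x.mean(axis=1)
    grand = spec_means.mean(axis=0)
    n = len(ids1)
    r = 2
    ss_within = float(np.sum((x - spec_means[:, None, :]) ** 2))
    ss_among = float(r * np.sum((spec_means - grand) ** 2))
    ms_within = ss_within / (n * (r - 1))
    ms_among = ss_among / (n - 1)
    var_within = ms_within
    var_among = (ms_among - ms_within) / r
    total = var_among + var_within
    if total <= 0:
        frac = 0.0 if ss_within == 0 else 1.0
    else:
        frac = var_within / total
    agreement = 1.0 - frac
    return RepeatabilityReport(
        agreement=float(np.clip(agreement, -1.0, 1.0)),
        error_variance_fraction=float(np.clip(frac, 0.0, 1.0)),
        among_variance=var_among,
        within_variance=var_within,
        n_specimens=n,
    )


def centroid_size_dimorphism_test(sizes, labels, positive: str = "F") -> Tuple[float, float]:
    """Welch two-sample t test on ln(centroid size) between the sexes.

    Returns (t statistic, two-sided p value); the statistic is positive when
    the positive class ("female") has the larger mean log size.
    """
    s = np.asarray(sizes, dtype=float)
    lab = np.asarray(labels).astype(str)
    if np.any(s <= 0):
        raise InvalidInputError("centroid sizes must be positive")
    a = np.log(s[lab == positive])
    b = np.log(s[lab != positive])
    if len(a) == 0 or len(b) == 0:
        raise InvalidInputError("both sexes must be present")
    if np.var(a) == 0 and np.var(b) == 0:
        # degenerate: no variation at all
        return (0.0, 1.0) if np.mean(a) == np.mean(b) else (math.inf, 0.0)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
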