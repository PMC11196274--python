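"""Classifier evaluation, agreement analysis and group-comparison statistics.

Three classical classifier families — a linear-kernel maximum-margin
classifier (SVM), linear discriminant analysis, and a k-nearest-neighbour
voter (k = 5) — are trained on per-subject feature tables from thermal,
visible or fused tongue images, using a stratified 70/15/15
train/validation/test split, with features z-scored on the training split
only.  Test-split performance is summarized by the confusion-matrix
percentages (sensitivity, specificity, accuracy, PPV, NPV) and the ROC AUC.

Also here: Bland–Altman limits of agreement for observer-variability
analysis of repeated temperature readings, and the per-variable two-group
comparison report (Shapiro–Wilk normality check plus Welch's t-test,
significance flagged at p < 0.01).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import roc_auc_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .synthetic_cohort import split_dataset

__all__ = [
    "ConfusionCounts",
    "ConfusionMetrics",
    "ClassificationReport",
    "AgreementResult",
    "confusion_metrics",
    "roc_auc",
    "train_eval",
    "bland_altman",
    "group_comparison",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class ConfusionMetrics:
    """The five confusion-derived percentages; a metric whose denominator is
    zero is NaN and listed in ``undefined``."""

    sensitivity: float
    specificity: float
    accuracy: float
    ppv: float
    npv: float
    undefined: tuple[str, ...] = ()


def confusion_metrics(c: ConfusionCounts) -> ConfusionMetrics:
    """Sensitivity, specificity, accuracy, PPV, NPV — each in percent."""
    if c.total == 0:
        raise ValueError("all confusion counts are zero")

    undefined = []

    def ratio(name, num, den):
        if den == 0:
            undefined.append(name)
            return math.nan
        return 100.0 * num / den

    m = ConfusionMetrics(
        sensitivity=ratio("sensitivity", c.tp, c.tp + c.fn),
        specificity=ratio("specificity", c.tn, c.tn + c.fp),
        accuracy=ratio("accuracy", c.tp + c.tn, c.total),
        ppv=ratio("ppv", c.tp, c.tp + c.fp),
        npv=ratio("npv", c.tn, c.tn + c.fn),
        undefined=tuple(undefined),
    )
    return m


def roc_auc(scores, labels) -> float:
    """ROC AUC via the rank (midrank-tie) construction; requires both
    classes to be present."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("roc_auc requires both classes in labels")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


@dataclass
class ClassificationReport:
    classifier_name: str
    modality: str
    sensitivity: float
    specificity: float
    accuracy: float
    ppv: float
    npv: float
    auc: float
    counts: ConfusionCounts
    n_train: int
    n_val: int
    n_test: int

    def as_dict(self) -> dict:
        return {
            "classifier": self.classifier_name,
            "modality": self.modality,
            "auc": self.auc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "accuracy": self.accuracy,
        }


def _default_classifiers(knn_k: int, svm_c: float) -> dict:
    return {
        "SVM": SVC(kernel="linear", C=svm_c),
        "LDA": LinearDiscriminantAnalysis(),
        "k-NN": KNeighborsClassifier(n_neighbors=knn_k),
    }


def train_eval(features, labels, split=(0.70, 0.15, 0.15), seed: int = 0,
               modality: str = "fused", knn_k: int = 5,
               svm_c: float = 1.0, classifiers=None):
    """Train the three classifier families and evaluate on the test split.

    ``features`` is a DataFrame or 2-D array (subjects x features);
    ``labels`` holds the group of each subject ("diabetes" positive, or
    1/0).  Returns one :class:`ClassificationReport` per classifier.
    The validation split is held out from both fitting and evaluation; it
    is reserved for hyperparameter sweeps.
    """
    X = (features.to_numpy(dtype=float)
         if isinstance(features, pd.DataFrame)
         else np.asarray(features, dtype=float))
    labels = np.asarray(labels)
    if len(labels) != X.shape[0]:
        raise ValueError("labels length mismatch")
    positive = "diabetes" if "diabetes" in set(map(str, labels)) else None
    y = ((labels.astype(str) == positive).astype(int)
         if positive is not None else labels.astype(int))

    idx_tr, idx_va, idx_te = split_dataset(
        list(range(len(y))), fractions=split, seed=seed, labels=y)
    for name, idx in (("training", idx_tr), ("validation", idx_va),
                      ("test", idx_te)):
        counts = np.bincount(y[idx], minlength=2)
        if counts.min() < 2:
            raise ValueError(
                f"degenerate {name} split: need >= 2 subjects per class, "
                f"got {counts.tolist()}")

    scaler = StandardScaler().fit(X[idx_tr])
    Xtr, Xte = scaler.transform(X[idx_tr]), scaler.transform(X[idx_te])
    ytr, yte = y[idx_tr], y[idx_te]

    if classifiers is None:
        classifiers = _default_classifiers(knn_k, svm_c)
    reports = []
    for name, clf in classifiers.items():
        clf.fit(Xtr, ytr)
        pred = clf.predict(Xte)
        counts = ConfusionCounts(
            tp=int(np.sum((pred == 1) & (yte == 1))),
            fp=int(np.sum((pred == 1) & (yte == 0))),
            tn=int(np.sum((pred == 0) & (yte == 0))),
            fn=int(np.sum((pred == 0) & (yte == 1))),
        )
        m = confusion_metrics(counts)
        if hasattr(clf, "decision_function"):
            scores = clf.decision_function(Xte)
        else:
            scores = clf.predict_proba(Xte)[:, 1]
        reports.append(ClassificationReport(
            classifier_name=name, modality=modality,
            sensitivity=m.sensitivity, specificity=m.specificity,
            accuracy=m.accuracy, ppv=m.ppv, npv=m.npv,
            auc=roc_auc(scores, yte), counts=counts,
            n_train=len(idx_tr), n_val=len(idx_va), n_test=len(idx_te),
        ))
    return reports


@dataclass
class AgreementResult:
    """Bland–Altman agreement summary: mean of paired differences and the
    95% limits of agreement (mean +/- 1.96 sample SD)."""

    mean_difference: float
    lower_loa: float
    upper_loa: float
    differences: np.ndarray = field(repr=False, default=None)


def bland_altman(measA, measB) -> AgreementResult:
    a = np.asarray(measA, dtype=float)
    b = np.asarray(measB, dtype=float)
    if a.shape != b.shape:
        raise ValueError("measurement series differ in length")
    if a.size < 2:
        raise ValueError("need at least 2 paired measurements")
    d = a - b
    mean_d = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementResult(
        mean_difference=mean_d,
        lower_loa=mean_d - 1.96 * sd,
        upper_loa=mean_d + 1.96 * sd,
        differences=d,
    )


def group_comparison(table, groups, variables=None,
                     alpha: float = 0.01) -> pd.DataFrame:
    """Per-variable two-group report: mean ± SD per group, Shapiro–Wilk
    normality p-values, Welch's t-test and a significance flag at
    ``p < alpha``.

    ``groups`` labels each row of ``table``; the groups are reported in the
    order ("normal", "diabetes") when those labels are present.  Variables
    that are constant and identical in both groups get t = 0, p = 1
    (degenerate-case convention).
    """
    table = pd.DataFrame(table)
    if variables is None:
        variables = [c for c in table.columns
                     if pd.api.types.is_numeric_dtype(table[c])]
    groups = np.asarray(groups)
    names = list(pd.unique(groups))
    if len(names) != 2:
        raise ValueError(f"expected exactly 2 groups, got {names}")
    if set(names) == {"normal", "diabetes"}:
        names = ["normal", "diabetes"]
    g1, g2 = (table.loc[groups == name, variables] for name in names)
    if len(g1) < 3 or len(g2) < 3:
        raise ValueError("need >= 3 subjects per group")

    def shapiro_p(x):
        if np.ptp(x) == 0:
            return math.nan
        return float(stats.shapiro(x).pvalue)

    rows = []
    for var in variables:
        x1 = g1[var].to_numpy(dtype=float)
        x2 = g2[var].to_numpy(dtype=float)
        if x1.var() == 0 and x2.var() == 0:
            t, p = (0.0, 1.0) if x1.mean() == x2.mean() else (math.inf, 0.0)
        else:
            t, p = stats.ttest_ind(x1, x2, equal_var=False)
        rows.append({
            "variable": var,
            f"{names[0]}_mean": x1.mean(), f"{names[0]}_sd": x1.std(ddof=1),
            f"{names[1]}_mean": x2.mean(), f"{names[1]}_sd": x2.std(ddof=1),
            f"shapiro_p_{names[0]}": shapiro_p(x1),
            f"shapiro_p_{names[1]}": shapiro_p(x2),
            "t_stat": float(t),
            "p_value": float(p),
            "significant": bool(p < alpha),
            "label": f"p<{alpha:g}" if p < alpha else "NS",
        })
    return pd.DataFrame(rows).set_index("variable")
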