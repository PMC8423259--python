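"""Per-feature ANOVA screening, p-value threshold reports, classification
metrics and the independent SVM validation harness.

ANOVA is the one-way fixed-effects F test computed per feature from between-
and within-group sums of squares, with p from the F distribution on
(k−1, n−k) degrees of freedom.  Degenerate features use two documented
conventions: a feature constant everywhere carries no signal and gets p = 1;
a feature with zero within-group variance but positive between-group variance
separates the groups perfectly and gets p = 0.  No multiple-testing
correction is applied anywhere — reported p-values are raw.

Two threshold conventions coexist deliberately: :func:`count_pvalues_above`
counts strictly greater than alpha (matching "greater than 0.05" counts),
while :func:`pvalue_ratio_report` buckets the boundary p = alpha into the
upper fraction (matching a "⩾ 0.05 vs < 0.05" split).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import confusion_matrix
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .io import ExpressionMatrix, LabelVector

__all__ = [
    "PValueTable",
    "MetricsReport",
    "load_reference_pvalues",
    "anova_pvalues",
    "count_pvalues_above",
    "pvalue_ratio_report",
    "classification_metrics",
    "svm_validate",
    "stratified_holdout",
]

# relative tolerance deciding that a sum of squares is zero
_SS_RTOL = 1e-12


@dataclass
class PValueTable:
    """feature name → raw one-way ANOVA p-value, plus the class partition used."""

    pvalues: dict
    class_set: list

    def __post_init__(self) -> None:
        for name, p in self.pvalues.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"p-value for {name!r} outside [0, 1]: {p}")

    def values(self) -> list[float]:
        return list(self.pvalues.values())


@dataclass
class MetricsReport:
    """One-vs-rest precision/recall/F1 per class, overall accuracy, confusion.

    ``confusion`` rows are true classes, columns predicted, in ``class_set``
    order.  ``n_test`` is the per-class support.  For averaged reports the
    metrics are plain arithmetic means of the per-report metrics (so F1 is
    the mean of F1s, not the harmonic mean of averaged precision/recall) and
    the confusion matrix is the element-wise mean.
    """

    class_set: list
    precision: dict
    recall: dict
    f1: dict
    accuracy: float
    confusion: np.ndarray
    n_test: dict


def anova_pvalues(
    X: ExpressionMatrix, labels: LabelVector, features: Optional[Sequence[str]] = None
) -> PValueTable:
    """One-way F-test p-value per feature across the label classes.

    Vectorized over features via per-class sums; degenerate features follow
    the module's documented conventions.  Requires ≥ 2 classes present and
    n > k for a defined within-group variance.
    """
    classes = [c for c in labels.class_set if labels.counts.get(c, 0) > 0]
    k = len(classes)
    if k < 2:
        raise ValueError("ANOVA needs at least 2 classes with samples")
    if features is None:
        cols = np.arange(X.m)
        names = list(X.feature_names)
    else:
        index = {name: j for j, name in enumerate(X.feature_names)}
        unknown = [f for f in features if f not in index]
        if unknown:
            raise ValueError(f"unknown feature(s): {unknown}")
        cols = np.array([index[f] for f in features])
        names = list(features)
    values = X.values[:, cols]
    n = values.shape[0]
    if n <= k:
        raise ValueError("need more samples than classes")

    grand_mean = values.mean(axis=0)
    ss_between = np.zeros(values.shape[1])
    ss_within = np.zeros(values.shape[1])
    for c in classes:
        idx = labels.indices_of(c)
        group = values[idx]
        gmean = group.mean(axis=0)
        ss_between += len(idx) * (gmean - grand_mean) ** 2
        ss_within += ((group - gmean) ** 2).sum(axis=0)

    ss_total = ss_between + ss_within
    scale = np.maximum(ss_total, (np.abs(values).max(axis=0) ** 2) * n)
    zero_between = ss_between <= _SS_RTOL * np.maximum(scale, 1.0)
    zero_within = ss_within <= _SS_RTOL * np.maximum(scale, 1.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = (ss_between / (k - 1)) / (ss_within / (n - k))
    pvals = stats.f.sf(f_stat, k - 1, n - k)
    pvals = np.where(zero_within & ~zero_between, 0.0, pvals)  # perfect separation
    pvals = np.where(zero_between & zero_within, 1.0, pvals)  # constant feature
    return PValueTable(pvalues=dict(zip(names, map(float, pvals))), class_set=classes)


def load_reference_pvalues(comparison: Optional[str] = None) -> dict:
    """Published raw ANOVA p-values of the AD/LATE gene signatures.

    Ships the per-gene p-values reported for the 31-gene four-class signature
    (``four_class``) and the six pairwise-class signatures of the AD/LATE
    cohort study, as printed.  Returns ``{comparison: [(gene, p), ...]}`` in
    reported rank order, or the single list when ``comparison`` is given.
    """
    import importlib.resources as resources

    import pandas as pd

    with resources.files("imrf.data").joinpath("reference_pvalues.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    table: dict = {}
    for comp, group in df.groupby("comparison", sort=False):
        table[comp] = [(g, float(p)) for g, p in zip(group["gene"], group["pvalue"])]
    if comparison is not None:
        if comparison not in table:
            raise KeyError(f"unknown comparison {comparison!r}; have {sorted(table)}")
        return table[comparison]
    return table


def count_pvalues_above(pvals: Sequence[float], alpha: float) -> int:
    """Number of p-values strictly greater than alpha."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    pvals = list(pvals)
    if any(not 0.0 <= p <= 1.0 for p in pvals):
        raise ValueError("p-values must lie in [0, 1]")
    return sum(1 for p in pvals if p > alpha)


def pvalue_ratio_report(pvals: Sequence[float], alpha: float) -> tuple[float, float]:
    """(fraction with p ⩾ alpha, fraction with p < alpha); boundary goes up."""
    pvals = list(pvals)
    if not pvals:
        raise ValueError("empty p-value list")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    above = sum(1 for p in pvals if p >= alpha)
    return above / len(pvals), (len(pvals) - above) / len(pvals)


def classification_metrics(y_true, y_pred, class_set: Sequence) -> MetricsReport:
    """One-vs-rest precision/recall/F1 per class plus accuracy and confusion.

    F1 = 2PR/(P+R), defined as 0 when P + R = 0.  Labels outside
    ``class_set`` are an error.
    """
    y_true = np.asarray(list(y_true), dtype=object)
    y_pred = np.asarray(list(y_pred), dtype=object)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    known = set(class_set)
    unknown = (set(y_true) | set(y_pred)) - known
    if unknown:
        raise ValueError(f"unknown label(s): {sorted(map(str, unknown))}")
    index = {c: i for i, c in enumerate(class_set)}
    cm = confusion_matrix(
        [index[t] for t in y_true], [index[t] for t in y_pred], labels=list(range(len(class_set)))
    )
    precision, recall, f1 = {}, {}, {}
    for i, c in enumerate(class_set):
        tp = cm[i, i]
        p_den = cm[:, i].sum()
        r_den = cm[i, :].sum()
        prec = tp / p_den if p_den else 0.0
        rec = tp / r_den if r_den else 0.0
        precision[c] = float(prec)
        recall[c] = float(rec)
        f1[c] = float(2 * prec * rec / (prec + rec)) if prec + rec > 0 else 0.0
    return MetricsReport(
        class_set=list(class_set),
        precision=precision,
        recall=recall,
        f1=f1,
        accuracy=float(np.trace(cm) / cm.sum()),
        confusion=cm.astype(float),
        n_test={c: int(cm[i, :].sum()) for i, c in enumerate(class_set)},
    )


def stratified_holdout(labels: LabelVector, per_class_test: int, rng: np.random.Generator):
    """Random per-class split into (train indices, test indices)."""
    if per_class_test >= labels.n_min:
        raise ValueError(
            f"per_class_test={per_class_test} must be < smallest class size {labels.n_min}"
        )
    test: list[int] = []
    for c in labels.class_set:
        members = labels.indices_of(c)
        pick = rng.choice(len(members), size=per_class_test, replace=False)
        test.extend(int(members[i]) for i in pick)
    test_set = set(test)
    train = [i for i in range(labels.n) if i not in test_set]
    return train, sorted(test)


def svm_validate(
    X: ExpressionMatrix,
    labels: LabelVector,
    feature_subset: Optional[Sequence[str]] = None,
    per_class_test: int = 16,
    kernel_degree: int = 3,
    C: float = 1.0,
    seed: int = 0,
) -> MetricsReport:
    """Polynomial-kernel SVM benchmark on a stratified random test split.

    Holds out ``per_class_test`` samples per class, standardizes features on
    the training split, trains an SVC with a degree-``kernel_degree``
    polynomial kernel on the remaining samples restricted to
    ``feature_subset`` (all features when None), and reports test metrics.
    Deterministic under ``seed``.
    """
    if feature_subset is not None:
        index = {name: j for j, name in enumerate(X.feature_names)}
        unknown = [f for f in feature_subset if f not in index]
        if unknown:
            raise ValueError(f"unknown feature(s): {unknown}")
        cols = np.array([index[f] for f in feature_subset])
    else:
        cols = np.arange(X.m)

    rng = np.random.default_rng(seed)
    train_idx, test_idx = stratified_holdout(labels, per_class_test, rng)
    X_train = X.values[np.ix_(train_idx, cols)]
    X_test = X.values[np.ix_(test_idx, cols)]
    y_train = labels.labels[train_idx]
    y_test = labels.labels[test_idx]

    scaler = StandardScaler().fit(X_train)
    clf = SVC(kernel="poly", degree=kernel_degree, C=C, random_state=int(rng.integers(2**31)))
    clf.fit(scaler.transform(X_train), y_train.astype(str))
    y_pred = clf.predict(scaler.transform(X_test))

    tokens = {str(c): c for c in labels.class_set}
    y_pred = np.array([tokens[t] for t in y_pred], dtype=object)
    return classification_metrics(y_test, y_pred, labels.class_set)
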