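"""The integrated multiple-random-forest selector.

One run proceeds in five stages: (1) split the imbalanced cohort into L
class-balanced subsets (see :mod:`imrf.sampling`); (2) on each subset train p
independently seeded random forests of T trees and average their normalized
mean-decrease-in-impurity importances into one importance row; (3) score each
subset's p-forest majority vote on a single stratified holdout; (4) average
the validation reports; (5) aggregate the L importance rows into the final
ranked feature list (see :mod:`imrf.aggregation`).

Reproducibility: samples are first canonically ordered by sample id, then all
randomness (holdout, sampling plan, every forest) is derived from the one
RunConfig seed through a SeedSequence spawn tree, so a run is a pure function
of (data, config) — including under permutations of the input row order.  The
L×p forest trainings are seeded independently per task and may be executed
concurrently without changing results.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .aggregation import ImportanceTensor, RankedFeatureList, aggregate
from .evaluation import MetricsReport, classification_metrics, stratified_holdout
from .io import ExpressionMatrix, LabelVector, RunConfig, derive_seeds, get_logger
from .sampling import BalancedSubset, plan_subsets

__all__ = ["ValidationReport", "train_subset", "average_reports", "run_imrf", "ImrfResult"]

# a validation report is a plain metrics report
ValidationReport = MetricsReport


def _majority_vote(predictions: np.ndarray, class_set: Sequence) -> np.ndarray:
    """Per-column majority over p prediction rows; ties → earlier class."""
    order = {c: i for i, c in enumerate(class_set)}
    out = []
    for col in predictions.T:
        counts: dict = {}
        for token in col:
            counts[token] = counts.get(token, 0) + 1
        best = max(counts, key=lambda c: (counts[c], -order[c]))
        out.append(best)
    return np.asarray(out, dtype=object)


def _fit_forest(X_train, y_train, T: int, seed: int, max_features, max_depth) -> RandomForestClassifier:
    forest = RandomForestClassifier(
        n_estimators=T,
        random_state=seed,
        max_features=max_features,
        max_depth=max_depth,
        n_jobs=1,
    )
    forest.fit(X_train, y_train)
    return forest


def _normalized_importances(forest: RandomForestClassifier) -> np.ndarray:
    imp = np.asarray(forest.feature_importances_, dtype=float)
    total = imp.sum()
    return imp / total if total > 0 else imp


def train_subset(
    X: ExpressionMatrix,
    labels: LabelVector,
    subset: BalancedSubset,
    T: int,
    p: int,
    seeds: Sequence[int],
    val_indices: Sequence[int],
    max_features="sqrt",
    max_depth: Optional[int] = None,
):
    """Train p forests on one balanced subset.

    Returns the subset's importance row (mean of the p normalized
    mean-decrease-in-impurity vectors) and the validation report of the
    p-forest majority vote on the held-out samples.
    """
    if T < 1 or p < 1:
        raise ValueError("T and p must be ≥ 1")
    if len(seeds) != p:
        raise ValueError(f"need {p} seeds, got {len(seeds)}")
    val_indices = list(val_indices)
    if not val_indices:
        raise ValueError("validation set is empty")
    overlap = set(subset.all_indices) & set(val_indices)
    if overlap:
        raise ValueError(f"subset overlaps validation set: {sorted(overlap)[:5]}")

    train_idx = subset.all_indices
    X_train = X.values[train_idx]
    y_train = labels.labels[train_idx].astype(str)
    X_val = X.values[val_indices]
    y_val = labels.labels[val_indices]

    rows = np.zeros((p, X.m))
    predictions = np.empty((p, len(val_indices)), dtype=object)
    tokens = {str(c): c for c in labels.class_set}
    for j, seed in enumerate(seeds):
        forest = _fit_forest(X_train, y_train, T, int(seed), max_features, max_depth)
        rows[j] = _normalized_importances(forest)
        predictions[j] = [tokens[t] for t in forest.predict(X_val)]

    importance_row = rows.mean(axis=0)
    total = importance_row.sum()
    if total > 0:
        importance_row = importance_row / total
    voted = _majority_vote(predictions, labels.class_set)
    report = classification_metrics(y_val, voted, labels.class_set)
    return importance_row, report


def average_reports(reports: Sequence[ValidationReport]) -> ValidationReport:
    """Element-wise arithmetic mean of the per-subset validation reports."""
    if not reports:
        raise ValueError("no reports to average")
    class_set = reports[0].class_set
    for r in reports[1:]:
        if r.class_set != class_set:
            raise ValueError("reports have inconsistent class sets")
    mean = lambda key: {c: float(np.mean([getattr(r, key)[c] for r in reports])) for c in class_set}
    return ValidationReport(
        class_set=list(class_set),
        precision=mean("precision"),
        recall=mean("recall"),
        f1=mean("f1"),
        accuracy=float(np.mean([r.accuracy for r in reports])),
        confusion=np.mean([r.confusion for r in reports], axis=0),
        n_test=reports[0].n_test,
    )


@dataclass
class ImrfResult:
    tensor: ImportanceTensor
    reports: list
    mean_report: ValidationReport
    ranked: RankedFeatureList
    validation_indices: list


def _default_holdout(labels: LabelVector) -> int:
    # 16 per class when every class can spare 16 and still train, else 20%
    if labels.n_min >= 18:
        return 16
    return max(1, int(0.2 * labels.n_min))


def run_imrf(X: ExpressionMatrix, labels: LabelVector, cfg: RunConfig) -> ImrfResult:
    """Full integrated run: holdout → balanced plan → L×p forests → aggregation.

    Fully reproducible under ``cfg.seed``; invariant to permutations of the
    input sample order (samples are canonically reordered by id first).
    """
    if labels.n != X.n:
        raise ValueError("labels and matrix disagree on sample count")
    if cfg.d > X.m:
        raise ValueError(f"d={cfg.d} exceeds number of features m={X.m}")
    log = get_logger()

    order = sorted(range(X.n), key=lambda i: X.sample_ids[i])
    X = X.select_samples(order)
    labels = labels.select(order)

    holdout_seed, plan_seed, forest_root = derive_seeds(cfg.seed, 3)
    per_class_test = cfg.validation_per_class or _default_holdout(labels)
    rng = np.random.default_rng(holdout_seed)
    train_idx, val_idx = stratified_holdout(labels, per_class_test, rng)

    train_labels = labels.select(train_idx)
    if train_labels.n_min < 2:
        raise ValueError("fewer than 2 training samples in the smallest class after holdout")
    plan = plan_subsets(train_labels, L=cfg.L, seed=plan_seed)
    log.info(
        "run: n=%d m=%d classes=%s holdout=%d/class L=%d p=%d q=%d d=%d T=%d round_size=%d",
        X.n, X.m, {str(k): v for k, v in labels.counts.items()},
        per_class_test, cfg.L, cfg.p, cfg.q, cfg.d, cfg.T, plan.round_size,
    )

    forest_seeds = derive_seeds(forest_root, cfg.L * cfg.p)
    rows, reports = [], []
    for l, subset in enumerate(plan.subsets):
        # map subset's train-relative indices back to canonical sample indices
        mapped = BalancedSubset(
            indices_by_class={
                c: [train_idx[i] for i in idx] for c, idx in subset.indices_by_class.items()
            },
            subset_seed=subset.subset_seed,
        )
        seeds = forest_seeds[l * cfg.p : (l + 1) * cfg.p]
        row, report = train_subset(
            X, labels, mapped, cfg.T, cfg.p, seeds, val_idx,
            max_features=cfg.max_features, max_depth=cfg.max_depth,
        )
        rows.append(row)
        reports.append(report)

    tensor = ImportanceTensor(values=np.stack(rows), feature_names=list(X.feature_names))
    ranked = aggregate(tensor, cfg.q, cfg.d)
    return ImrfResult(
        tensor=tensor,
        reports=reports,
        mean_report=average_reports(reports),
        ranked=ranked,
        validation_indices=list(val_idx),
    )
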