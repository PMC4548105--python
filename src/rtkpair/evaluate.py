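"""Metrics and evaluation protocols.

Metrics: confusion counts at a fixed decision threshold of 0, precision
p = TP/(TP+FP), recall r = TP/(TP+FN), F-measure 2pr/(p+r), and the ROC
curve with its trapezoidal area (equal to the Mann-Whitney concordance
probability with ties counted 1/2).  Undefined ratios (e.g. precision
when nothing is predicted positive) are reported as absent and rendered
"—" in report tables.

Protocols: repeated stratified 5-fold cross-validation (decision values
pooled over the five folds into one report per repeat, then averaged
across repeats), a repeated stratified 80/20 independent test, and the
decision-value combination protocol where two models trained per fold are
merged with AUC-0.5 weights measured by inner CV on the training portion
only.  Everything downstream of the seeds is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_curve

from . import featurize
from .dataset import PairDataset, holdout_split, stratified_kfold
from .featurize import build_vocabulary
from .model import SvmConfig, combine_decisions, decision_values, fit_tuned
from .seqio import PairExample

UNDEFINED = "—"


class EvaluateError(ValueError):
    pass


@dataclass
class EvalReport:
    """Confusion counts and ranking metrics for one evaluation run.

    Counts are floats so that reports averaged across repeats remain
    representable; single-run reports hold integral values.  ``precision``
    / ``recall`` / ``f_measure`` are None when undefined.
    """

    tp: float
    fp: float
    tn: float
    fn: float
    precision: float | None
    recall: float | None
    f_measure: float | None
    roc_points: list[tuple[float, float]]
    auc: float
    method: str = ""

    @property
    def n(self) -> float:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_scores(
        cls,
        labels: Sequence[int],
        scores: Sequence[float],
        threshold: float = 0.0,
        method: str = "",
    ) -> "EvalReport":
        tp, fp, tn, fn = confusion(labels, scores, threshold)
        p, r, f = precision_recall_f(tp, fp, fn)
        points, auc = roc_auc(labels, scores)
        return cls(
            tp=tp, fp=fp, tn=tn, fn=fn,
            precision=p, recall=r, f_measure=f,
            roc_points=points, auc=auc, method=method,
        )


def confusion(
    labels: Sequence[int], scores: Sequence[float], threshold: float = 0.0
) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) with predicted-positive iff score > threshold (strict)."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise EvaluateError(f"length mismatch: {labels.shape} labels, {scores.shape} scores")
    pred = scores > threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    return tp, fp, tn, fn


def precision_recall_f(
    tp: float, fp: float, fn: float
) -> tuple[float | None, float | None, float | None]:
    """p = TP/(TP+FP), r = TP/(TP+FN), F = 2pr/(p+r); None where undefined."""
    if min(tp, fp, fn) < 0:
        raise EvaluateError("confusion counts must be nonnegative")
    p = tp / (tp + fp) if tp + fp > 0 else None
    r = tp / (tp + fn) if tp + fn > 0 else None
    if p is None or r is None or p + r == 0:
        f = None
    else:
        f = 2 * p * r / (p + r)
    return p, r, f


def roc_auc(
    labels: Sequence[int], scores: Sequence[float]
) -> tuple[list[tuple[float, float]], float]:
    """ROC points (FPR, TPR) by descending-score sweep, and trapezoidal AUC.

    Tied scores collapse into single steps, which makes the trapezoidal
    area equal to the pairwise concordance probability with ties counted
    one half.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise EvaluateError("labels and scores must have equal length")
    if len(np.unique(labels)) < 2:
        raise EvaluateError("ROC requires both classes present")
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def mean_report(reports: Sequence[EvalReport], method: str = "") -> EvalReport:
    """Average metrics and counts (as reals) across repeats.

    Ratio metrics are averaged over the repeats where they are defined and
    are None only if undefined in every repeat.  ROC points are taken from
    the first repeat (per-repeat curves are written individually when
    needed).
    """
    if not reports:
        raise EvaluateError("cannot average zero reports")

    def avg(values: list[float | None]) -> float | None:
        defined = [v for v in values if v is not None]
        return float(np.mean(defined)) if defined else None

    return EvalReport(
        tp=float(np.mean([r.tp for r in reports])),
        fp=float(np.mean([r.fp for r in reports])),
        tn=float(np.mean([r.tn for r in reports])),
        fn=float(np.mean([r.fn for r in reports])),
        precision=avg([r.precision for r in reports]),
        recall=avg([r.recall for r in reports]),
        f_measure=avg([r.f_measure for r in reports]),
        roc_points=list(reports[0].roc_points),
        auc=float(np.mean([r.auc for r in reports])),
        method=method or reports[0].method,
    )


def _fold_vocabulary(ds: PairDataset, train_pairs: Sequence[PairExample], scope: str):
    """Vocabulary from training-fold proteins only (default) or the whole dataset."""
    if scope == "all":
        return build_vocabulary(ds.hits, ds.proteins)
    if scope != "train":
        raise EvaluateError(f"unknown vocabulary scope {scope!r}")
    in_train = {p.receptor_id for p in train_pairs} | {p.ligand_id for p in train_pairs}
    hits = [h for h in ds.hits if h.protein_id in in_train]
    return build_vocabulary(hits, ds.proteins)


def _features(ds: PairDataset, pairs, vocab, recipe):
    X, _ = featurize.pair_feature_matrix(pairs, ds.proteins, ds.hits, vocab, recipe)
    return X


def _seed_list(seeds: Sequence[int] | None, n_repeats: int, base_seed: int) -> list[int]:
    if seeds is None:
        seeds = [base_seed + i for i in range(n_repeats)]
    if len(seeds) != n_repeats:
        raise EvaluateError(f"need {n_repeats} seeds, got {len(seeds)}")
    return list(seeds)


def cross_validate(
    ds: PairDataset,
    recipe: str,
    config: SvmConfig | None = None,
    n_folds: int = 5,
    n_repeats: int = 5,
    seeds: Sequence[int] | None = None,
    vocab_scope: str = "train",
    method: str | None = None,
) -> tuple[list[EvalReport], EvalReport]:
    """Repeated stratified k-fold CV for one feature recipe.

    Per repeat: stratified folds; per fold the vocabulary and the
    hyperparameter tuning use the training portion only, and decision
    values are collected on the held-out fold.  Pooled decision values
    over the folds give one report per repeat; the mean report averages
    across repeats.
    """
    config = config or SvmConfig()
    seeds = _seed_list(seeds, n_repeats, config.seed)
    reports = []
    for seed in seeds:
        folds = stratified_kfold(ds.pairs, n_folds=n_folds, seed=seed)
        pooled_labels: list[int] = []
        pooled_scores: list[float] = []
        for fold in range(n_folds):
            train_pairs = [p for p, f in zip(ds.pairs, folds) if f != fold]
            test_pairs = [p for p, f in zip(ds.pairs, folds) if f == fold]
            vocab = _fold_vocabulary(ds, train_pairs, vocab_scope)
            X_train = _features(ds, train_pairs, vocab, recipe)
            X_test = _features(ds, test_pairs, vocab, recipe)
            y_train = np.array([p.label for p in train_pairs])
            m = fit_tuned(X_train, y_train, replace(config, seed=seed),
                          recipe=recipe, n_folds=n_folds, seed=seed)
            pooled_scores.extend(decision_values(m, X_test).tolist())
            pooled_labels.extend(p.label for p in test_pairs)
        reports.append(
            EvalReport.from_scores(pooled_labels, pooled_scores, method=method or recipe)
        )
    return reports, mean_report(reports, method=method or recipe)


def independent_test(
    ds: PairDataset,
    recipe: str,
    config: SvmConfig | None = None,
    fraction: float = 0.2,
    n_repeats: int = 3,
    seeds: Sequence[int] | None = None,
    n_folds: int = 5,
    vocab_scope: str = "train",
    method: str | None = None,
) -> tuple[list[EvalReport], EvalReport]:
    """Repeated stratified holdout: tune by inner CV on training data only,
    refit on all training data, evaluate once on the holdout, then average
    over repeats."""
    config = config or SvmConfig()
    seeds = _seed_list(seeds, n_repeats, config.seed)
    reports = []
    for seed in seeds:
        train_pairs, test_pairs = holdout_split(ds.pairs, fraction=fraction, seed=seed)
        vocab = _fold_vocabulary(ds, train_pairs, vocab_scope)
        X_train = _features(ds, train_pairs, vocab, recipe)
        X_test = _features(ds, test_pairs, vocab, recipe)
        y_train = np.array([p.label for p in train_pairs])
        m = fit_tuned(X_train, y_train, replace(config, seed=seed),
                      recipe=recipe, n_folds=n_folds, seed=seed)
        scores = decision_values(m, X_test)
        labels = [p.label for p in test_pairs]
        reports.append(EvalReport.from_scores(labels, scores, method=method or recipe))
    return reports, mean_report(reports, method=method or recipe)


def run_combination_protocol(
    ds: PairDataset,
    recipe_a: str,
    recipe_b: str,
    config: SvmConfig | None = None,
    n_folds: int = 5,
    n_repeats: int = 5,
    seeds: Sequence[int] | None = None,
    vocab_scope: str = "train",
    method: str = "combined results",
) -> tuple[list[EvalReport], EvalReport]:
    """Combine two recipes' decision values within each CV fold.

    Both models are trained on the same training portion; their inner-CV
    AUCs (training portion only, never the evaluation fold) set the
    combination weights a = AUC_A - 0.5 and b = AUC_B - 0.5; the held-out
    decision values are merged and pooled into one report per repeat.
    """
    config = config or SvmConfig()
    seeds = _seed_list(seeds, n_repeats, config.seed)
    reports = []
    for seed in seeds:
        folds = stratified_kfold(ds.pairs, n_folds=n_folds, seed=seed)
        pooled_labels: list[int] = []
        pooled_scores: list[float] = []
        for fold in range(n_folds):
            train_pairs = [p for p, f in zip(ds.pairs, folds) if f != fold]
            test_pairs = [p for p, f in zip(ds.pairs, folds) if f == fold]
            vocab = _fold_vocabulary(ds, train_pairs, vocab_scope)
            y_train = np.array([p.label for p in train_pairs])
            fold_scores = {}
            fold_aucs = {}
            for tag, recipe in (("a", recipe_a), ("b", recipe_b)):
                X_train = _features(ds, train_pairs, vocab, recipe)
                X_test = _features(ds, test_pairs, vocab, recipe)
                m = fit_tuned(X_train, y_train, replace(config, seed=seed),
                              recipe=recipe, n_folds=n_folds, seed=seed)
                fold_scores[tag] = decision_values(m, X_test)
                fold_aucs[tag] = m.training_auc
            combined = combine_decisions(
                fold_scores["a"], fold_scores["b"], fold_aucs["a"], fold_aucs["b"]
            )
            pooled_scores.extend(combined.tolist())
            pooled_labels.extend(p.label for p in test_pairs)
        reports.append(EvalReport.from_scores(pooled_labels, pooled_scores, method=method))
    return reports, mean_report(reports, method=method)


def write_report_table(path: str | Path, reports: Sequence[EvalReport]) -> None:
    """One row per method: method, precision, recall, f_measure, auc, tp, fp, tn, fn."""

    def fmt(v: float | None) -> str:
        return UNDEFINED if v is None else f"{v:.3f}"

    def fmt_count(v: float) -> str:
        return str(int(v)) if float(v).is_integer() else f"{v:.1f}"

    with open(path, "w") as handle:
        handle.write("method\tprecision\trecall\tf_measure\tauc\ttp\tfp\ttn\tfn\n")
        for r in reports:
            handle.write(
                f"{r.method}\t{fmt(r.precision)}\t{fmt(r.recall)}\t{fmt(r.f_measure)}\t"
                f"{r.auc:.3f}\t{fmt_count(r.tp)}\t{fmt_count(r.fp)}\t"
                f"{fmt_count(r.tn)}\t{fmt_count(r.fn)}\n"
            )


def write_roc_points(path: str | Path, report: EvalReport) -> None:
    """Two-column TSV (fpr, tpr) for plotting the report's ROC curve."""
    with open(path, "w") as handle:
        handle.write("fpr\ttpr\n")
        for fpr, tpr in report.roc_points:
            handle.write(f"{fpr:.6f}\t{tpr:.6f}\n")
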