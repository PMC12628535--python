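"""Classifier evaluation and interpretability analyses.

Threshold metrics (sensitivity, specificity, accuracy, precision, F1, MCC)
are computed from explicit confusion counts; ranking metrics (AUROC, AUPRC)
integrate the ROC and precision-recall curves by the trapezoid rule.
Degenerate denominators yield 0 with a flag rather than an exception, so a
bad cross-validation fold cannot abort a whole run.

Interpretability utilities mirror three standard analyses: per-position mean
absolute input gradients, per-position perturbation (base-substitution)
importance, and per-dimension Welch t-statistics of the learned
representation between classes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
from scipy import stats
from sklearn.metrics import precision_recall_curve, roc_curve

from .autodiff import Tensor
from .sequence_io import SequenceRecord


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class MetricReport:
    sn: float
    sp: float
    acc: float
    pre: float
    f1: float
    mcc: float
    degenerate: bool = False  # some denominator was zero; affected metrics are 0

    def as_dict(self) -> dict:
        return {
            "Sn": self.sn,
            "Sp": self.sp,
            "Acc": self.acc,
            "Pre": self.pre,
            "F1": self.f1,
            "MCC": self.mcc,
        }


def confusion(labels, scores, threshold: float = 0.5) -> ConfusionCounts:
    """Count TP/TN/FP/FN at `threshold` (score >= threshold -> positive)."""
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=np.float64)
    if labels.shape != scores.shape:
        raise ValueError(f"length mismatch: {labels.shape} labels, {scores.shape} scores")
    pred = (scores >= threshold).astype(int)
    return ConfusionCounts(
        tp=int(np.sum((labels == 1) & (pred == 1))),
        tn=int(np.sum((labels == 0) & (pred == 0))),
        fp=int(np.sum((labels == 0) & (pred == 1))),
        fn=int(np.sum((labels == 1) & (pred == 0))),
    )


def _ratio(num: float, den: float) -> tuple[float, bool]:
    return (num / den, False) if den > 0 else (0.0, True)


def metrics(counts: ConfusionCounts) -> MetricReport:
    """Sn, Sp, Acc, Pre, F1 and MCC from confusion counts."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    sn, d1 = _ratio(tp, tp + fn)
    sp, d2 = _ratio(tn, tn + fp)
    acc, d3 = _ratio(tp + tn, tp + tn + fp + fn)
    pre, d4 = _ratio(tp, tp + fp)
    f1, d5 = _ratio(2 * pre * sn, pre + sn)
    mcc_den = np.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc, d6 = _ratio(tp * tn - fp * fn, mcc_den)
    return MetricReport(
        sn=sn, sp=sp, acc=acc, pre=pre, f1=f1, mcc=mcc,
        degenerate=any((d1, d2, d3, d4, d5, d6)),
    )


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("ranking metrics require both classes to be present")


def auroc(scores, labels) -> float:
    """Area under the ROC curve (trapezoid; equals the rank statistic with
    ties counted 1/2)."""
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=np.float64)
    _check_two_classes(labels)
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    return float(np.trapezoid(tpr, fpr))


def auprc(scores, labels) -> float:
    """Area under the precision-recall curve by trapezoid integration."""
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=np.float64)
    _check_two_classes(labels)
    precision, recall, _ = precision_recall_curve(labels, scores)
    # precision_recall_curve returns points from high threshold (recall 0) to
    # low (recall 1) — reverse for an increasing integration axis
    return float(np.trapezoid(precision[::-1], recall[::-1]))


def roc_points(scores, labels) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    return np.column_stack([fpr, tpr])


def pr_points(scores, labels) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    precision, recall, _ = precision_recall_curve(labels, scores)
    return np.column_stack([recall[::-1], precision[::-1]])


def full_report(scores, labels, threshold: float = 0.5) -> dict:
    """Threshold metrics plus AUROC/AUPRC in one dictionary."""
    rep = metrics(confusion(labels, scores, threshold)).as_dict()
    rep["AUROC"] = auroc(scores, labels)
    rep["AUPRC"] = auprc(scores, labels)
    return rep


# -- repeated-run stability ---------------------------------------------------


def repeated_runs(
    train_records,
    test_records,
    config,
    n_runs: int,
    master_seed: int = 0,
) -> dict:
    """Re-train `n_runs` times under seeds derived from `master_seed`.

    Returns per-run AUROC values and summary quantiles, the machinery behind
    repeated-trial stability boxplots.
    """
    from .pipeline import prepare_features, run_experiment, score_records

    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    seed_rng = np.random.default_rng(master_seed)
    run_seeds = seed_rng.integers(0, 2**31 - 1, size=n_runs)
    _, _, y_te = prepare_features(test_records, config.k, config.target_len)
    values = []
    for s in run_seeds:
        cfg = dc_replace(config, seed=int(s))
        model, _ = run_experiment(train_records, test_records, cfg)
        values.append(auroc(score_records(model, test_records, cfg), y_te))
    values = np.asarray(values)
    return {
        "auroc": values,
        "median": float(np.median(values)),
        "q25": float(np.quantile(values, 0.25)),
        "q75": float(np.quantile(values, 0.75)),
    }


def cross_modification_matrix(datasets: dict, config) -> "object":
    """AUROC of the model trained on type i, evaluated on type j's test set.

    `datasets` maps name -> (train_records, test_records).  Returns a pandas
    DataFrame with training types as columns and testing types as rows.
    """
    import pandas as pd

    from .pipeline import prepare_features, run_experiment, score_records

    if len(datasets) < 2:
        raise ValueError("cross-modification analysis needs at least 2 datasets")
    names = list(datasets)
    mat = np.zeros((len(names), len(names)))
    for j, train_name in enumerate(names):
        tr, te = datasets[train_name]
        model, _ = run_experiment(tr, te, config)
        for i, test_name in enumerate(names):
            _, test_records = datasets[test_name]
            _, _, y = prepare_features(test_records, config.k, config.target_len)
            scores = score_records(model, test_records, config)
            mat[i, j] = auroc(scores, y)
    return pd.DataFrame(mat, index=names, columns=names)


# -- interpretability ---------------------------------------------------------


def gradient_importance(model, records: list[SequenceRecord], config) -> np.ndarray:
    """Mean |d positive-score / d input| aggregated per sequence position.

    Gradients are taken with respect to the embedded token matrix (tokens are
    discrete, so the embedding input is the differentiable surface) and the
    CGR state matrix.  Each interior token's gradient magnitude is spread
    evenly over the k positions it covers; the CGR branch contributes its
    per-position magnitude directly.  Profile length equals the padded
    sequence length.
    """
    from .pipeline import prepare_features

    ids, cgr, _ = prepare_features(records, config.k, config.target_len)
    L0 = cgr.shape[1]
    k = config.k
    profile = np.zeros(L0)
    n = ids.shape[0]
    for b in range(n):
        X = Tensor(model.embedding(ids[b : b + 1]).data, requires_grad=True)
        Xe = Tensor(cgr[b : b + 1], requires_grad=True)
        probs = model.forward_probs((X, Xe), train_mode=False)
        probs[0, 1].backward()
        tok_mag = (
            np.abs(X.grad[0]).mean(axis=1) if X.grad is not None else np.zeros(X.shape[1])
        )
        pos_mag = np.abs(Xe.grad[0][:, 0]) if Xe.grad is not None else np.zeros(L0)
        contrib = np.zeros(L0)
        # tokens: [CLS], k-mers starting at 0..L0-k, [SEP]
        for t in range(1, ids.shape[1] - 1):
            start = t - 1
            contrib[start : start + k] += tok_mag[t] / k
        profile += contrib + pos_mag
    return profile / max(n, 1)


def perturbation_importance(model, records: list[SequenceRecord], config) -> np.ndarray:
    """Mean |change in positive-class score| under base substitution.

    Position p's score is the mean absolute change of the model's positive
    probability when the base at p is replaced by each of the three
    alternative bases (gap positions are scored over all four bases).
    """
    from .pipeline import prepare_features, score_records

    bases = "ACGU"
    L0 = config.target_len
    base_scores = score_records(model, records, config)
    profile = np.zeros(L0)
    for p in range(L0):
        deltas = []
        mutated_records = []
        owners = []
        for i, r in enumerate(records):
            seq = r.seq + "-" * (L0 - len(r.seq))
            current = seq[p].replace("T", "U")
            for b in bases:
                if b == current:
                    continue
                mutated_records.append(
                    SequenceRecord(r.id, seq[:p] + b + seq[p + 1 :], r.label)
                )
                owners.append(i)
        mut_scores = score_records(model, mutated_records, config)
        for s, i in zip(mut_scores, owners):
            deltas.append(abs(s - base_scores[i]))
        profile[p] = float(np.mean(deltas)) if deltas else 0.0
    return profile


def feature_t_stats(representations: np.ndarray, labels) -> np.ndarray:
    """Welch two-sample t-statistic per representation dimension.

    Positive group minus negative group; dimensions with zero variance in
    both groups are reported as NaN sentinels.
    """
    X = np.asarray(representations, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    pos, neg = X[labels == 1], X[labels == 0]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("each class needs at least 2 samples")
    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # constant dimensions
        t = stats.ttest_ind(pos, neg, axis=0, equal_var=False).statistic
    return np.asarray(t)


def top_features(t_stats: np.ndarray, k: int = 10) -> list[tuple[int, float]]:
    """Dimensions ranked by |t|, NaN sentinels last."""
    order = np.argsort(-np.nan_to_num(np.abs(t_stats), nan=-np.inf))
    return [(int(i), float(t_stats[i])) for i in order[:k]]
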