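"""Repeated nested cross-validated SVM-RBF classification.

For every admissible accumulated feature set: stratified 3-fold outer CV,
repeated (default 100 times).  Within each outer training fold the
accumulated features are re-ranked by mRMR and the top fraction retained;
SVM-RBF hyperparameters (C and the kernel width) are tuned by stratified
10-fold inner CV on mean accuracy; outer-test accuracy, sensitivity,
specificity and AUC are averaged over the three folds, and the per-repeat
values are summarised as mean +/- SD.  The threshold with the highest mean
test accuracy wins (ties break toward the larger threshold, i.e. fewer
features), and "major features" are those retained by the inner mRMR step
in more than 90% of repeats.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .mrmr import mrmr_select

__all__ = [
    "CVPerformance",
    "nested_cv",
    "compute_metrics",
    "select_best_threshold",
    "major_features",
    "compare_performance",
    "C_GRID",
    "GAMMA_MULTIPLIERS",
]

#: SVM hyperparameter grid.  gamma is expressed as multiples of the "scale"
#: width 1 / (n_features * Var(X)); the grid spans two octaves either side.
C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)
GAMMA_MULTIPLIERS = (0.25, 0.5, 1.0, 2.0, 4.0)


@dataclass
class CVPerformance:
    """Per-repeat fold-averaged metrics with mean +/- SD summaries."""

    per_repeat: pd.DataFrame  # columns: accuracy, sensitivity, specificity, auc
    positive_class: object
    threshold: int = None
    selection_log: list = None  # per repeat: list (per outer fold) of feature-index arrays
    tuning_log: list = None  # per repeat: list (per outer fold) of chosen (C, gamma)

    @property
    def summary(self):
        out = {}
        for m in ("accuracy", "sensitivity", "specificity", "auc"):
            v = self.per_repeat[m]
            out[f"{m}_mean"] = float(v.mean())
            out[f"{m}_sd"] = float(v.std(ddof=1)) if len(v) > 1 else 0.0
        return out

    @property
    def mean_accuracy(self):
        return float(self.per_repeat["accuracy"].mean())


def compute_metrics(y_true, y_pred, scores, positive_class):
    """Accuracy, sensitivity, specificity and AUC for one test fold.

    Sensitivity is TP/(TP+FN) for the designated positive class and
    specificity TN/(TN+FP); AUC uses the rank (Mann-Whitney) formulation,
    in which tied scores contribute 1/2.  Scores must be oriented so that
    larger values favour the positive class.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    scores = np.asarray(scores, dtype=float)
    pos = y_true == positive_class
    neg = ~pos
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present in y_true")
    tp = int(np.sum(pos & (y_pred == positive_class)))
    tn = int(np.sum(neg & (y_pred != positive_class)))
    accuracy = (tp + tn) / y_true.size
    sensitivity = tp / n_pos
    specificity = tn / n_neg
    ranks = sps.rankdata(scores)
    auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return {"accuracy": accuracy, "sensitivity": sensitivity,
            "specificity": specificity, "auc": float(auc)}


def _repeat_seeds(seed, repeats):
    """Documented fan-out: repeat r uses SeedSequence((seed, r)); the derived
    32-bit state seeds the fold shufflers."""
    return [int(np.random.SeedSequence((seed, r)).generate_state(1)[0] % (2**31))
            for r in range(repeats)]


def _tune_and_fit(Xtr, ytr, inner, seed, c_grid, gamma_multipliers):
    """Inner stratified CV over the (C, gamma) grid; first-max tie-break in
    grid order.  Returns the tuned SVC fitted on the full training fold."""
    var = Xtr.var()
    if var == 0:
        var = 1.0
    gamma_base = 1.0 / (Xtr.shape[1] * var)
    inner_cv = StratifiedKFold(n_splits=inner, shuffle=True, random_state=seed)
    splits = list(inner_cv.split(Xtr, ytr))
    best = None
    best_acc = -1.0
    for C in c_grid:
        for gm in gamma_multipliers:
            gamma = gm * gamma_base
            correct = 0
            total = 0
            for tr, te in splits:
                clf = SVC(C=C, kernel="rbf", gamma=gamma)
                clf.fit(Xtr[tr], ytr[tr])
                correct += int(np.sum(clf.predict(Xtr[te]) == ytr[te]))
                total += te.size
            acc = correct / total
            if acc > best_acc:
                best_acc = acc
                best = (C, gamma)
    clf = SVC(C=best[0], kernel="rbf", gamma=best[1])
    clf.fit(Xtr, ytr)
    return clf, best


def nested_cv(X, y, positive_class, repeats=100, outer=3, inner=10, seed=0,
              inner_keep=0.8, c_grid=C_GRID, gamma_multipliers=GAMMA_MULTIPLIERS,
              threshold=None):
    """Repeated stratified nested CV of an SVM-RBF on one feature set.

    Parameters
    ----------
    X : (n, p) array
        Feature matrix restricted to one accumulated feature set.
    y : (n,) array
        Binary labels.
    positive_class :
        Label treated as positive for sensitivity and AUC.
    inner_keep : float
        Fraction of the accumulated features retained by the per-fold mRMR
        re-ranking before the SVM sees them.

    Returns a :class:`CVPerformance` whose ``selection_log`` records, per
    repeat and outer fold, the indices (columns of X) retained by the inner
    mRMR step — the input to the major-feature rule.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, cc = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("nested_cv requires exactly two classes")
    if cc.min() < outer:
        raise ValueError(f"need at least {outer} subjects per class for {outer}-fold outer CV")
    k_keep = max(1, ceil(inner_keep * X.shape[1])) if X.shape[1] > 1 else 1

    rows = []
    log = []
    tlog = []
    for rs in _repeat_seeds(seed, repeats):
        outer_cv = StratifiedKFold(n_splits=outer, shuffle=True, random_state=rs)
        fold_metrics = []
        fold_sel = []
        fold_tune = []
        for tr, te in outer_cv.split(X, y):
            if X.shape[1] > 1:
                keep = np.asarray(mrmr_select(X[tr], y[tr], k_keep).order, dtype=int)
            else:
                keep = np.array([0])
            fold_sel.append(np.sort(keep))
            Xtr, Xte = X[np.ix_(tr, keep)], X[np.ix_(te, keep)]
            clf, params = _tune_and_fit(Xtr, y[tr], inner, rs, c_grid, gamma_multipliers)
            fold_tune.append(params)
            pred = clf.predict(Xte)
            scores = clf.decision_function(Xte)
            if clf.classes_[1] != positive_class:
                scores = -scores
            fold_metrics.append(compute_metrics(y[te], pred, scores, positive_class))
        rows.append({m: float(np.mean([f[m] for f in fold_metrics]))
                     for m in ("accuracy", "sensitivity", "specificity", "auc")})
        log.append(fold_sel)
        tlog.append(fold_tune)
    return CVPerformance(per_repeat=pd.DataFrame(rows), positive_class=positive_class,
                         threshold=threshold, selection_log=log, tuning_log=tlog)


def select_best_threshold(results):
    """Threshold with the highest mean test accuracy; ties prefer the larger
    threshold (the smaller feature set).  ``results`` maps threshold ->
    CVPerformance."""
    if not results:
        raise ValueError("no thresholds evaluated")
    best_t = None
    best_acc = -np.inf
    for t in sorted(results):
        acc = results[t].mean_accuracy
        if acc >= best_acc:
            best_acc = acc
            best_t = t
    return best_t


def major_features(perf: CVPerformance, X=None, y=None, descriptors=None,
                   min_repeats=None, fold_rule="majority"):
    """Features re-selected by the inner mRMR in more than 90% of repeats.

    A feature counts once per repeat if it was retained in a majority of the
    outer training folds (``fold_rule`` may also be "any" or "all").
    Inclusion requires count strictly greater than ``min_repeats`` (default
    0.9 * repeats, i.e. > 90 of 100).  When X/y are given, each feature's
    direction is the sign of mean(positive class) - mean(negative class);
    descriptor columns (feature name, network pair) are joined when
    available.
    """
    log = perf.selection_log
    if not log:
        raise ValueError("empty selection log")
    repeats = len(log)
    n_folds = len(log[0])
    need = {"majority": n_folds // 2 + 1, "any": 1, "all": n_folds}[fold_rule]
    if min_repeats is None:
        min_repeats = 0.9 * repeats

    repeat_counts = {}
    for folds in log:
        per_repeat = {}
        for sel in folds:
            for f in sel:
                per_repeat[f] = per_repeat.get(f, 0) + 1
        for f, c in per_repeat.items():
            if c >= need:
                repeat_counts[f] = repeat_counts.get(f, 0) + 1

    chosen = sorted(f for f, c in repeat_counts.items() if c > min_repeats)
    out = pd.DataFrame({"column": chosen,
                        "repeat_count": [repeat_counts[f] for f in chosen]})
    if X is not None and y is not None and len(chosen):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        pos = y == perf.positive_class
        diff = X[pos].mean(axis=0) - X[~pos].mean(axis=0)
        out["direction"] = np.where(diff[chosen] >= 0, "+", "-")
    if descriptors is not None and len(chosen):
        cols = [c for c in ("feature", "kind", "i", "j", "network_i", "network_j",
                            "region", "measure") if c in descriptors.columns]
        out = pd.concat([out.reset_index(drop=True),
                         descriptors.iloc[chosen][cols].reset_index(drop=True)], axis=1)
    return out


def compare_performance(perf_a: CVPerformance, perf_b: CVPerformance):
    """Independent-samples (pooled-variance) t test on per-repeat accuracies."""
    a = perf_a.per_repeat["accuracy"].to_numpy()
    b = perf_b.per_repeat["accuracy"].to_numpy()
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 repeats per performance")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("both accuracy vectors have zero variance; t test undefined")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)
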