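"""Bootstrap-aggregated mRMR selection and the selection-count threshold sweep.

Generalised features are estimated by resampling a fixed fraction of the
cohort (default 90%, with replacement) B times, running the greedy
MIQ-mRMR selector on each resample, and counting per feature the number of
resamples in which it was selected.  Accumulating the features whose count
strictly exceeds each threshold on a grid yields a nested family of
candidate sets (the "number of features vs threshold" curve); sets larger
than a dimensionality cap tied to the outer-training-fold size are excluded
from classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import floor

import numpy as np
import pandas as pd

from .mrmr import mrmr_select

__all__ = [
    "SelectionCounts",
    "ThresholdSweep",
    "bootstrap_resample",
    "run_bootstrap_selection",
    "accumulate",
    "cap_by_dimensionality",
    "default_threshold_grid",
]

#: Threshold grid as fractions of B: 0.15 .. 0.95 step 0.05, which at
#: B = 1000 gives the canonical 150..950 step-50 grid.
GRID_FRACTIONS = np.round(np.arange(0.15, 0.951, 0.05), 2)


def default_threshold_grid(B):
    """Selection-count thresholds at 15%..95% of B in 5% steps."""
    grid = sorted({int(round(f * B)) for f in GRID_FRACTIONS})
    return [t for t in grid if 0 <= t <= B]


@dataclass
class SelectionCounts:
    """Per-feature bootstrap selection frequencies over B resamples."""

    counts: np.ndarray
    B: int
    K_per_run: int
    resample_size: int
    seed: int
    n_redraws: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if (self.counts < 0).any() or (self.counts > self.B).any():
            raise ValueError("counts must lie in 0..B")

    def to_frame(self, descriptors=None):
        df = pd.DataFrame({"feature_index": np.arange(self.counts.size),
                           "count": self.counts})
        if descriptors is not None:
            df.insert(1, "feature", descriptors["feature"].to_numpy())
        return df


@dataclass
class ThresholdSweep:
    """Accumulated feature sets per threshold; nested and non-increasing."""

    thresholds: list
    sets: dict  # threshold -> sorted np.ndarray of feature indices
    B: int

    @property
    def table(self):
        return pd.DataFrame({
            "threshold": self.thresholds,
            "n_features": [len(self.sets[t]) for t in self.thresholds],
        })


def bootstrap_resample(n, fraction=0.9, rng=None, replace=True):
    """Indices of one bootstrap resample: floor(fraction * n) draws (at
    least 1), so a 90% bootstrap of n = 98 yields 88 indices.

    With replacement by default; ``replace=False`` gives subsampling
    without replacement.
    """
    if n <= 0:
        raise ValueError("cannot resample an empty cohort")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(rng)
    size = max(1, floor(fraction * n + 1e-9))
    return rng.choice(n, size=size, replace=replace)


def run_bootstrap_selection(X, y, B=1000, K_per_run=50, fraction=0.9,
                            replace=True, seed=0, scheme="sd3", bins=None):
    """Aggregate mRMR selections over B bootstrap resamples.

    Resamples that lose one of the two classes are redrawn (and counted);
    a redraw rate above 10% triggers a class-imbalance warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, class_counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("both classes must be present in the cohort")
    n, p = X.shape
    rng = np.random.default_rng(seed)
    counts = np.zeros(p, dtype=int)
    n_redraws = 0
    size = max(1, floor(fraction * n + 1e-9))
    for _ in range(B):
        while True:
            idx = bootstrap_resample(n, fraction=fraction, rng=rng, replace=replace)
            if np.unique(y[idx]).size == 2:
                break
            n_redraws += 1
        sel = mrmr_select(X[idx], y[idx], K_per_run, scheme=scheme, bins=bins)
        counts[sel.order] += 1
    if n_redraws > 0.1 * B:
        warnings.warn(
            f"bootstrap redraw rate {n_redraws}/{B} exceeds 10%; class sizes are "
            f"{dict(zip(classes.tolist(), class_counts.tolist()))} — consider a larger "
            "resample fraction or rebalanced groups", stacklevel=2)
    return SelectionCounts(counts=counts, B=B, K_per_run=min(K_per_run, p),
                           resample_size=size, seed=seed, n_redraws=n_redraws)


def accumulate(counts: SelectionCounts, thresholds=None):
    """Accumulated feature sets {features with count > t} per threshold.

    The comparison is strict, so a feature sitting exactly at a threshold is
    excluded at that threshold.
    """
    if thresholds is None:
        thresholds = default_threshold_grid(counts.B)
    thresholds = sorted(int(t) for t in thresholds)
    if any(t < 0 or t > counts.B for t in thresholds):
        raise ValueError("thresholds must lie within 0..B")
    sets = {t: np.flatnonzero(counts.counts > t) for t in thresholds}
    return ThresholdSweep(thresholds=thresholds, sets=sets, B=counts.B)


def cap_by_dimensionality(sweep: ThresholdSweep, n_subjects, cap=None):
    """Thresholds whose accumulated set is small enough to train on.

    The default cap is floor(2/3 * n_subjects) — the largest outer-training
    fold of a 3-fold split — so no classifier ever sees more features than
    training subjects.  Empty sets are inadmissible too.  Returns the
    admissible thresholds; raises if there are none.
    """
    if cap is None:
        cap = floor(2 * n_subjects / 3)
    admissible = [t for t in sweep.thresholds if 1 <= len(sweep.sets[t]) <= cap]
    if not admissible:
        raise ValueError(
            f"no admissible threshold: all accumulated sets exceed the cap of {cap} "
            "features or are empty; extend the threshold grid upward")
    return admissible


def plot_sweep(sweep: ThresholdSweep, ax=None):
    """Feature-count-vs-threshold curve (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = sweep.table
    ax.plot(t["threshold"], t["n_features"], marker="o")
    ax.set_xlabel("selection-count threshold")
    ax.set_ylabel("accumulated features")
    return ax
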