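"""Minimum-redundancy maximum-relevance (mRMR) feature selection.

Greedy forward selection driven by the mutual-information quotient

    MIQ(x) = V(x) / W(x),

where V(x) is the mutual information between feature x and the (binary)
response and W(x) is the mean mutual information between x and the features
already selected.  Mutual information is the plug-in estimate on discretised
states, reported in bits.  The first feature is chosen by pure relevance
(W is undefined for an empty selected set); candidates whose redundancy is
exactly zero are treated as having infinite quotient and are ordered among
themselves by relevance.  All ties break toward the lower feature index.

``mrmr_select`` is the production implementation (vectorised over candidate
features).  ``mrmr_brute_oracle`` is an intentionally naive literal
re-evaluation of the quotient at every step, used as an independent
cross-check; the two must agree exactly on small pools.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MIQScore",
    "SelectionResult",
    "discretize",
    "mutual_information",
    "mrmr_select",
    "mrmr_brute_oracle",
]


# ---------------------------------------------------------------------------
# discretisation


def discretize(x, scheme="sd3", bins=None):
    """Map a real vector onto a small set of integer states.

    Parameters
    ----------
    x : array-like of float
        Finite values.
    scheme : {"sd3", "quantile"}
        ``sd3`` (default): three states ``{-1, 0, 1}`` with cut points at
        mean +/- one sample standard deviation; values at or beyond a cut
        fall in the outer state.  ``quantile``: ``bins`` equal-frequency
        bins coded ``0..bins-1``.
    bins : int, optional
        Number of bins for the quantile scheme.

    Constant vectors map to a single state under either scheme.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("discretize expects a 1-D vector")
    if not np.all(np.isfinite(x)):
        raise ValueError("discretize requires finite values")
    if scheme == "sd3":
        m = x.mean()
        s = x.std(ddof=1) if x.size > 1 else 0.0
        states = np.zeros(x.size, dtype=np.int64)
        if s > 0:
            states[x <= m - s] = -1
            states[x >= m + s] = 1
        return states
    if scheme == "quantile":
        if bins is None or bins < 1:
            raise ValueError("quantile scheme requires bins >= 1")
        if np.all(x == x[0]):
            return np.zeros(x.size, dtype=np.int64)
        qs = np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1])
        return np.searchsorted(qs, x, side="left").astype(np.int64)
    raise ValueError(f"unknown discretisation scheme: {scheme!r}")


def _encode(v):
    """Factorise an arbitrary discrete vector into codes 0..k-1 (sorted order)."""
    v = np.asarray(v)
    _, codes = np.unique(v, return_inverse=True)
    return codes.astype(np.int64)


def mutual_information(a, b):
    """Plug-in mutual information between two discrete vectors, in bits.

    Zero-count cells contribute nothing; the estimate is non-negative up to
    floating-point rounding of the sum.
    """
    a = _encode(a)
    b = _encode(b)
    if a.shape != b.shape:
        raise ValueError("mutual_information: length mismatch")
    if a.size < 1:
        raise ValueError("mutual_information: empty input")
    ka = int(a.max()) + 1
    kb = int(b.max()) + 1
    counts = np.bincount(a * kb + b, minlength=ka * kb).reshape(ka, kb)
    return _mi_from_counts(counts)


def _mi_from_counts(counts):
    # Summation runs row-major over the contingency table so the scalar and
    # vectorised paths accumulate in an identical order.
    n = counts.sum()
    if n == 0:
        raise ValueError("mutual_information: empty input")
    pa = counts.sum(axis=1) / n
    pb = counts.sum(axis=0) / n
    mi = 0.0
    for s in range(counts.shape[0]):
        for t in range(counts.shape[1]):
            c = counts[s, t]
            if c > 0:
                p = c / n
                mi += p * np.log2(p / (pa[s] * pb[t]))
    return float(mi)


# ---------------------------------------------------------------------------
# selection results


@dataclass(frozen=True)
class MIQScore:
    """Per-step score of the selected feature: relevance V, mean redundancy W
    against the previously selected set, and the quotient V/W (inf if W=0)."""

    V: float
    W: float
    MIQ: float


@dataclass
class SelectionResult:
    """Ranked feature indices in selection order with per-step scores."""

    order: list = field(default_factory=list)
    scores: list = field(default_factory=list)

    def __len__(self):
        return len(self.order)

    def __iter__(self):
        return iter(self.order)


def _check_xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (subjects x features)")
    if y.shape[0] != X.shape[0]:
        raise ValueError("X and y have different numbers of rows")
    if X.shape[1] < 2:
        raise ValueError("mRMR needs at least 2 candidate features")
    if np.unique(y).size < 2:
        raise ValueError("response has a single class; mRMR needs both classes")
    return X, y


def _discretize_columns(X, scheme, bins):
    return np.column_stack([discretize(X[:, j], scheme=scheme, bins=bins) for j in range(X.shape[1])])


class _PairwiseMI:
    """Vectorised MI between one discrete column and every column of a state
    matrix, mirroring the accumulation order of ``_mi_from_counts``."""

    def __init__(self, states):
        states = np.asarray(states)
        self.n, self.p = states.shape
        codes = np.empty_like(states, dtype=np.int64)
        self.n_states = np.empty(self.p, dtype=np.int64)
        for j in range(self.p):
            codes[:, j] = _encode(states[:, j])
            self.n_states[j] = codes[:, j].max() + 1
        self.kmax = int(self.n_states.max())
        # one-hot per state level, shared by every MI evaluation
        self.onehot = [(codes == s).astype(np.float64) for s in range(self.kmax)]
        self.codes = codes
        self.marginals = np.stack([h.sum(axis=0) / self.n for h in self.onehot])  # kmax x p

    def mi_with(self, v):
        """MI (bits) between discrete vector v and every column."""
        v = _encode(v)
        kv = int(v.max()) + 1
        n = self.n
        pv = np.bincount(v, minlength=kv) / n
        vh = [(v == s).astype(np.float64) for s in range(kv)]
        mi = np.zeros(self.p)
        for s in range(kv):
            for t in range(self.kmax):
                c = vh[s] @ self.onehot[t]  # joint counts per column
                p = c / n
                denom = pv[s] * self.marginals[t]
                term = np.zeros(self.p)
                mask = c > 0
                term[mask] = p[mask] * np.log2(p[mask] / denom[mask])
                mi += term
        return mi


def _pick(candidates, V, W_sum, n_sel):
    """Greedy-step argmax under the documented tie rules.

    Candidates with zero redundancy rank above all finite quotients and are
    ordered by relevance; all remaining ties break toward the lower index.
    """
    best = None
    best_key = None
    for j in candidates:
        if n_sel == 0:
            key = (1, V[j])  # pure relevance at step 1
        else:
            W = W_sum[j] / n_sel
            if W == 0.0:
                key = (2, V[j])  # infinite quotient, ordered by V
            else:
                key = (1, V[j] / W)
        if best_key is None or key > best_key:
            best, best_key = j, key
    return best


def mrmr_select(X, y, K, scheme="sd3", bins=None):
    """Greedy MIQ-mRMR ranking of the top-K features.

    Parameters
    ----------
    X : (n, p) array
        Feature matrix (continuous; discretised internally).
    y : (n,) array
        Binary class labels (any two distinct values).
    K : int
        Number of features to rank; capped at the pool size.

    Returns
    -------
    SelectionResult
        Feature indices in selection order with per-step (V, W, MIQ).
    """
    X, y = _check_xy(X, y)
    if K < 1:
        raise ValueError("K must be >= 1")
    p = X.shape[1]
    K = min(K, p)
    states = _discretize_columns(X, scheme, bins)
    pw = _PairwiseMI(states)
    V = pw.mi_with(y)

    result = SelectionResult()
    selected_mask = np.zeros(p, dtype=bool)
    W_sum = np.zeros(p)
    for step in range(K):
        candidates = np.flatnonzero(~selected_mask)
        j = _pick(candidates, V, W_sum, step)
        if step == 0:
            score = MIQScore(V=V[j], W=float("nan"), MIQ=V[j])
        else:
            W = W_sum[j] / step
            score = MIQScore(V=V[j], W=W, MIQ=float("inf") if W == 0.0 else V[j] / W)
        result.order.append(int(j))
        result.scores.append(score)
        selected_mask[j] = True
        if step + 1 < K:
            W_sum += pw.mi_with(states[:, j])
    return result


def mrmr_brute_oracle(X, y, K, scheme="sd3", bins=None, max_pool=15):
    """Literal re-evaluation of the quotient at every greedy step.

    Same contract as :func:`mrmr_select` but with no caching, no incremental
    updates and scalar mutual-information calls throughout; refuses pools
    larger than ``max_pool`` features.  Serves as the independent oracle.
    """
    X, y = _check_xy(X, y)
    if X.shape[1] > max_pool:
        raise ValueError(f"brute oracle refuses pools larger than {max_pool} features")
    if K < 1:
        raise ValueError("K must be >= 1")
    p = X.shape[1]
    K = min(K, p)
    states = _discretize_columns(X, scheme, bins)

    result = SelectionResult()
    selected = []
    for step in range(K):
        best = None
        best_key = None
        best_score = None
        for j in range(p):
            if j in selected:
                continue
            V = mutual_information(y, states[:, j])
            if step == 0:
                key = (1, V)
                score = MIQScore(V=V, W=float("nan"), MIQ=V)
            else:
                W_sum = 0.0
                for s in selected:
                    W_sum += mutual_information(states[:, s], states[:, j])
                W = W_sum / len(selected)
                if W == 0.0:
                    key = (2, V)
                    score = MIQScore(V=V, W=W, MIQ=float("inf"))
                else:
                    key = (1, V / W)
                    score = MIQScore(V=V, W=W, MIQ=V / W)
            if best_key is None or key > best_key:
                best, best_key, best_score = j, key, score
        selected.append(best)
        result.order.append(int(best))
        result.scores.append(best_score)
    return result
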