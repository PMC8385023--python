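"""Analysis-ready feature construction for connectome classification.

Stages, in the order the pipeline runs them: motion-based subject exclusion
(mean framewise displacement), Pearson connectivity from ROI time series,
Fisher r-to-z variance stabilisation, strict-upper-triangle vectorisation
with network annotation from a parcellation lookup, optional morphometric
merge, and age/sex residualisation (full-sample, as published, or fold-safe).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("neurostab")

NETWORKS = ("MFN", "FPN", "DMN", "SC", "MON", "VisI", "VisII", "VA")

#: Columns a phenotype table must carry for the full pipeline.
PHENOTYPE_LABELS = ("episodes", "hospitalizations", "suicide", "psychosis", "diagnosis")
WLT_TASKS = ("wlt_immediate", "wlt_delayed", "wlt_slope", "wlt_recognition", "wlt_retention")

__all__ = [
    "FeatureMatrix",
    "Parcellation",
    "filter_motion",
    "connectivity",
    "fisher_z",
    "vectorize",
    "devectorize",
    "merge_morphometry",
    "residualize",
    "NETWORKS",
    "PHENOTYPE_LABELS",
    "WLT_TASKS",
]


@dataclass
class Parcellation:
    """Region lookup: contiguous 1-based region ids, each in one network."""

    table: pd.DataFrame  # columns: region_id, region_name, network

    def __post_init__(self):
        t = self.table
        required = {"region_id", "region_name", "network"}
        if not required.issubset(t.columns):
            raise ValueError(f"parcellation table needs columns {sorted(required)}")
        ids = np.sort(t["region_id"].to_numpy())
        if not np.array_equal(ids, np.arange(1, len(t) + 1)):
            raise ValueError("region ids must be contiguous 1..R")
        unknown = set(t["network"]) - set(NETWORKS)
        if unknown:
            raise ValueError(f"unknown networks: {sorted(unknown)}")

    @property
    def n_regions(self):
        return len(self.table)

    def network_of(self, region_id):
        row = self.table.loc[self.table["region_id"] == region_id]
        return row["network"].iloc[0]

    @classmethod
    def from_csv(cls, path):
        return cls(pd.read_csv(path))

    @classmethod
    def uniform(cls, n_regions, rng=None):
        """Assign regions to the eight canonical networks round-robin."""
        nets = [NETWORKS[i % len(NETWORKS)] for i in range(n_regions)]
        return cls(pd.DataFrame({
            "region_id": np.arange(1, n_regions + 1),
            "region_name": [f"region_{i}" for i in range(1, n_regions + 1)],
            "network": nets,
        }))


@dataclass
class FeatureMatrix:
    """Subjects x features with per-feature descriptors.

    ``values`` is an (n_subjects, n_features) float array on the z-scale for
    connectivity edges; ``descriptors`` carries one row per feature with a
    ``kind`` of ``edge`` (columns i, j, network_i, network_j; 1 <= i < j) or
    ``morph`` (columns region, measure).  Row order matches the phenotype
    table the matrix was built against.
    """

    values: np.ndarray
    descriptors: pd.DataFrame
    subjects: list
    residualized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[1] != len(self.descriptors):
            raise ValueError("descriptor count does not match feature count")
        if self.values.shape[0] != len(self.subjects):
            raise ValueError("subject count does not match row count")
        if np.isnan(self.values).any():
            raise ValueError("feature matrix contains NaN")

    @property
    def n_subjects(self):
        return self.values.shape[0]

    @property
    def n_features(self):
        return self.values.shape[1]

    @property
    def feature_names(self):
        return self.descriptors["feature"].tolist()

    def subset(self, columns):
        """New FeatureMatrix restricted to the given feature column indices."""
        columns = np.asarray(columns, dtype=int)
        return FeatureMatrix(
            values=self.values[:, columns],
            descriptors=self.descriptors.iloc[columns].reset_index(drop=True),
            subjects=list(self.subjects),
            residualized=self.residualized,
        )

    def take_subjects(self, rows, subjects=None):
        rows = np.asarray(rows, dtype=int)
        subs = [self.subjects[i] for i in rows] if subjects is None else subjects
        return replace(self, values=self.values[rows], subjects=subs)

    def to_frame(self):
        return pd.DataFrame(self.values, index=pd.Index(self.subjects, name="subject_id"),
                            columns=self.feature_names)


# ---------------------------------------------------------------------------
# motion QC


def filter_motion(phenotypes, fd_threshold=0.2):
    """Keep subjects whose mean framewise displacement is <= the threshold.

    Subjects exceeding the threshold (strictly) are removed, mirroring the
    convention of excluding mean FD > 0.2 mm.
    """
    if "mean_fd" not in phenotypes.columns:
        raise ValueError("phenotype table has no mean_fd column")
    missing = phenotypes.loc[phenotypes["mean_fd"].isna(), "subject_id"].tolist()
    if missing:
        raise ValueError(f"mean_fd missing for subjects: {missing}")
    keep = phenotypes["mean_fd"] <= fd_threshold
    n_removed = int((~keep).sum())
    logger.info("motion filter: removed %d of %d subjects (mean FD > %g mm)",
                n_removed, len(phenotypes), fd_threshold)
    return phenotypes.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# connectivity


def connectivity(ts):
    """Pearson correlation matrix of a T x R ROI time-series array."""
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2 or ts.shape[0] < 3:
        raise ValueError("time series must be T x R with T >= 3")
    sd = ts.std(axis=0)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        raise ValueError(f"constant time series for region(s) {(constant + 1).tolist()}")
    r = np.corrcoef(ts, rowvar=False)
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def fisher_z(r, clip=1e-7):
    """Fisher r-to-z transform, z = atanh(r), with |r| clipped to 1 - clip
    so perfect correlations map to a finite z."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1):
        raise ValueError("correlations must satisfy |r| <= 1")
    return np.arctanh(np.clip(r, -1.0 + clip, 1.0 - clip))


# ---------------------------------------------------------------------------
# vectorisation


def _edge_index_pairs(R):
    iu, ju = np.triu_indices(R, k=1)
    return iu, ju


def vectorize(matrix, parcellation=None):
    """Strict upper triangle of a symmetric R x R matrix, row-major.

    Returns (vector, descriptors): the vector has length R(R-1)/2 and the
    descriptor table annotates each edge(i, j) (1-based, i < j) with its
    (network_i, network_j) pair when a parcellation is supplied.
    """
    matrix = np.asarray(matrix, dtype=float)
    R = matrix.shape[0]
    if matrix.shape != (R, R):
        raise ValueError("matrix must be square")
    if np.max(np.abs(matrix - matrix.T)) > 1e-8:
        raise ValueError("matrix is asymmetric beyond 1e-8")
    if parcellation is not None and parcellation.n_regions != R:
        raise ValueError("parcellation does not cover the matrix regions")
    iu, ju = _edge_index_pairs(R)
    vec = matrix[iu, ju]
    desc = pd.DataFrame({
        "feature": [f"edge_{i}_{j}" for i, j in zip(iu + 1, ju + 1)],
        "kind": "edge",
        "i": iu + 1,
        "j": ju + 1,
    })
    if parcellation is not None:
        nets = parcellation.table.set_index("region_id")["network"]
        desc["network_i"] = nets.loc[desc["i"]].to_numpy()
        desc["network_j"] = nets.loc[desc["j"]].to_numpy()
    return vec, desc


def devectorize(vec, R, diagonal=0.0):
    """Inverse of :func:`vectorize`: rebuild the symmetric matrix."""
    vec = np.asarray(vec, dtype=float)
    if vec.size != R * (R - 1) // 2:
        raise ValueError("vector length does not match R(R-1)/2")
    out = np.full((R, R), float(diagonal))
    iu, ju = _edge_index_pairs(R)
    out[iu, ju] = vec
    out[ju, iu] = vec
    return out


def merge_morphometry(features, morph):
    """Append z-scored morphometric columns to a connectivity FeatureMatrix.

    ``morph`` is a subject-indexed DataFrame whose columns are named
    ``<measure>_<region>`` with measure in {volume, thickness}.  Columns are
    z-scored before concatenation so the mutual-information discretisation
    sees both feature kinds on a comparable scale.
    """
    morph = morph.loc[features.subjects]
    vals = morph.to_numpy(dtype=float)
    sd = vals.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    vals = (vals - vals.mean(axis=0)) / sd
    parts = []
    for col in morph.columns:
        measure, _, region = col.partition("_")
        if measure not in ("volume", "thickness"):
            raise ValueError(f"morph column {col!r} must be <measure>_<region>")
        parts.append({"feature": f"morph_{col}", "kind": "morph",
                      "region": region, "measure": measure})
    desc = pd.concat([features.descriptors, pd.DataFrame(parts)], ignore_index=True)
    return FeatureMatrix(
        values=np.hstack([features.values, vals]),
        descriptors=desc,
        subjects=list(features.subjects),
        residualized=features.residualized,
    )


# ---------------------------------------------------------------------------
# covariate control


def _design(age, sex):
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=float)
    D = np.column_stack([np.ones_like(age), age, sex])
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise ValueError("rank-deficient covariate design (age/sex collinear or constant)")
    return D


def residualize(features, age, sex, mode="paper", train_idx=None, test_idx=None):
    """Regress age and sex out of every feature column.

    mode="paper"
        One OLS fit per feature on the full sample; mirrors the published
        procedure, which controlled covariates before feature selection and
        therefore shares covariate fits across later train/test splits.
    mode="fold_safe"
        Coefficients estimated on ``train_idx`` rows only and applied to both
        train and test rows; use inside cross-validation to avoid leakage.
    """
    X = features.values
    if mode == "paper":
        D = _design(age, sex)
        beta, *_ = np.linalg.lstsq(D, X, rcond=None)
        resid = X - D @ beta
    elif mode == "fold_safe":
        if train_idx is None:
            raise ValueError("fold_safe mode requires train_idx")
        train_idx = np.asarray(train_idx, dtype=int)
        D = _design(age, sex)
        Dt = D[train_idx]
        if np.linalg.matrix_rank(Dt) < Dt.shape[1]:
            raise ValueError("rank-deficient covariate design on training rows")
        beta, *_ = np.linalg.lstsq(Dt, X[train_idx], rcond=None)
        # every row, train and test alike, uses the train-fitted coefficients
        resid = X - D @ beta
    else:
        raise ValueError(f"unknown residualisation mode: {mode!r}")
    return replace(features, values=resid, residualized=True)
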