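"""Cognition regression, confound screens, demographics, and FDR control.

Conventions chosen to match the published analysis: pooled-variance
(Student) two-sample t tests throughout, chi-square without continuity
correction for sex ratios, Benjamini-Hochberg step-up FDR within each
declared family, and multiple linear regression reporting the proportion of
variance explained (R²) with the overall F-test p value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RegressionResult",
    "regress_cognition",
    "fdr_bh",
    "confound_screen",
    "group_compare_demographics",
    "two_sample_t_from_summary",
    "sex_chi_square",
]


@dataclass
class RegressionResult:
    """Multiple-regression summary for one cognitive outcome."""

    outcome: str
    r2: float
    f_pvalue: float
    n: int
    p_features: int
    n_dropped: int = 0
    q: float = None


def regress_cognition(X, score, outcome="score", feature_names=None):
    """OLS of a cognitive score on all selected features jointly.

    Rows with a missing score are dropped (complete-case per task) and
    counted; the fit requires n > p + 1 so the model is identified with at
    least one residual degree of freedom.
    """
    X = np.asarray(X, dtype=float)
    score = np.asarray(score, dtype=float)
    keep = ~np.isnan(score)
    n_dropped = int((~keep).sum())
    X, score = X[keep], score[keep]
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(
            f"n = {n} subjects cannot support {p} features: need n > p + 1 "
            "(dimensionality cap)")
    model = sm.OLS(score, sm.add_constant(X)).fit()
    return RegressionResult(outcome=outcome, r2=float(model.rsquared),
                            f_pvalue=float(model.f_pvalue), n=n, p_features=p,
                            n_dropped=n_dropped)


def fdr_bh(pvalues):
    """Benjamini-Hochberg step-up q values (monotonicity enforced)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def confound_screen(features, clinical, continuous=(), binary=(), categorical=()):
    """Association screen between selected features and clinical variables.

    Pearson correlation for continuous variables, pooled-variance two-sample
    t tests for binary flags, one-way ANOVA for categorical variables;
    BH-FDR is applied separately within each variable's family of feature
    tests.  Degenerate groups (a binary flag with one level, categorical
    levels with fewer than 2 subjects) are skipped or dropped with a
    warning.

    Parameters
    ----------
    features : DataFrame
        Subjects x selected features.
    clinical : DataFrame
        Subjects x clinical variables (row-aligned with ``features``).

    Returns a tidy DataFrame with one row per (feature, variable) pair.
    """
    rows = []
    for var in continuous:
        x = clinical[var].to_numpy(dtype=float)
        for feat in features.columns:
            f = features[feat].to_numpy(dtype=float)
            ok = ~(np.isnan(x) | np.isnan(f))
            r, p = sps.pearsonr(x[ok], f[ok])
            rows.append({"variable": var, "feature": feat, "kind": "pearson_r",
                         "statistic": float(r), "p": float(p)})
    for var in binary:
        g = clinical[var].to_numpy()
        levels = pd.unique(g[~pd.isna(g)])
        if len(levels) < 2:
            warnings.warn(f"binary variable {var!r} has a single level; t test skipped",
                          stacklevel=2)
            continue
        for feat in features.columns:
            f = features[feat].to_numpy(dtype=float)
            a, b = f[g == levels[0]], f[g == levels[1]]
            t, p = sps.ttest_ind(a, b, equal_var=True)
            rows.append({"variable": var, "feature": feat, "kind": "t",
                         "statistic": float(t), "p": float(p)})
    for var in categorical:
        g = clinical[var].astype(str).to_numpy()
        counts = pd.Series(g).value_counts()
        small = counts[counts < 2].index.tolist()
        if small:
            warnings.warn(f"dropping level(s) {small} of {var!r} with < 2 subjects",
                          stacklevel=2)
        levels = [lv for lv in counts.index if counts[lv] >= 2]
        if len(levels) < 2:
            warnings.warn(f"categorical variable {var!r} has < 2 usable levels; skipped",
                          stacklevel=2)
            continue
        for feat in features.columns:
            f = features[feat].to_numpy(dtype=float)
            groups = [f[g == lv] for lv in levels]
            F, p = sps.f_oneway(*groups)
            rows.append({"variable": var, "feature": feat, "kind": "F",
                         "statistic": float(F), "p": float(p)})
    report = pd.DataFrame(rows)
    if len(report):
        report["q"] = np.nan
        for var, idx in report.groupby("variable").groups.items():
            report.loc[idx, "q"] = fdr_bh(report.loc[idx, "p"].to_numpy())
    return report


def two_sample_t_from_summary(mean1, sd1, n1, mean2, sd2, n2):
    """Pooled-variance two-sample t test from summary statistics."""
    t, p = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=True)
    return float(t), float(p)


def sex_chi_square(counts):
    """Chi-square test (no continuity correction) on a 2x2 count table."""
    counts = np.asarray(counts, dtype=float)
    chi2, p, _, _ = sps.chi2_contingency(counts, correction=False)
    return float(chi2), float(p)


DEFAULT_CONTINUOUS = ("age", "ymrs", "madrs", "panss")


def group_compare_demographics(phenotypes, label, continuous=DEFAULT_CONTINUOUS,
                               sex_column="sex"):
    """Demographic comparison between the two groups defined by ``label``.

    Continuous variables: pooled-variance two-sample t test with means and
    SDs reported per group.  Sex: chi-square on the 2x2 contingency table
    without continuity correction.  Missing variables are omitted with a
    warning.
    """
    groups = pd.unique(phenotypes[label].dropna())
    if len(groups) != 2:
        raise ValueError(f"label {label!r} must define exactly two groups, got {list(groups)}")
    g1 = phenotypes[phenotypes[label] == groups[0]]
    g2 = phenotypes[phenotypes[label] == groups[1]]
    rows = []
    for var in continuous:
        if var not in phenotypes.columns:
            warnings.warn(f"variable {var!r} missing; omitted from the comparison",
                          stacklevel=2)
            continue
        a = g1[var].dropna().to_numpy(dtype=float)
        b = g2[var].dropna().to_numpy(dtype=float)
        t, p = sps.ttest_ind(a, b, equal_var=True)
        rows.append({"variable": var, "test": "t",
                     f"{groups[0]}_mean": a.mean(), f"{groups[0]}_sd": a.std(ddof=1),
                     f"{groups[1]}_mean": b.mean(), f"{groups[1]}_sd": b.std(ddof=1),
                     "statistic": float(t), "p": float(p)})
    if sex_column in phenotypes.columns:
        tab = pd.crosstab(phenotypes[label], phenotypes[sex_column])
        if tab.shape == (2, 2):
            chi2, p = sex_chi_square(tab.to_numpy())
            rows.append({"variable": sex_column, "test": "chi2",
                         "statistic": chi2, "p": float(p)})
        else:
            warnings.warn("sex table is not 2x2; chi-square omitted", stacklevel=2)
    return pd.DataFrame(rows)
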