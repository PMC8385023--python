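"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a two-group clinical cohort (default 43 vs 55
subjects, the episode split of the motivating study design) with a
connectome-style feature matrix: one Fisher-z value per region pair, a small
set of planted edges whose group difference is a chosen standardised effect
size, optional age/sex leakage into the features, and cognition (five
word-list-test scaled scores) generated as a linear function of the planted
edges with noise calibrated analytically to a target R².

Features are drawn directly on the residual z-scale as Gaussians — the
scale on which the downstream selection and classification operate — with
Gaussian ROI time series available as an optional slower path for testing
the connectivity stage end-to-end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import NETWORKS, WLT_TASKS, FeatureMatrix, Parcellation, devectorize

__all__ = ["SynthConfig", "SynthCohort", "generate_cohort", "generate_timeseries", "sample_timeseries"]


@dataclass
class SynthConfig:
    """Cohort-generation parameters.

    n_low, n_high
        Group sizes for the primary (episodes low/high) split.
    n_regions, n_networks
        Parcellation size; edges = n_regions(n_regions-1)/2.  30 regions
        (435 edges) is the desk-scale default; 268 reproduces the
        full-scale connectome (35,778 edges).
    n_informative_edges
        Number of planted differential edges.
    effect_size
        Standardised between-group mean difference (Cohen's d) of each
        planted edge on the residual z-scale.
    covariate_confounding
        Coefficient with which standardised age and sex leak into every
        feature (random sign per feature); 0 disables confounding.
    cognition_r2
        Target proportion of cognition variance explained by the planted
        edges; the noise variance is solved in closed form so OLS on the
        true edges recovers this value in expectation.
    noise_sd
        Within-group feature standard deviation on the z-scale.
    ts_length
        Time points per subject when generating the optional time series.
    """

    n_low: int = 43
    n_high: int = 55
    n_regions: int = 30
    n_networks: int = 8
    n_informative_edges: int = 10
    effect_size: float = 1.5
    covariate_confounding: float = 0.0
    cognition_r2: float = 0.6
    noise_sd: float = 0.3
    ts_length: int = 192
    seed: int = 0

    def validate(self):
        for name in ("n_low", "n_high", "n_regions", "n_networks",
                     "n_informative_edges", "ts_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"SynthConfig.{name} must be >= 1")
        n_edges = self.n_regions * (self.n_regions - 1) // 2
        if self.n_informative_edges > n_edges:
            raise ValueError("SynthConfig.n_informative_edges exceeds the number of edges")
        if not 0 <= self.cognition_r2 < 1:
            raise ValueError("SynthConfig.cognition_r2 must be in [0, 1)")
        if self.effect_size < 0:
            raise ValueError("SynthConfig.effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("SynthConfig.noise_sd must be > 0")
        if self.n_networks > len(NETWORKS):
            raise ValueError(f"SynthConfig.n_networks must be <= {len(NETWORKS)}")
        return self


@dataclass
class SynthCohort:
    """Generated cohort: phenotypes, features, and ground truth."""

    phenotypes: pd.DataFrame
    features: FeatureMatrix
    parcellation: Parcellation
    truth: pd.DataFrame  # columns: feature_index, feature, sign
    cognition_weights: dict = field(default_factory=dict)
    config: SynthConfig = None

    @property
    def labels(self):
        return self.phenotypes["episodes"].to_numpy()


def _truncated_normal(rng, mean, sd, low, high, size):
    out = np.empty(size)
    remaining = np.arange(size)
    while remaining.size:
        draw = rng.normal(mean, sd, remaining.size)
        ok = (draw >= low) & (draw <= high)
        out[remaining[ok]] = draw[ok]
        remaining = remaining[~ok]
    return out


def generate_cohort(config: SynthConfig) -> SynthCohort:
    """Generate a reproducible synthetic cohort from the given config.

    Planted edges differ between the episode groups by ``effect_size``
    standard deviations on the z-scale with a random sign per edge;
    non-planted edges carry no group effect.  Cognition scores are
    ``y = X w + eps`` over the planted edges with Var(Xw)/Var(y) equal to
    ``cognition_r2`` by construction (noise variance solved in closed form
    from the realised Var(Xw)).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_low + config.n_high
    n_edges = config.n_regions * (config.n_regions - 1) // 2

    # --- phenotypes -------------------------------------------------------
    age = _truncated_normal(rng, 38.0, 13.0, 18.0, 70.0, n)
    sex = (rng.random(n) < 0.3).astype(int)  # 1 = male
    episodes = np.array(["low"] * config.n_low + ["high"] * config.n_high)
    pheno = pd.DataFrame({
        "subject_id": [f"sub-{i + 1:04d}" for i in range(n)],
        "episodes": episodes,
        "hospitalizations": rng.choice(["never", "more"], n),
        "suicide": rng.choice(["yes", "no"], n),
        "psychosis": rng.choice(["yes", "no"], n),
        "diagnosis": rng.choice(["BDI", "BDII", "mixed"], n, p=[0.5, 0.45, 0.05]),
        "age": np.round(age, 2),
        "sex": np.where(sex == 1, "male", "female"),
        "ymrs": np.round(np.abs(rng.normal(3.2, 4.7, n)), 1),
        "madrs": np.round(np.abs(rng.normal(11.5, 10.2, n)), 1),
        "panss": np.round(rng.normal(41.5, 13.0, n), 1),
        "duration": np.round(np.abs(rng.normal(12.0, 8.0, n)), 1),
        "mood_state": rng.choice(["euthymic", "depressive", "manic"], n, p=[0.6, 0.3, 0.1]),
        "med_atypical": rng.random(n) < 0.6,
        "med_antidep": rng.random(n) < 0.4,
        "med_moodstab": rng.random(n) < 0.7,
        "mean_fd": np.round(rng.uniform(0.02, 0.18, n), 4),
    })

    # --- features ---------------------------------------------------------
    X = rng.normal(0.0, config.noise_sd, size=(n, n_edges))
    planted = np.sort(rng.choice(n_edges, config.n_informative_edges, replace=False))
    signs = rng.choice([-1.0, 1.0], config.n_informative_edges)
    is_high = (episodes == "high").astype(float)
    # shift groups by -/+ d*sd/2 so mean_high - mean_low = sign * d * sd
    X[:, planted] += np.outer(is_high - 0.5, signs * config.effect_size * config.noise_sd)

    if config.covariate_confounding != 0.0:
        age_z = (age - age.mean()) / age.std(ddof=0)
        sex_c = sex - sex.mean()
        u = rng.choice([-1.0, 1.0], n_edges)
        v = rng.choice([-1.0, 1.0], n_edges)
        X += config.covariate_confounding * (np.outer(age_z, u) + np.outer(sex_c, v))

    parcellation = Parcellation.uniform(config.n_regions)
    template = devectorize(np.zeros(n_edges), config.n_regions)
    from .features import vectorize  # descriptor construction only

    _, desc = vectorize(template, parcellation)
    features = FeatureMatrix(values=X, descriptors=desc,
                             subjects=pheno["subject_id"].tolist(), residualized=False)

    truth = pd.DataFrame({
        "feature_index": planted,
        "feature": [desc["feature"].iloc[k] for k in planted],
        "sign": signs.astype(int),
    })

    # --- cognition --------------------------------------------------------
    weights = {}
    for task in WLT_TASKS:
        w = rng.normal(0.0, 1.0, config.n_informative_edges)
        signal = (X[:, planted] - X[:, planted].mean(axis=0)) @ w
        var_sig = signal.var(ddof=0)
        if config.cognition_r2 > 0 and var_sig > 0:
            eps_var = var_sig * (1 - config.cognition_r2) / config.cognition_r2
            y = signal + rng.normal(0.0, np.sqrt(eps_var), n)
        else:
            w = np.zeros_like(w)
            y = rng.normal(0.0, 1.0, n)
        # present as Wechsler-style scaled scores (mean 10, SD 3); affine,
        # so R-squared against the planted edges is unchanged
        y_scaled = 10.0 + 3.0 * (y - y.mean()) / y.std(ddof=0)
        pheno[task] = np.round(y_scaled, 3)
        weights[task] = w

    return SynthCohort(phenotypes=pheno, features=features, parcellation=parcellation,
                       truth=truth, cognition_weights=weights, config=config)


# ---------------------------------------------------------------------------
# optional time-series path


def sample_timeseries(corr, T, rng, shrinkage=0.0):
    """Draw a T x R Gaussian series with the given target correlation.

    ``shrinkage`` in [0, 1] blends the target toward the identity,
    C <- (1 - s) C + s I, which is required whenever the raw target is not
    positive definite.
    """
    corr = np.asarray(corr, dtype=float)
    if shrinkage:
        corr = (1 - shrinkage) * corr + shrinkage * np.eye(corr.shape[0])
    eigmin = np.linalg.eigvalsh(corr).min()
    if eigmin <= 1e-10:
        raise ValueError(
            "target correlation matrix is not positive definite "
            f"(min eigenvalue {eigmin:.3g}); increase the shrinkage parameter")
    L = np.linalg.cholesky(corr)
    return rng.standard_normal((T, corr.shape[0])) @ L.T


def generate_timeseries(cohort: SynthCohort, config: SynthConfig, shrinkage="auto"):
    """Per-subject ROI time series whose sample correlations converge to the
    subject's target matrix tanh(z) implied by the cohort features.

    shrinkage="auto" picks, per subject, the smallest shrinkage on a coarse
    grid that makes the target positive definite; pass a float to fix it, or
    0 to require raw targets to be positive definite already.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0x7365)))
    R = config.n_regions
    out = {}
    for row, subject in enumerate(cohort.features.subjects):
        target = np.tanh(devectorize(cohort.features.values[row], R, diagonal=0.0))
        np.fill_diagonal(target, 1.0)
        if shrinkage == "auto":
            s_used = 0.0
            for s in (0.0, 0.1, 0.2, 0.3, 0.5, 0.7, 0.9):
                c = (1 - s) * target + s * np.eye(R)
                if np.linalg.eigvalsh(c).min() > 1e-6:
                    s_used = s
                    break
            else:
                s_used = 0.95
            series = sample_timeseries(target, config.ts_length, rng, shrinkage=s_used)
        else:
            series = sample_timeseries(target, config.ts_length, rng, shrinkage=float(shrinkage))
        out[subject] = pd.DataFrame(series, columns=[f"r{j + 1}" for j in range(R)])
    return out
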