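# Methods

This note documents the models, estimators, numerical conventions and
design choices behind `neurostab`, and what the synthetic experiments do
and do not establish.

## Feature construction

Connectivity features are Pearson correlations between ROI time series,
mapped through Fisher's transform z = atanh(r). Correlations are clipped
to |r| ≤ 1 − 1e−7 before the transform so duplicated signals produce a
finite z rather than ±∞. Vectorisation takes the strict upper triangle in
row-major order with 1-based region indices; `devectorize` inverts it
exactly, and each edge descriptor carries the network pair of its two
regions from the parcellation lookup (eight networks: MFN, FPN, DMN, SC,
MON, VisI, VisII, VA). Asymmetry beyond 1e−8 is rejected rather than
symmetrised, since it indicates an upstream error.

Motion QC keeps subjects with mean framewise displacement ≤ 0.2 mm; the
boundary subject is kept (the exclusion rule is strictly "> 0.2 mm").

Morphometric columns (regional volume and cortical thickness), when
supplied, are z-scored before being pooled with connectivity z-values so
that the mutual-information discretisation is not dominated by scale
differences between feature kinds.

Age/sex control fits one ordinary-least-squares model per feature on
[1, age, sex] and keeps the residuals. `mode="paper"` fits on the full
sample — matching the published procedure, which controlled covariates
once before any selection — while `mode="fold_safe"` estimates the
coefficients on training subjects only and applies them to held-out
subjects, for users who want leakage-free covariate control inside
cross-validation.

## Mutual information and mRMR

The MI estimator is the plug-in estimate on discretised states, in bits.
The default discretisation (`sd3`) cuts each feature at mean ± one sample
SD into states {−1, 0, 1}, with values at a cut assigned to the outer
state; an equal-frequency quantile scheme is available for sensitivity
analysis. Constant vectors map to a single state and carry zero
information. The ranking is invariant to the logarithm base.

Greedy selection maximises the mutual-information quotient
MIQ(x) = V(x) / W(x) with V the relevance MI(x, y) and W the mean MI
between x and the already-selected set. Three conventions close gaps the
quotient leaves open:

- the first feature is chosen by pure relevance (W is undefined for an
  empty set);
- candidates with W = 0 exactly are treated as infinite-quotient and
  ordered among themselves by relevance;
- all remaining ties break toward the lower feature index.

Redundancy is accumulated against the *selected set*, not the whole pool:
against the whole pool the quotient would be a fixed per-feature constant
and selection would never respond to what has already been chosen. Using
the mean rather than the sum of pairwise MI changes nothing at any given
step (the selected-set size is constant across candidates) but keeps W on
the scale of a single MI value.

`mrmr_brute_oracle` re-evaluates the full quotient for every candidate at
every step with scalar MI calls and no caching. It is deliberately naive
and serves as the independent cross-check: the production selector matches
it exactly on random instances (both paths accumulate MI cell
contributions in the same order, so even near-ties resolve identically).

## Bootstrap stability selection

Each of B resamples draws ⌊0.9 n⌋ subjects with replacement (88 of 98 at
the reference cohort size; subsampling without replacement is available),
runs mRMR for K_per_run = 50 features, and increments the count of every
selected feature. Resamples that lose a class are redrawn and counted; a
redraw rate above 10% triggers a diagnostic warning. The threshold grid is
expressed as fractions of B — 15% to 95% in 5% steps, i.e. 150…950 at
B = 1000 — and the accumulated set at threshold t is {features with
count > t} (strictly greater, so a feature exactly at the threshold is
excluded). Sets are nested and non-increasing in t by construction.
Thresholds whose set exceeds ⌊2n/3⌋ features (the largest outer-training
fold) or is empty are inadmissible; 65 features at n = 98.

K_per_run is not identifiable from the published description; 50 is the
default and the threshold sweep absorbs its choice. Note that at desk
scale (hundreds rather than tens of thousands of candidate features) the
counts of pure-noise features are far from uniform: resamples share most
of their subjects, so features that are spuriously associated with the
labels in the given sample are selected again and again, and null count
distributions are heavy-tailed (maxima of 0.7–0.9 B are normal). This
matters for interpretation; see "Selection-induced optimism" below.

## Nested cross-validation

Per repeat: a stratified 3-fold outer split (per-repeat fold seeds derive
from the master seed through a documented counter scheme,
SeedSequence((seed, repeat))). In each outer training fold the accumulated
features are re-ranked by mRMR on the training rows only and the top 80%
kept (the published pipeline re-selects inside training folds but does not
state the retained count; 0.8 is the default and is configurable). The
RBF-SVM is tuned by stratified 10-fold inner CV over
C ∈ {0.01, 0.1, 1, 10, 100} × γ ∈ {0.25, 0.5, 1, 2, 4} / (p · Var X),
selecting the first grid point with maximal inner accuracy, then refitted
on the whole training fold. Outer-test accuracy, sensitivity (positive
class = the "more occurrences" group, or BDI), specificity and AUC (rank /
Mann–Whitney form, ties at ½) are averaged over the three folds; repeats
are summarised as mean ± SD. No class weighting is applied (the 55/43
imbalance is mild, and the reference procedure reports plain accuracy).

The best threshold maximises mean accuracy; exact ties go to the larger
threshold, i.e. the smaller feature set. Major features are those retained
in a majority of outer folds in strictly more than 90% of repeats
("any"/"all"-fold variants are available); each carries the sign of
(mean in positive class − mean in negative class) and its network pair.
Per-threshold performances are compared with pooled-variance independent
t tests on the per-repeat accuracies.

## Statistics

- Cognition regression: OLS of each word-list-test scaled score on all
  selected edges jointly, complete cases per task, requiring n > p + 1;
  reported as R² with the overall-F p value and BH q across the five tasks.
- Confound screen: Pearson r (illness duration, YMRS, MADRS, PANSS),
  pooled-variance t (medication flags), one-way ANOVA (mood state), with
  BH-FDR applied within each variable's family of feature tests.
  Degenerate groups are skipped with warnings.
- Demographics: pooled-variance (Student) t tests, not Welch, and
  chi-square without continuity correction — these are the conventions
  that reproduce the published worked examples (age p ≈ 0.0069 from the
  printed summaries 34.05 ± 14.386 (n=43) vs 41.45 ± 12.176 (n=55); sex
  p ≈ 0.0226 from counts 8/35 vs 22/33). A summary-statistics entry point
  accepts printed means/SDs/counts directly.
- BH-FDR uses the step-up procedure with monotonicity enforcement; the
  test suite checks it against a literal step-up oracle.

## Synthetic cohorts

`SynthConfig` defaults encode the reference study design: groups of 43
(low-episode) and 55 (high-episode) subjects; 30 regions (435 edges) for
desk-scale work, 268 regions (35,778 edges) for full scale; 10 planted
differential edges; age ~ N(38, 13²) truncated to [18, 70], sex ~
Bernoulli(0.3 male); within-group feature SD 0.3 on the z-scale (a typical
between-subject spread for Fisher-z connectivity). Features are drawn
directly as Gaussians on the residual z-scale — the scale on which
selection and classification operate — with planted edges shifted by
±d·SD/2 per group so the standardised group difference is exactly the
configured Cohen's d and the sign encodes which group is higher. Age/sex
confounding, when enabled, adds the standardised covariates to every
feature with a per-feature random sign. Cognition scores are y = Xw + ε
over the planted edges with the noise variance solved in closed form from
the realised Var(Xw), so Var(Xw)/Var(y) equals the configured R² exactly
in the generating equation; scores are presented as Wechsler-style scaled
scores (mean 10, SD 3), an affine map that leaves R² unchanged.

An optional slower path generates Gaussian ROI time series whose target
correlation per subject is tanh of the subject's z-matrix. Random z
matrices of this size are generally not positive definite, so the
generator shrinks the target toward the identity — automatically choosing
the smallest shrinkage on a coarse grid, or a user-fixed value — and
refuses non-positive-definite targets otherwise, with an error that says
to increase the shrinkage. Shrinkage rescales the off-diagonal structure
but preserves its pattern, so features recomputed from the series
correlate > 0.9 with the cohort's feature matrix at T = 1000.

What the generator does *not* emulate: scanner artefacts, head motion,
hemodynamics, autocorrelated time series, network-structured covariance
between edges, or heavy-tailed clinical scores. Passing tests on these
cohorts demonstrate the correctness and calibration of the machinery, not
classification performance on real connectomes.

## Selection-induced optimism (known limitation)

The published procedure runs the bootstrap-mRMR selection on the full
sample before cross-validation, and its authors note the resulting double
dipping. The consequence is quantified here on synthetic cohorts: on a
cohort with no group effect at all (n = 98, 435 features, B = 200), the
best-threshold nested-CV accuracy is ~0.74 rather than 0.5, because the
features that pass a selection-count threshold are partly those with
spurious full-sample label association, and the outer test folds contain
the very subjects that made those features look stable. The same
mechanism pulls extra stable-noise features into the major-feature set in
planted-signal runs, and rewards *larger* leaky feature sets when choosing
the best threshold. The effect grows as the candidate pool shrinks (it is
mild at tens of thousands of features, strong at hundreds) — consistent
with the near-chance accuracy the original procedure reported on its own
age-split control at full scale. Fold-safe covariate residualisation is
provided, and the per-fold inner re-selection is leakage-free; the
full-sample *selection* step is retained deliberately because it is the
procedure being modelled. Absolute accuracies from this pipeline should
therefore be read as descriptive of that procedure, and null-cohort runs
(effect_size = 0) are the recommended way to estimate its optimism for
any given configuration.

## Problem sizes and reproducibility

Desk-scale runs use 30 regions (435 edges), B = 200, 20 CV repeats; the
quick replication studies use B = 60 with 2 repeats on a 3-point
threshold grid; cognition calibration uses 50 cohorts at n = 98. One
master seed fans out to named per-stage seeds (synth, bootstrap, cv)
through SeedSequence; identical configs and seeds give bit-identical
outputs, and every output CSV is stamped with a hash of the run manifest.
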