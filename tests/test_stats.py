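"""Cognition regression, BH-FDR, confound screens, and demographics."""

import numpy as np
import pandas as pd
import pytest

from neurostab import (
    SynthConfig,
    confound_screen,
    fdr_bh,
    generate_cohort,
    group_compare_demographics,
    regress_cognition,
    sex_chi_square,
    two_sample_t_from_summary,
)


def bh_stepup_oracle(p):
    """Literal BH step-up: q_(i) = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q[idx] = min(running, 1.0)
    return q


class TestRegression:
    def test_score_equal_to_feature_r2_one(self, rng):
        X = rng.normal(size=(50, 3))
        res = regress_cognition(X, X[:, 1])
        assert res.r2 == pytest.approx(1.0, abs=1e-10)

    def test_null_r2_small_at_large_n(self, rng):
        X = rng.normal(size=(2000, 5))
        res = regress_cognition(X, rng.normal(size=2000))
        assert res.r2 < 0.01  # expectation p/(n-1) ~ 0.0025

    def test_r2_equals_one_minus_sse_over_sst(self, rng):
        import statsmodels.api as sm

        X = rng.normal(size=(60, 4))
        y = X @ rng.normal(size=4) + rng.normal(size=60)
        res = regress_cognition(X, y)
        fit = sm.OLS(y, sm.add_constant(X)).fit()
        sse = np.sum(fit.resid ** 2)
        sst = np.sum((y - y.mean()) ** 2)
        assert res.r2 == pytest.approx(1 - sse / sst, abs=1e-10)

    def test_adding_feature_never_decreases_r2(self, rng):
        X = rng.normal(size=(80, 3))
        y = X[:, 0] + rng.normal(size=80)
        r2_small = regress_cognition(X[:, :2], y).r2
        r2_big = regress_cognition(X, y).r2
        assert r2_big >= r2_small - 1e-12

    def test_dimensionality_cap_error(self, rng):
        with pytest.raises(ValueError, match="cap"):
            regress_cognition(rng.normal(size=(10, 9)), rng.normal(size=10))

    def test_missing_scores_dropped_and_counted(self, rng):
        X = rng.normal(size=(40, 2))
        y = rng.normal(size=40)
        y[[3, 7]] = np.nan
        res = regress_cognition(X, y)
        assert res.n == 38 and res.n_dropped == 2

    def test_parameter_recovery_at_study_scale(self):
        """Cognition generated at true R² = 0.6 (n = 98, 10 edges) is
        recovered by OLS on the planted edges, mean over 50 cohorts."""
        est = []
        for seed in range(50):
            co = generate_cohort(SynthConfig(n_regions=30, n_informative_edges=10,
                                             cognition_r2=0.6, seed=seed))
            X = co.features.values[:, co.truth["feature_index"]]
            y = co.phenotypes["wlt_retention"].to_numpy()
            est.append(regress_cognition(X, y).r2)
        assert np.mean(est) == pytest.approx(0.6, abs=0.1)


class TestFdrBH:
    def test_hand_applied_example(self):
        q = fdr_bh([0.005, 0.03, 0.04])
        assert np.allclose(q, [0.015, 0.04, 0.04], atol=1e-12)

    def test_single_p_unchanged(self):
        assert fdr_bh([0.037])[0] == pytest.approx(0.037)

    def test_all_equal_stay_equal(self):
        assert np.allclose(fdr_bh([0.2, 0.2, 0.2, 0.2]), 0.2)

    def test_q_at_least_p(self, rng):
        p = rng.uniform(size=50)
        assert np.all(fdr_bh(p) >= p - 1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.2])

    def test_matches_stepup_oracle_on_random_vectors(self, rng):
        for _ in range(100):
            p = rng.uniform(size=rng.integers(1, 40))
            assert np.allclose(fdr_bh(p), bh_stepup_oracle(p), atol=1e-12)


class TestConfoundScreen:
    def test_planted_confound_flagged(self, rng):
        n = 98
        madrs = rng.normal(11, 10, n)
        feats = pd.DataFrame({
            "edge_a": 0.9 * (madrs - madrs.mean()) / madrs.std() + rng.normal(0, 0.44, n),
            "edge_b": rng.normal(size=n),
        })
        clinical = pd.DataFrame({"madrs": madrs})
        rep = confound_screen(feats, clinical, continuous=("madrs",))
        row = rep[(rep["feature"] == "edge_a")].iloc[0]
        assert row["q"] < 0.05

    def test_null_family_flag_rate_bounded(self, rng):
        """Independent features: families with any BH flag occur at no more
        than roughly the nominal FDR level across simulations."""
        flags = 0
        sims = 200
        for _ in range(sims):
            feats = pd.DataFrame(rng.normal(size=(40, 5)),
                                 columns=[f"f{j}" for j in range(5)])
            clinical = pd.DataFrame({"ymrs": rng.normal(size=40)})
            rep = confound_screen(feats, clinical, continuous=("ymrs",))
            flags += int((rep["q"] < 0.05).any())
        assert flags / sims <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / sims)

    def test_degenerate_medication_flag_skipped(self, rng):
        feats = pd.DataFrame({"f": rng.normal(size=20)})
        clinical = pd.DataFrame({"med": [True] * 20})
        with pytest.warns(UserWarning, match="single level"):
            rep = confound_screen(feats, clinical, binary=("med",))
        assert len(rep) == 0

    def test_small_categorical_level_dropped(self, rng):
        feats = pd.DataFrame({"f": rng.normal(size=21)})
        clinical = pd.DataFrame({"mood": ["euthymic"] * 10 + ["depressive"] * 10 + ["manic"]})
        with pytest.warns(UserWarning, match="manic"):
            rep = confound_screen(feats, clinical, categorical=("mood",))
        assert rep.iloc[0]["kind"] == "F"


class TestDemographics:
    def test_age_summary_reproduces_published_p(self):
        t, p = two_sample_t_from_summary(34.05, 14.386, 43, 41.45, 12.176, 55)
        assert p == pytest.approx(0.0069, abs=2e-4)

    def test_sex_counts_reproduce_published_p(self):
        _, p = sex_chi_square([[8, 35], [22, 33]])
        assert p == pytest.approx(0.0226, abs=2e-4)

    def test_identical_groups_p_one(self, rng):
        half = pd.DataFrame({
            "age": rng.uniform(20, 60, 30), "ymrs": rng.uniform(0, 10, 30),
            "sex": ["male"] * 10 + ["female"] * 20,
        })
        pheno = pd.concat([half.assign(grp="a"), half.assign(grp="b")],
                          ignore_index=True)
        rep = group_compare_demographics(pheno, "grp", continuous=("age", "ymrs"))
        assert np.allclose(rep["p"], 1.0)

    def test_raw_equals_summary_path(self, rng):
        pheno = pd.DataFrame({"age": rng.normal(40, 12, 60),
                              "grp": ["x"] * 25 + ["y"] * 35})
        rep = group_compare_demographics(pheno, "grp", continuous=("age",))
        row = rep.iloc[0]
        _, p = two_sample_t_from_summary(row["x_mean"], row["x_sd"], 25,
                                         row["y_mean"], row["y_sd"], 35)
        assert p == pytest.approx(row["p"], abs=1e-10)

    def test_missing_variable_warns_and_omits(self, rng):
        pheno = pd.DataFrame({"age": rng.normal(40, 10, 20), "grp": ["a", "b"] * 10})
        with pytest.warns(UserWarning, match="panss"):
            rep = group_compare_demographics(pheno, "grp", continuous=("age", "panss"))
        assert rep["variable"].tolist() == ["age"]
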