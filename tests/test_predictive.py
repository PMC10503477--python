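"""Bayesian trait prediction: size score, feature assembly, calibration."""
import numpy as np
import pandas as pd
import pytest

from pigait.bayes import ConjugateLinearModel
from pigait.cohort import generate_cohort
from pigait.config import CohortConfig
from pigait.errors import DomainError
from pigait.normalization import normalize_stride_table
from pigait.predictive import (
    FEATURE_NAMES,
    age_stall_experiment,
    assemble_features,
    build_feature_table,
    compare_predictions,
    predict,
    size_score,
    train,
    validate,
)


class TestSizeScore:
    def test_rank_correlates_with_mass_on_isometric_cohort(self, zero_noise_cohort):
        from scipy.stats import spearmanr

        s = size_score(zero_noise_cohort.piglets)
        masses = zero_noise_cohort.piglets.set_index("piglet_id")["birth_mass_kg"]
        assert spearmanr(s[masses.index], masses).statistic == pytest.approx(1.0)

    def test_identical_animals_score_zero(self):
        pg = pd.DataFrame(
            {"piglet_id": list("abc"), "seg_femur_m": 0.07, "seg_tibia_m": 0.08}
        )
        with pytest.warns(UserWarning):
            s = size_score(pg)
        assert np.allclose(s, 0.0)

    def test_enlarging_one_animal_raises_only_its_score(self):
        pg = pd.DataFrame(
            {
                "piglet_id": list("abcd"),
                "seg_femur_m": [0.07, 0.071, 0.069, 0.07],
                "seg_tibia_m": [0.08, 0.081, 0.079, 0.08],
            }
        )
        s0 = size_score(pg)
        pg2 = pg.copy()
        pg2.loc[3, ["seg_femur_m", "seg_tibia_m"]] *= 2.0
        s1 = size_score(pg2)
        assert s1["d"] > s0["d"]
        assert s1["d"] == s1.max()


class TestAssemble:
    def test_length_34_and_fixed_order(self):
        spat = {k: 0.5 for k in FEATURE_NAMES[1:10]}
        post = {k: 1.5 for k in FEATURE_NAMES[10:22]}
        vec = assemble_features(spat, post, np.zeros(12), sex=1)
        assert vec.shape == (34,)
        assert vec[0] == 1.0 and vec[1] == 0.5 and vec[10] == 1.5

    def test_missing_block_named(self):
        spat = {k: 0.5 for k in FEATURE_NAMES[1:9]}  # one missing
        post = {k: 1.5 for k in FEATURE_NAMES[10:22]}
        with pytest.raises(DomainError, match="spatiotemporal"):
            assemble_features(spat, post, np.zeros(12), sex=0)

    def test_nan_rejected(self):
        spat = {k: 0.5 for k in FEATURE_NAMES[1:10]}
        post = {k: 1.5 for k in FEATURE_NAMES[10:22]}
        spat["froude_speed"] = np.nan
        with pytest.raises(DomainError):
            assemble_features(spat, post, np.zeros(12), sex=0)

    def test_feature_table_from_cohort(self, small_cohort):
        norm = normalize_stride_table(small_cohort.strides)
        feats, pca = build_feature_table(norm, small_cohort.joint_traces,
                                         small_cohort.piglets)
        assert list(FEATURE_NAMES) == [c for c in feats.columns if c in FEATURE_NAMES]
        assert len(feats) == len(norm)
        assert pca["loadings"].shape == (96, 12)


def _linear_data(rng, n, p=6, sigma=0.0):
    X = rng.normal(size=(n, p))
    beta = np.zeros(p)
    beta[:3] = [1.5, -2.0, 0.7]
    y = X @ beta + 3.0 + sigma * rng.normal(size=n)
    return X, y, beta


class TestConjugateModel:
    def test_recovers_exact_linear_target(self, rng):
        # N(0,1) priors on standardized slopes shrink estimates by O(p/n);
        # recovery is exact up to that factor
        X, y, beta = _linear_data(rng, 200, sigma=1e-8)
        m = ConjugateLinearModel().fit(X, y)
        summ = m.coefficient_summary()
        for j in range(len(beta)):
            tol = max(2 * summ.sd[j], 0.02 * abs(beta[j]) + 1e-6)
            assert abs(summ.mean[j] - beta[j]) < tol
        mean, lo, hi = m.predict(X[:10])
        assert np.max(np.abs(mean - y[:10])) < 0.05

    def test_null_target_intervals_cover_zero(self, rng):
        X = rng.normal(size=(300, 8))
        y = rng.normal(size=300)
        m = ConjugateLinearModel().fit(X, y)
        covered = 0
        for j in range(8):
            lo, hi = m.coefficient_interval(j, level=0.95)
            covered += lo <= 0 <= hi
        assert covered >= 7

    def test_duplicating_data_shrinks_posterior_sd(self, rng):
        X, y, _ = _linear_data(rng, 150, sigma=1.0)
        m1 = ConjugateLinearModel().fit(X, y)
        m2 = ConjugateLinearModel().fit(np.vstack([X, X]), np.concatenate([y, y]))
        ratio = m2.coefficient_summary().sd / m1.coefficient_summary().sd
        assert np.median(ratio) == pytest.approx(1 / np.sqrt(2), abs=0.08)

    def test_affine_feature_rescaling_invariance(self, rng):
        X, y, _ = _linear_data(rng, 120, sigma=0.5)
        m1 = ConjugateLinearModel().fit(X, y)
        X2 = X.copy()
        X2[:, 0] = 100.0 * X2[:, 0] - 7.0
        m2 = ConjugateLinearModel().fit(X2, y)
        Xq = X[:15]
        X2q = X2[:15]
        p1, _, _ = m1.predict(Xq)
        p2, _, _ = m2.predict(X2q)
        assert np.max(np.abs(p1 - p2)) < 1e-8

    def test_constant_target_rejected(self, rng):
        with pytest.raises(DomainError):
            ConjugateLinearModel().fit(rng.normal(size=(20, 3)), np.ones(20))

    def test_narrower_interval_at_lower_level(self, rng):
        X, y, _ = _linear_data(rng, 100, sigma=1.0)
        m = ConjugateLinearModel().fit(X, y)
        _, lo9, hi9 = m.predict(X[:5], level=0.9)
        _, lo5, hi5 = m.predict(X[:5], level=0.5)
        assert np.all(hi5 - lo5 < hi9 - lo9)


class TestTrainPredictValidate:
    def _features(self, rng, n):
        X = rng.normal(size=(n, 34))
        X[:, 0] = (X[:, 0] > 0).astype(float)  # sex is binary
        return X

    def test_interval_coverage_calibrated(self, rng):
        # well-specified setup: coefficients drawn from the prior scale
        X = self._features(rng, 294)
        beta = rng.normal(size=34)
        y = X @ beta + rng.normal(size=294)
        model = train(X, y, target="mass")
        Xh = self._features(rng, 500)
        yh = Xh @ beta + rng.normal(size=500)
        report = validate(model, Xh, yh, level=0.9)
        assert report["coverage"] == pytest.approx(0.90, abs=0.03)

    def test_zero_noise_rmse_near_zero(self, rng):
        # shrinkage-limited: relative error O(p/n) of the response scale
        X = self._features(rng, 300)
        beta = rng.normal(size=34)
        y = X @ beta + 5.0
        model = train(X, y)
        report = validate(model, X[:50], y[:50])
        assert report["rmse"] < 0.02 * np.std(y)

    def test_shuffled_actuals_destroy_coverage(self, rng):
        X = self._features(rng, 294)
        beta = 3.0 * rng.normal(size=34)
        y = X @ beta + 0.1 * rng.normal(size=294)
        model = train(X, y)
        Xh = self._features(rng, 300)
        yh = Xh @ beta + 0.1 * rng.normal(size=300)
        good = validate(model, Xh, yh, level=0.9)["coverage"]
        bad = validate(model, Xh, rng.permutation(yh), level=0.9)["coverage"]
        assert bad < good - 0.3

    def test_reproducible_summaries(self, rng):
        X = self._features(rng, 100)
        y = X @ rng.normal(size=34) + rng.normal(size=100)
        t1 = train(X, y, seed=5).coefficient_table()
        t2 = train(X, y, seed=5).coefficient_table()
        pd.testing.assert_frame_equal(t1, t2)


class TestComparePredictions:
    def test_sga_predicted_heavier_when_kinematics_are_aga_like(self):
        # dimensionless kinematics carry no size signal, so a model trained
        # on AGA strides predicts near the AGA mass for SGA strides too
        cfg = CohortConfig(n_aga=12, n_sga=8, age_mode="cross_sectional",
                           strides_per_recording=4)
        data = generate_cohort(cfg, 17)
        norm = normalize_stride_table(data.strides)
        aga, sga = norm[norm.category == "AGA"], norm[norm.category == "SGA"]
        fa, pca = build_feature_table(aga, data.joint_traces, data.piglets)
        fs, _ = build_feature_table(sga, data.joint_traces, data.piglets, pca=pca)
        model = train(fa, fa["actual_mass"], target="mass")
        preds = predict(model, fs)
        actual = fs.set_index("stride_id")["actual_mass"]
        groups = fs.set_index("stride_id")["category"]
        table = compare_predictions(preds, actual, groups)
        row = table[table["group"] == "SGA"].iloc[0]
        assert row["mean_diff"] > 0.3       # predicted ~AGA mean, actual ~0.7 kg
        assert row["frac_positive"] > 0.9

    def test_aga_heldout_unbiased(self, rng):
        X = rng.normal(size=(200, 34))
        beta = rng.normal(size=34)
        y = X @ beta + 0.3 * rng.normal(size=200)
        model = train(X[:150], y[:150])
        preds = predict(model, X[150:])
        preds["stride_id"] = [f"s{i}" for i in range(50)]
        actual = pd.Series(y[150:], index=preds["stride_id"])
        groups = pd.Series("AGA", index=preds["stride_id"])
        table = compare_predictions(preds, actual, groups)
        assert abs(table.iloc[0]["mean_diff"]) < 0.2

    def test_unmatched_id_rejected(self):
        preds = pd.DataFrame({"stride_id": ["a"], "posterior_mean": [1.0]})
        with pytest.raises(DomainError):
            compare_predictions(preds, pd.Series({"b": 1.0}), pd.Series({"b": "AGA"}))

    def test_empty_group_skipped(self):
        preds = pd.DataFrame({"stride_id": ["a", "b"], "posterior_mean": [1.0, 2.0]})
        actual = pd.Series({"a": 1.0, "b": 1.5})
        groups = pd.Series({"a": "AGA", "b": "AGA"})
        table = compare_predictions(preds, actual, groups)
        assert list(table["group"]) == ["AGA"]


class TestAgeStall:
    BASE = dict(n_aga=30, n_sga=10, age_mode="cross_sectional",
                age_range=(1.0, 10.0), strides_per_recording=4)

    def test_fraction_in_unit_interval(self):
        res = age_stall_experiment(CohortConfig(**self.BASE), 1)
        assert 0.0 <= res["fraction_underestimated"] <= 1.0

    def test_stall_biases_age_low_relative_to_null(self):
        # average over replicate cohorts: with a 4 h behavioural stall the
        # age of older SGA strides is predominantly underestimated
        nulls, stalls = [], []
        for seed in range(6):
            nulls.append(
                age_stall_experiment(CohortConfig(**self.BASE), seed)[
                    "fraction_underestimated"]
            )
            stalls.append(
                age_stall_experiment(
                    CohortConfig(**self.BASE, sga_stall_age=4.0), seed
                )["fraction_underestimated"]
            )
        assert np.mean(stalls) > np.mean(nulls) + 0.15
        assert np.mean(stalls) > 0.6
        assert 0.25 < np.mean(nulls) < 0.75
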