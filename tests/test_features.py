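"""First-order features, rank statistics, feature selection, classifier."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from qsmhead import features, phantom


def _brute_force_quartiles(x):
    """Sort-based linear-interpolation percentiles, independent of numpy."""
    s = np.sort(np.asarray(x, float))
    n = len(s)

    def pct(q):
        pos = q / 100.0 * (n - 1)
        lo = int(np.floor(pos))
        hi = int(np.ceil(pos))
        frac = pos - lo
        return s[lo] * (1 - frac) + s[hi] * frac

    return pct(25), pct(50), pct(75)


class TestFirstOrderFeatures:
    def test_constant_region(self):
        chi = np.full((4, 4, 4), 0.2)
        f = features.extract_first_order_features(chi, np.ones((4, 4, 4), bool))
        assert f["std_all"] == pytest.approx(0, abs=1e-12)
        assert f["iqr_all"] == pytest.approx(0, abs=1e-12)
        assert f["icv_all"] == pytest.approx(0, abs=1e-12)
        assert f["max_all"] == f["min_all"] == pytest.approx(0.2)

    def test_hand_computed_percentiles(self):
        x = np.array([1, 2, 3, 4, 5, 6, 7, 8], float).reshape(2, 2, 2)
        f = features.extract_first_order_features(x, np.ones((2, 2, 2), bool))
        assert f["p25_all"] == pytest.approx(2.75)
        assert f["p75_all"] == pytest.approx(6.25)
        assert f["iqr_all"] == pytest.approx(3.5)
        assert f["icv_all"] == pytest.approx(3.5 / 9.0)

    def test_all_negative_gives_empty_positive_subset(self):
        chi = -np.ones((3, 3, 3))
        f = features.extract_first_order_features(chi, np.ones((3, 3, 3), bool))
        assert np.isnan(f["mean_pos"])
        assert f["mean_neg"] == pytest.approx(-1.0)

    def test_volume_uses_voxel_size(self):
        m = np.zeros((4, 4, 4), bool)
        m[:2, :2, :2] = True
        f = features.extract_first_order_features(np.ones((4, 4, 4)), m,
                                                  voxel_size=(0.75, 0.75, 2.5))
        assert f["volume_mm3"] == pytest.approx(8 * 0.75 * 0.75 * 2.5)

    def test_quartile_oracle_agreement(self):
        # spec invariant: agree with a sort-based oracle on random vectors
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = rng.integers(5, 60)
            x = rng.standard_normal(n)
            p25, med, p75 = _brute_force_quartiles(x)
            v = features._stats_vector(x, "quartile_dispersion")
            assert v["p25"] == pytest.approx(p25, abs=1e-12)
            assert v["median"] == pytest.approx(med, abs=1e-12)
            assert v["p75"] == pytest.approx(p75, abs=1e-12)
            assert v["iqr"] == pytest.approx(p75 - p25, abs=1e-12)
            if abs(p75 + p25) > 1e-9:
                assert v["icv"] == pytest.approx((p75 - p25) / (p75 + p25),
                                                 rel=1e-9)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            features.extract_first_order_features(np.ones((3, 3, 3)),
                                                  np.zeros((3, 3, 3), bool))


class TestKruskalWallis:
    def _tables(self, groups):
        return {name: pd.DataFrame({"f": vals}) for name, vals in groups.items()}

    def test_identical_distributions_null(self):
        g = self._tables({"a": [1, 2, 3, 4], "b": [4, 3, 2, 1],
                          "c": [2, 1, 4, 3]})
        rep = features.compare_gtv_vs_reference(g)
        assert rep.loc[0, "H"] == pytest.approx(0.0, abs=1e-9)
        assert rep.loc[0, "p"] > 0.05

    def test_separated_groups_significant(self):
        g = self._tables({"a": [1, 2, 3], "b": [10, 11, 12],
                          "c": [20, 21, 22]})
        rep = features.compare_gtv_vs_reference(g)
        assert rep.loc[0, "H"] == pytest.approx(7.2, abs=1e-9)
        assert rep.loc[0, "p"] < 0.05
        assert rep.loc[0, "significant"]

    def test_shift_invariance_of_ranks(self):
        base = {"a": [1.0, 2, 3.5], "b": [2.5, 4, 5], "c": [0.5, 3, 6]}
        shifted = {k: [v + 100 for v in vals] for k, vals in base.items()}
        h1 = features.compare_gtv_vs_reference(self._tables(base)).loc[0, "H"]
        h2 = features.compare_gtv_vs_reference(self._tables(shifted)).loc[0, "H"]
        assert h1 == pytest.approx(h2)

    def test_all_identical_marked_undefined(self):
        g = self._tables({"a": [1, 1, 1], "b": [1, 1, 1]})
        rep = features.compare_gtv_vs_reference(g)
        assert np.isnan(rep.loc[0, "H"])


class TestSpearman:
    def _table(self, feat, ki):
        return pd.DataFrame({"ki67": ki, "feat": feat})

    def test_identity_and_negation(self):
        ki = np.array([1.0, 3, 6, 9, 12, 20, 30])
        r = features.correlate_with_ki67(self._table(ki, ki), "feat")
        assert r["spearman_rho"] == pytest.approx(1.0)
        r2 = features.correlate_with_ki67(self._table(-ki, ki), "feat")
        assert r2["spearman_rho"] == pytest.approx(-1.0)

    def test_exact_p_matches_brute_force_n7(self):
        ki = np.arange(1.0, 8.0)
        feat = np.array([1, 2, 3, 4, 5, 7, 6], float)  # one discordant swap
        r = features.correlate_with_ki67(self._table(feat, ki), "feat")
        # independent brute force over all 7! permutations
        xr = stats.rankdata(feat)
        yr = stats.rankdata(ki)
        obs = stats.spearmanr(feat, ki)[0]
        count = 0
        for perm in itertools.permutations(range(7)):
            rho = stats.pearsonr(xr[list(perm)], yr)[0]
            if abs(rho) >= abs(obs) - 1e-12:
                count += 1
        assert r["p_exact"] == pytest.approx(count / 5040)

    def test_constant_feature_undefined(self):
        ki = np.arange(1.0, 8.0)
        r = features.correlate_with_ki67(self._table(np.ones(7), ki), "feat")
        assert np.isnan(r["spearman_rho"])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            features.correlate_with_ki67(
                self._table(np.arange(4.0), np.arange(4.0)), "feat")


class TestFeatureSelection:
    def _cohort(self, seed=0):
        rng = np.random.default_rng(seed)
        n = 60
        ki = rng.uniform(1, 30, n)
        e = rng.normal(0, 5.5, n)
        return pd.DataFrame({
            "patient_id": [f"P{i}" for i in range(n)],
            "ki67": ki,
            # shared noise makes each feature strongly Ki-67-linked while
            # keeping their mutual correlation below the redundancy cut
            "max_all": ki + e,                               # rho ~ +0.9
            "icv_all": -ki + e,                              # rho ~ -0.9
            "noise_a": rng.normal(size=n),
            "noise_b": rng.normal(size=n),
        })

    def test_two_strong_nonredundant_features_selected(self):
        tab = self._cohort()
        sel = features.select_classifier_features(tab, n_extra=0)
        assert set(sel) == {"max_all", "icv_all"}

    def test_redundant_second_feature_replaced(self):
        tab = self._cohort(1)
        tab["max_dup"] = tab["max_all"] + 1e-6  # rank-identical to max_all
        sel = features.select_classifier_features(tab, n_extra=0)
        assert "max_all" in sel or "max_dup" in sel
        assert not ({"max_all", "max_dup"} <= set(sel))

    def test_rfe_adds_third_feature(self):
        tab = self._cohort(2)
        sel = features.select_classifier_features(tab, n_extra=1)
        assert len(sel) == 3
        assert sel[2] not in sel[:2]

    def test_no_passing_features_rejected(self):
        rng = np.random.default_rng(3)
        tab = pd.DataFrame({"patient_id": list("abcdefgh"),
                            "ki67": rng.uniform(1, 30, 8),
                            "noise": rng.normal(size=8)})
        with pytest.raises(ValueError):
            features.select_classifier_features(tab)


class TestNestedCv:
    @pytest.fixture(scope="class")
    def separable(self):
        rng = np.random.default_rng(0)
        n = 24
        ki = np.r_[rng.uniform(0.5, 3.5, 11), rng.uniform(7, 20, 13)]
        high = (ki >= 5).astype(float)
        return pd.DataFrame({
            "patient_id": [f"P{i}" for i in range(n)],
            "ki67": ki,
            "max_all": high * 2.0 + rng.normal(0, 0.05, n),
            "icv_all": -high * 1.5 + rng.normal(0, 0.05, n),
        })

    def test_separable_cohort_perfect_loo(self, separable):
        rep = features.nested_cv_classify(separable, ["max_all", "icv_all"],
                                          models=("logistic", "random_forest"),
                                          seed=1)
        assert rep.metrics["logistic"]["accuracy"] == 1.0
        assert rep.metrics["random_forest"]["accuracy"] == 1.0

    def test_importances_normalized(self, separable):
        rep = features.nested_cv_classify(separable, ["max_all", "icv_all"],
                                          models=("svm",), seed=1)
        assert sum(rep.importances["svm"].values()) == pytest.approx(1.0)

    def test_report_schema_small_cohort(self):
        # 7 subjects, 4 high / 3 low
        rng = np.random.default_rng(5)
        ki = np.array([1.0, 2.0, 3.0, 7.0, 10.0, 15.0, 25.0])
        tab = pd.DataFrame({
            "patient_id": [f"P{i}" for i in range(7)],
            "ki67": ki,
            "max_all": (ki >= 5) * 1.0 + rng.normal(0, 0.2, 7),
            "icv_all": (ki >= 5) * -1.0 + rng.normal(0, 0.2, 7),
        })
        rep = features.nested_cv_classify(tab, ["max_all", "icv_all"],
                                          models=("logistic",), seed=0)
        m = rep.metrics["logistic"]
        for key in ("accuracy", "precision_high", "precision_low",
                    "recall_high", "recall_low", "f1_high", "f1_low"):
            assert key in m
        frame = rep.to_frame()
        assert "imp_max_all" in frame.columns

    def test_scaling_fit_inside_training_folds_only(self, separable,
                                                    monkeypatch):
        # no-leak instrumentation: every scaler fit during LOO must see
        # strictly fewer samples than the full cohort
        from sklearn.preprocessing import StandardScaler
        sizes = []
        orig = StandardScaler.fit

        def spy(self, X, y=None, **kw):
            sizes.append(len(X))
            return orig(self, X, y, **kw)

        monkeypatch.setattr(StandardScaler, "fit", spy)
        features.nested_cv_classify(separable, ["max_all", "icv_all"],
                                    models=("logistic",), seed=2)
        n = len(separable)
        loo_fits = [s for s in sizes if s != n]
        assert loo_fits and all(s < n for s in loo_fits)

    def test_single_class_rejected(self):
        tab = pd.DataFrame({"patient_id": list("abcde"),
                            "ki67": [10.0, 12, 14, 16, 18],
                            "max_all": np.arange(5.0)})
        with pytest.raises(ValueError):
            features.nested_cv_classify(tab, ["max_all"])


class TestCohortFeatureTable:
    def test_columns_and_determinism(self):
        c = phantom.generate_synthetic_cohort(10, 0.8, 0.0, seed=1)
        t = features.cohort_feature_table(c)
        assert "patient_id" in t.columns and "ki67" in t.columns
        assert "max_all" in t.columns and "icv_all" in t.columns
        t2 = features.cohort_feature_table(
            phantom.generate_synthetic_cohort(10, 0.8, 0.0, seed=1))
        pd.testing.assert_frame_equal(t, t2)
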