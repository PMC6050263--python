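import numpy as np
import pandas as pd
import pytest
from scipy import stats

from endofactor.evaluation import (ClassificationReport, compare_experiments,
                                   factor_associations,
                                   property_occurrence_by_group,
                                   svm_cv_accuracy)
from endofactor.ibp import PropertyAssignments


def _report(accs, experiment_id=""):
    return ClassificationReport(np.asarray(accs, float), 1 / 3, experiment_id)


class TestSVMCVAccuracy:
    def test_linearly_separable_classes(self, rng):
        centers = np.array([[0, 0], [8, 0], [0, 8]])
        y = np.repeat([0, 1, 2], 60)
        X = centers[y] + 0.3 * rng.normal(size=(180, 2))
        folds = np.arange(180) % 6
        rep = svm_cv_accuracy(X, y, folds)
        assert rep.mean_accuracy >= 0.99
        assert rep.chance_level == pytest.approx(1 / 3)

    def test_one_accuracy_per_fold(self, rng):
        X = rng.normal(size=(90, 5))
        y = np.arange(90) % 3
        rep = svm_cv_accuracy(X, y, np.arange(90) % 9)
        assert rep.per_fold_accuracy.shape == (9,)
        assert np.all((rep.per_fold_accuracy >= 0)
                      & (rep.per_fold_accuracy <= 1))

    def test_permuted_labels_stay_at_chance(self, rng):
        X = rng.normal(size=(300, 20))
        y = rng.permutation(np.arange(300) % 3)
        folds = np.arange(300) % 10
        rep = svm_cv_accuracy(X, y, folds)
        n_correct = int(round(rep.mean_accuracy * 300))
        lo, hi = stats.binom.interval(0.95, 300, 1 / 3)
        assert lo <= n_correct <= hi

    def test_single_class_training_fold_raises(self):
        X = np.random.default_rng(0).normal(size=(6, 2))
        y = np.array([0, 0, 0, 1, 1, 1])
        folds = np.array([0, 0, 0, 1, 1, 1])   # removing fold 1 leaves one class
        with pytest.raises(ValueError, match="single class"):
            svm_cv_accuracy(X, y, folds)

    def test_standardization_uses_training_fold_statistics_only(self, rng):
        """Each fold's accuracy must equal a manual pipeline whose scaler is
        fit on the training rows alone — including when the test fold holds
        gross outliers that would distort a leaky (train+test) scaler."""
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import LinearSVC

        centers = np.array([[0, 0], [5, 0], [0, 5]])
        y = np.repeat([0, 1, 2], 30)
        X = centers[y] + 0.3 * rng.normal(size=(90, 2))
        folds = np.arange(90) % 3
        X[folds == 0] += 1e4            # outliers confined to fold-0 test rows
        rep = svm_cv_accuracy(X, y, folds)
        for f in range(3):
            train, test = folds != f, folds == f
            scaler = StandardScaler().fit(X[train])
            clf = LinearSVC(C=1.0, loss="hinge", max_iter=20000,
                            random_state=0)
            clf.fit(scaler.transform(X[train]), y[train])
            manual = float(np.mean(
                clf.predict(scaler.transform(X[test])) == y[test]))
            assert rep.per_fold_accuracy[f] == manual

    def test_deterministic(self, rng):
        X = rng.normal(size=(60, 4))
        y = np.arange(60) % 3
        folds = np.arange(60) % 5
        r1 = svm_cv_accuracy(X, y, folds)
        r2 = svm_cv_accuracy(X, y, folds)
        np.testing.assert_array_equal(r1.per_fold_accuracy,
                                      r2.per_fold_accuracy)


class TestCompareExperiments:
    def test_identical_vectors_give_t0_p1(self):
        t, p = compare_experiments(_report([0.5, 0.5, 0.5]),
                                   _report([0.5, 0.5, 0.5]))
        assert (t, p) == (0.0, 1.0)

    def test_matches_textbook_welch_formula(self):
        a, b = np.array([0.6, 0.7]), np.array([0.1, 0.2])
        t, p = compare_experiments(_report(a), _report(b))
        va, vb = a.var(ddof=1) / 2, b.var(ddof=1) / 2
        t_hand = (a.mean() - b.mean()) / np.sqrt(va + vb)
        assert t == pytest.approx(t_hand, abs=1e-10)

    def test_reported_fold_summaries_are_clearly_separated(self):
        """Fold vectors with means 67.33/46.73 and sds 3.07/3.97 at m = 10
        must separate at p < 0.0001 (Welch t around 13)."""
        rng = np.random.default_rng(0)
        def simulate(mean, sd):
            v = rng.normal(size=10)
            v = (v - v.mean()) / v.std(ddof=1)
            return v * sd + mean
        t, p = compare_experiments(_report(simulate(67.33, 3.07) / 100),
                                   _report(simulate(46.73, 3.97) / 100))
        assert p < 1e-4
        assert t == pytest.approx(13.0, abs=0.5)

    def test_single_fold_raises(self):
        with pytest.raises(ValueError, match="folds"):
            compare_experiments(_report([0.5]), _report([0.4, 0.6]))


class TestFactorAssociations:
    def test_score_equal_to_theta_column_gives_r_one(self, rng):
        theta = rng.dirichlet(np.ones(3), size=100)
        scores = pd.DataFrame({"s": theta[:, 1]})
        res = factor_associations(theta, scores)
        r1 = [a for a in res if a.factor_id == 1][0]
        assert r1.r == pytest.approx(1.0, abs=1e-12)
        assert r1.p < 1e-50

    def test_independent_score_is_null(self, rng):
        theta = rng.dirichlet(np.ones(3), size=1000)
        scores = pd.DataFrame({"noise": rng.normal(size=1000)})
        for a in factor_associations(theta, scores):
            assert abs(a.r) < 0.1
            assert a.n == 1000

    def test_constant_score_flagged_undefined(self, rng):
        theta = rng.dirichlet(np.ones(2), size=50)
        res = factor_associations(theta, pd.DataFrame({"c": np.ones(50)}))
        assert all(a.undefined for a in res)
        assert all(np.isnan(a.r) for a in res)

    def test_missing_values_pairwise_complete(self, rng):
        theta = rng.dirichlet(np.ones(2), size=60)
        score = theta[:, 0] + 0.1 * rng.normal(size=60)
        score[:10] = np.nan
        res = factor_associations(theta, pd.DataFrame({"s": score}))
        assert res[0].n == 50
        assert res[0].r > 0.5

    def test_benjamini_hochberg_attaches_q(self, rng):
        theta = rng.dirichlet(np.ones(3), size=80)
        scores = pd.DataFrame({"a": rng.normal(size=80),
                               "b": theta[:, 0]})
        res = factor_associations(theta, scores, benjamini_hochberg=True)
        defined = [a for a in res if not a.undefined]
        assert all(a.q is not None and a.q >= a.p - 1e-12 for a in defined)


class TestPropertyOccurrence:
    def test_universal_property_counts_group_sizes(self):
        Z = np.ones((9, 1), np.int8)
        labels = np.repeat([0, 1, 2], 3)
        table = property_occurrence_by_group(
            PropertyAssignments(Z, ("p0",)), labels)
        assert table.loc[0, ["group0", "group1", "group2"]].tolist() == [3, 3, 3]
        assert table.loc[0, "exclusive_to"] == -1

    def test_shared_structure_has_no_exclusive_properties(self, tiny_cohort):
        gt = tiny_cohort.ground_truth
        ass = PropertyAssignments(
            gt.Z_true, tuple(f"p{j}" for j in range(gt.Z_true.shape[1])))
        table = property_occurrence_by_group(ass, tiny_cohort.clinical_labels)
        assert (table["exclusive_to"] == -1).mean() >= 0.75

    def test_empty_property_counts_zero_everywhere(self):
        Z = np.zeros((6, 1), np.int8)
        Z[0, 0] = 1   # construction requires a non-trivial matrix
        Z[0, 0] = 0
        table = property_occurrence_by_group(
            PropertyAssignments(Z, ("p0",)), np.zeros(6, int))
        assert table.loc[0, "group0"] == 0

    def test_misaligned_labels_raise(self):
        with pytest.raises(ValueError, match="align"):
            property_occurrence_by_group(
                PropertyAssignments(np.ones((3, 1), np.int8), ("p0",)),
                np.zeros(5, int))


class TestRunFullPipeline:
    def test_stage_errors_carry_the_stage_name(self):
        from endofactor.evaluation import run_full_pipeline
        from endofactor.prevalidation import PrevalidationConfig
        from endofactor.synthetic import SyntheticConfig
        from endofactor.ibp import IBPConfig
        from endofactor.lda import LDAConfig

        # m larger than the smallest class forces the pre-validation split
        # step to fail; the pipeline must name the failing stage
        cfg = SyntheticConfig(n_subjects=12, n_edges=8, n_properties_true=4,
                              n_factors_true=2, mean_active_properties=1.5,
                              seed=0)
        pcfg = PrevalidationConfig(m=10, seed=0,
                                   ibp_config=IBPConfig(n_sweeps=10, burn_in=5),
                                   lda_config=LDAConfig(k=2, n_sweeps=10,
                                                        burn_in=5))
        with pytest.raises(RuntimeError, match="prevalidate"):
            run_full_pipeline(cfg, pcfg)

    def test_report_bundle_contains_all_four_experiments(self):
        from endofactor.evaluation import EXPERIMENT_IDS, run_full_pipeline
        from endofactor.prevalidation import PrevalidationConfig
        from endofactor.synthetic import SyntheticConfig
        from endofactor.ibp import IBPConfig
        from endofactor.lda import LDAConfig

        cfg = SyntheticConfig(n_subjects=48, n_edges=15, n_properties_true=4,
                              n_factors_true=2, mean_active_properties=1.5,
                              noise_scale=0.2, dirichlet_concentration=0.3,
                              label_flip_rate=0.2, seed=3)
        pcfg = PrevalidationConfig(
            m=4, seed=2, refit_ibp_per_fold=False,
            ibp_config=IBPConfig(n_sweeps=40, burn_in=20),
            lda_config=LDAConfig(k=2, n_sweeps=60, burn_in=30))
        bundle = run_full_pipeline(cfg, pcfg)
        assert set(bundle["reports"]) == set(EXPERIMENT_IDS)
        # the theta-only experiment sees exactly k features per subject
        theta = bundle["prevalidation"].theta_prevalidated
        assert theta.shape == (48, 2)
        assert set(bundle["comparisons"]) == {"biolabel_vs_clinical",
                                              "plus_theta_vs_fingerprint",
                                              "theta_only_vs_fingerprint"}
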