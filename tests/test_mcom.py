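import numpy as np
import pandas as pd
import pytest

from deltarad.mcom import (ImiaConfig, McomSolution, ParetoArchive, _dominates,
                           ensemble_external_predict, fuse_probabilities,
                           imia_optimize, lasso_baselines,
                           train_base_classifiers)
from deltarad.selection import CvPlan
from deltarad.synthdata import make_feature_table

SMALL_CFG = ImiaConfig(population=8, generations=4)


def separable_tables(n=100, seed=1, gap=0.4):
    """Two modalities sharing one perfectly separating feature (margin gap)."""
    A = make_feature_table(n, 3, seed=seed)
    x = A["f00"].to_numpy()
    x = np.where(np.abs(x) < gap, np.sign(x) * (gap + np.abs(x)), x)
    A["f00"] = x
    B = make_feature_table(n, 3, seed=seed + 1)
    B["f00"] = x
    return {"clin": A, "rad": B}, (x > 0).astype(int)


def solution_for(tables, weights=None):
    masks = {m: np.ones(df.shape[1], dtype=bool) for m, df in tables.items()}
    k = len(tables) * 3
    w = np.full(k, 1.0 / k) if weights is None else np.asarray(weights, float)
    return McomSolution(masks, {"svm_c": 1.0, "logistic_c": 1.0,
                                "lda_shrinkage": 0.1}, w)


class TestFusion:
    def test_equal_weights_give_mean(self):
        probs = np.array([[0.2], [0.4], [0.6]])
        out = fuse_probabilities(probs, np.full(3, 1 / 3))
        assert out[0] == pytest.approx(0.4)

    def test_one_hot_weight_is_identity(self):
        probs = np.array([[0.2, 0.3], [0.9, 0.8]])
        np.testing.assert_allclose(
            fuse_probabilities(probs, [0.0, 1.0]), [0.9, 0.8])

    def test_fused_output_bounded_by_members(self):
        rng = np.random.default_rng(2)
        probs = rng.random((5, 20))
        w = rng.dirichlet(np.ones(5))
        fused = fuse_probabilities(probs, w)
        assert (fused <= probs.max(axis=0) + 1e-12).all()
        assert (fused >= probs.min(axis=0) - 1e-12).all()

    def test_weight_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="weights"):
            fuse_probabilities(np.ones((3, 4)), [0.5, 0.5])


class TestBaseClassifiers:
    def test_separable_data_fit_perfectly_by_all_three(self):
        tables, y = separable_tables()
        sol = solution_for(tables)
        members = train_base_classifiers(tables, y, sol)
        assert len(members) == 6
        for _mod, _name, clf, cols in members:
            probs = clf.predict_proba(
                tables[_mod][cols].to_numpy(dtype=float))[:, 1]
            assert ((probs >= 0.5) == (y == 1)).all()
            assert (probs >= 0).all() and (probs <= 1).all()

    def test_one_hot_logistic_weight_reproduces_logistic_probability(self):
        tables, y = separable_tables()
        one_mod = {"clin": tables["clin"]}
        w = np.array([0.0, 1.0, 0.0])  # svm, logistic, lda
        sol = solution_for(one_mod, w)
        members = train_base_classifiers(one_mod, y, sol)
        logi = members[1][2]
        from deltarad.mcom import _member_probabilities
        fused = fuse_probabilities(_member_probabilities(members, one_mod), w)
        np.testing.assert_allclose(
            fused,
            logi.predict_proba(tables["clin"].to_numpy(dtype=float))[:, 1])

    def test_single_class_training_rejected(self):
        tables, _ = separable_tables(n=20)
        with pytest.raises(ValueError):
            train_base_classifiers(tables, np.ones(20, dtype=int),
                                   solution_for(tables))


class TestArchive:
    def test_members_are_mutually_nondominated(self):
        tables, y = separable_tables(n=60)
        res = imia_optimize(tables, y, CvPlan(1, 3, 0), SMALL_CFG)
        members = res.archive.members
        for a in members:
            for b in members:
                if a is not b:
                    assert not _dominates(a.objectives, b.objectives)

    def test_same_seed_identical_archive(self):
        tables, y = separable_tables(n=60)
        r1 = imia_optimize(tables, y, CvPlan(1, 3, 0), SMALL_CFG, seed=5)
        r2 = imia_optimize(tables, y, CvPlan(1, 3, 0), SMALL_CFG, seed=5)
        assert len(r1.archive.members) == len(r2.archive.members)
        for a, b in zip(r1.archive.members, r2.archive.members):
            assert a.objectives == b.objectives
            for m in a.masks:
                np.testing.assert_array_equal(a.masks[m], b.masks[m])
            np.testing.assert_allclose(a.weights, b.weights)

    def test_crowding_truncation_respects_cap(self):
        sols = []
        rng = np.random.default_rng(3)
        for _ in range(50):
            s = rng.uniform(0.2, 0.9)
            sol = McomSolution({"m": np.array([True])}, {}, np.array([1.0]))
            sol.objectives = (s, 1.0 - s)  # all on one front
            sols.append(sol)
        arch = ParetoArchive(cap=10)
        arch.update(sols)
        assert len(arch.members) <= 10

    def test_empty_archive_raises(self):
        with pytest.raises(RuntimeError):
            ParetoArchive().best_by_youden()


class TestRocMonotonicity:
    def test_raising_threshold_never_raises_sensitivity(self):
        tables, y = separable_tables(n=80, gap=0.0)
        sol = solution_for(tables)
        members = train_base_classifiers(tables, y, sol)
        from deltarad.mcom import _member_probabilities
        probs = fuse_probabilities(_member_probabilities(members, tables),
                                   sol.weights)
        prev = 1.1
        for thr in np.linspace(0, 1, 21):
            sens = ((probs >= thr) & (y == 1)).sum() / (y == 1).sum()
            assert sens <= prev + 1e-12
            prev = sens


class TestExternalEnsemble:
    def test_single_model_is_identity(self):
        tables, y = separable_tables(n=60)
        sol = solution_for(tables)
        members = train_base_classifiers(tables, y, sol)
        from deltarad.mcom import _member_probabilities
        own = fuse_probabilities(_member_probabilities(members, tables),
                                 sol.weights)
        np.testing.assert_allclose(
            ensemble_external_predict([(members, sol.weights)], tables), own)

    def test_missing_external_feature_named(self):
        tables, y = separable_tables(n=60)
        sol = solution_for(tables)
        members = train_base_classifiers(tables, y, sol)
        broken = {m: df.drop(columns=["f01"]) for m, df in tables.items()}
        with pytest.raises(KeyError, match="f01"):
            ensemble_external_predict([(members, sol.weights)], broken)

    def test_no_models_rejected(self):
        with pytest.raises(ValueError):
            ensemble_external_predict([], {})


class TestLassoBaselines:
    def test_strong_signal_feature_selected(self):
        rng = np.random.default_rng(4)
        X = make_feature_table(200, 5, seed=5)
        y = (X["f02"].to_numpy() + 0.3 * rng.standard_normal(200) > 0).astype(int)
        lr, svm = lasso_baselines(X, y, CvPlan(1, 5, 0))
        assert "f02" in lr.selected
        assert lr.selected == svm.selected

    def test_separable_two_feature_toy_reaches_auc_one(self):
        from deltarad.evalio import auc
        tables, y = separable_tables(n=80)
        X = tables["clin"][["f00", "f01"]]
        lr, svm = lasso_baselines(X, y, CvPlan(1, 5, 0))
        assert auc(y, lr.predict_proba(X)[:, 1]) == 1.0
        assert auc(y, svm.predict_proba(X)[:, 1]) == 1.0

    def test_all_zero_coefficients_fall_back_to_prevalence(self):
        # features carry no scale: L1 shrinks everything to zero
        n = 40
        X = pd.DataFrame({"a": np.zeros(n) + 1e-9 * np.arange(n)})
        y = np.array([0, 1] * (n // 2))
        lr, _svm = lasso_baselines(X, y, CvPlan(1, 5, 0))
        probs = lr.predict_proba(X)[:, 1]
        np.testing.assert_allclose(probs, y.mean())
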