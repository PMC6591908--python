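import numpy as np
import pytest

from metaboclust.classify import (
    ClassifierSpec,
    build_model_suite,
    external_validate,
    fit_family,
    grid_search,
    loocv_probabilities,
    rank_auc,
    select_best,
    select_threshold,
    train_final,
)
from metaboclust.cluster import ClusterAssignment
from metaboclust.diffstats import differential_analysis
from metaboclust.io import DatasetError

import oracles
from conftest import make_table

CHEAP_GRIDS = {
    "svm": {"cost": (0.5, 2.0)},
    "plsda": {"n_components": (1, 2)},
    "random_forest": {"mtry": (1,), "n_trees": (20,)},
    "gradient_boosted_trees": {"max_depth": (2,), "n_rounds": (20,), "learning_rate": (0.3,)},
}


def _separable_table(rng, n_per=10, m=1):
    X = np.vstack([rng.normal(3, 0.3, size=(n_per, m)), rng.normal(-3, 0.3, size=(n_per, m))])
    return make_table(X, state="covariate_adjusted",
                      labels=["case"] * n_per + ["control"] * n_per)


class TestLoocv:
    def test_majority_dummy_hand_loop(self):
        table = make_table([[1.0], [2.0], [3.0]], state="covariate_adjusted",
                           labels=["control", "control", "case"])
        spec = ClassifierSpec(("met0",), "majority")
        probs = loocv_probabilities(table, spec)
        np.testing.assert_array_equal(probs, [0.0, 0.0, 0.0])

    def test_separable_logistic_predicts_correct_side(self, rng):
        table = _separable_table(rng)
        probs = loocv_probabilities(table, ClassifierSpec(("met0",), "logistic"))
        y = table.labels01()
        assert ((probs > 0.5) == (y == 1)).all()

    def test_held_out_sample_never_influences_its_fold(self, rng):
        """Perturbing sample i's label or value leaves fold-i prediction unchanged."""
        table = _separable_table(rng, n_per=10)
        spec = ClassifierSpec(("met0",), "logistic")
        probs = loocv_probabilities(table, spec)
        for i in [0, 7, 19]:
            poisoned = table.values.copy()
            poisoned.iloc[i, 0] = 999.0
            meta = table.sample_meta.copy()
            meta.iloc[i, 0] = "case" if meta.iloc[i, 0] == "control" else "control"
            t2 = table.with_values(poisoned, state=table.state)
            # label flip changes other folds, so refit only fold i manually
            mask = np.ones(table.n_samples, bool)
            mask[i] = False
            X = table.values.to_numpy()[mask]
            y = table.labels01()[mask]
            model = fit_family("logistic", {}, X, y)
            p_direct = model.predict_proba_case(table.values.to_numpy()[i : i + 1])[0]
            assert probs[i] == pytest.approx(p_direct)
            # and with the poisoned held-out row, fold i training is identical
            X2 = t2.values.to_numpy()[mask]
            model2 = fit_family("logistic", {}, X2, y)
            assert model2.predict_proba_case(X[:1]) == pytest.approx(
                model.predict_proba_case(X[:1])
            )

    def test_single_class_training_fold_errors(self):
        table = make_table([[1.0], [2.0], [3.0]], state="covariate_adjusted",
                           labels=["control", "control", "case"])
        with pytest.raises(DatasetError, match="2 samples per class"):
            loocv_probabilities(table, ClassifierSpec(("met0",), "logistic"))


class TestSelectThreshold:
    def test_perfect_separation(self):
        res = select_threshold([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert res.accuracy == 1.0
        assert 0.2 < res.threshold < 0.8
        assert res.auc == 1.0

    def test_anti_aligned_probabilities(self):
        res = select_threshold([0.9, 0.8, 0.2, 0.1], [0, 0, 1, 1])
        assert res.auc == 0.0
        assert res.accuracy == 0.5  # best constant-side threshold

    def test_accuracy_at_least_prevalence(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 20))
            y = rng.integers(0, 2, size=n)
            y[:2] = [0, 1]
            probs = rng.random(n)
            res = select_threshold(probs, y)
            assert res.accuracy >= max(y.mean(), 1 - y.mean()) - 1e-12

    def test_auc_matches_pairwise_oracle(self, rng):
        for _ in range(120):
            n = int(rng.integers(4, 25))
            y = rng.integers(0, 2, size=n)
            y[:2] = [0, 1]
            probs = rng.choice([0.1, 0.25, 0.5, 0.77, 0.9], size=n)  # force ties
            assert rank_auc(probs, y) == pytest.approx(oracles.pairwise_auc(probs, y))

    def test_single_class_errors(self):
        with pytest.raises(DatasetError):
            select_threshold([0.1, 0.9], [1, 1])


class TestGridSearch:
    def test_single_point_grid_equals_direct_evaluation(self, rng):
        table = _separable_table(rng)
        spec = ClassifierSpec(("met0",), "svm", grid={"cost": (1.0,)})
        rep = grid_search(table, spec)
        probs = loocv_probabilities(table, spec, {"cost": 1.0})
        direct = select_threshold(probs, table.labels01())
        assert rep.internal["accuracy"] == pytest.approx(direct.accuracy)
        assert rep.chosen_hyperparameters == {"cost": 1.0}

    def test_good_grid_point_beats_degenerate_one(self, rng):
        table = _separable_table(rng, n_per=12)
        spec = ClassifierSpec(("met0",), "svm", grid={"cost": (1e-6, 1.0)})
        rep = grid_search(table, spec)
        assert rep.chosen_hyperparameters == {"cost": 1.0}

    def test_chosen_hyperparameters_always_in_grid(self, rng):
        table = _separable_table(rng, n_per=6)
        grid = {"n_components": (1,)}
        rep = grid_search(table, ClassifierSpec(("met0",), "plsda", grid=grid))
        assert rep.chosen_hyperparameters["n_components"] in grid["n_components"]

    def test_empty_grid_errors(self, rng):
        table = _separable_table(rng, n_per=4)
        with pytest.raises(DatasetError, match="empty grid"):
            grid_search(table, ClassifierSpec(("met0",), "svm", grid={"cost": ()}))


class TestTrainFinalAndExternal:
    def test_refit_deterministic(self, rng):
        table = _separable_table(rng, n_per=8, m=3)
        spec = ClassifierSpec(("met0", "met1", "met2"), "random_forest",
                              grid=CHEAP_GRIDS["random_forest"], seed=4)
        m1 = train_final(table, spec, {"mtry": 1, "n_trees": 20})
        m2 = train_final(table, spec, {"mtry": 1, "n_trees": 20})
        probe = rng.normal(size=(5, 3))
        np.testing.assert_array_equal(
            m1.predict_proba_case(probe), m2.predict_proba_case(probe)
        )

    def test_external_on_training_set_equals_resubstitution(self, rng):
        table = _separable_table(rng)
        spec = ClassifierSpec(("met0",), "logistic")
        rep = grid_search(table, spec)
        model = train_final(table, spec, rep.chosen_hyperparameters)
        ext = external_validate(model, rep.threshold, table, spec.metabolite_set)
        probs = model.predict_proba_case(table.values.to_numpy())
        pred = probs >= rep.threshold
        assert ext["accuracy"] == pytest.approx((pred == table.labels01()).mean())

    def test_shuffled_labels_give_chance_performance(self, rng):
        train = _separable_table(rng, n_per=15)
        spec = ClassifierSpec(("met0",), "logistic")
        rep = grid_search(train, spec)
        model = train_final(train, spec, rep.chosen_hyperparameters)
        n_test = 300
        X = rng.normal(0, 3, size=(n_test, 1))
        labels = ["case" if v else "control" for v in rng.integers(0, 2, size=n_test)]
        test = make_table(X, state="covariate_adjusted", labels=labels)
        ext = external_validate(model, rep.threshold, test, spec.metabolite_set)
        assert abs(ext["auc"] - 0.5) < 0.12
        prevalence = max(np.mean([l == "case" for l in labels]),
                         np.mean([l == "control" for l in labels]))
        assert ext["accuracy"] <= prevalence + 0.12

    def test_missing_metabolite_in_test_errors(self, rng):
        train = _separable_table(rng)
        spec = ClassifierSpec(("met0",), "logistic")
        model = train_final(train, spec, {})
        test = make_table(rng.normal(size=(4, 1)), state="covariate_adjusted",
                          metabolites=["other"])
        with pytest.raises(DatasetError, match="absent"):
            external_validate(model, 0.5, test, ["met0"])


class TestSuite:
    def _suite_inputs(self, rng):
        # 6 metabolites; the first 4 significant, of which met0/met1 are a pair
        n_per = 10
        X = rng.normal(size=(2 * n_per, 6))
        X[:n_per, :4] += 3.0
        table = make_table(X, state="covariate_adjusted",
                           labels=["case"] * n_per + ["control"] * n_per)
        diff = differential_analysis(table, n_perm=199, seed=0)
        sig = diff.significant_ids
        assert set(sig) >= {"met0", "met1", "met2", "met3"}
        assign = ClusterAssignment(
            ids=["met0", "met1", "met2", "met3"], labels=np.array([0, 0, 1, 2]),
            k=3, asw=0.5, silhouettes=np.zeros(4),
        )
        # restrict diff to exactly 4 significant for the counting contract
        diff.frame.loc[[m for m in diff.frame.index if m not in assign.ids],
                       "significant"] = False
        return table, diff, assign

    def test_suite_counting_by_construction(self, rng):
        table, diff, assign = self._suite_inputs(rng)
        families = ("svm", "plsda", "random_forest", "gradient_boosted_trees")
        reports = build_model_suite(
            table, diff, assign, families=families, grids=CHEAP_GRIDS, fit_final=False
        )
        # 4 single + 4 families x 1 pair-cluster + 4 all + 4 significant = 16
        assert len(reports) == 16
        names = [r.name for r in reports]
        assert sum(n.startswith("single:") for n in names) == 4
        assert sum(n.startswith("cluster0:") for n in names) == 4

    def test_metabolite_sets_respect_significance(self, rng):
        table, diff, assign = self._suite_inputs(rng)
        reports = build_model_suite(table, diff, assign, families=("plsda",),
                                    grids=CHEAP_GRIDS, fit_final=False)
        sig = set(diff.significant_ids)
        for rep in reports:
            if not rep.name.startswith("all:"):
                assert set(rep.spec.metabolite_set) <= sig

    def test_select_best_ignores_external(self, rng):
        table, diff, assign = self._suite_inputs(rng)
        reports = build_model_suite(table, diff, assign, families=("plsda",),
                                    grids=CHEAP_GRIDS, fit_final=False)
        best = select_best(reports)
        for rep in reports:
            rep.external = {"accuracy": 0.0 if rep is best else 1.0}
        assert select_best(reports) is best

    def test_single_report_selected(self, rng):
        table, diff, assign = self._suite_inputs(rng)
        rep = grid_search(table, ClassifierSpec(("met0",), "logistic"))
        assert select_best([rep]) is rep

    def test_logistic_restricted_to_single_metabolite(self):
        with pytest.raises(DatasetError, match="single-metabolite"):
            ClassifierSpec(("a", "b"), "logistic")
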