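import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metaboclust.cluster import ClusterAssignment
from metaboclust.diffstats import (
    bh_adjust,
    differential_analysis,
    fisher_cluster_enrichment,
    fisher_pathway_in_cluster,
    pathway_enrichment,
    permutation_t_test,
)
from metaboclust.io import DatasetError, PathwayAnnotation

import oracles
from conftest import make_table


def _assignment(labels):
    labels = np.asarray(labels)
    n = len(labels)
    return ClusterAssignment(
        ids=[f"m{i}" for i in range(n)], labels=labels,
        k=len(set(labels.tolist())), asw=0.0, silhouettes=np.zeros(n),
    )


class TestPermutationTTest:
    def test_extreme_separation_hits_add_one_floor(self):
        x = np.arange(10) * 0.01
        y = np.arange(10) * 0.01 + 100
        t, p = permutation_t_test(x, y, n_perm=99, seed=5)
        assert p == pytest.approx(1 / 100)

    def test_identical_groups_give_t0_p1(self):
        x = [1.0, 2.0, 3.0]
        t, p = permutation_t_test(x, list(x), n_perm=199, seed=0)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_swap_invariance(self, rng):
        x = rng.normal(size=7)
        y = rng.normal(size=12)
        t1, p1 = permutation_t_test(x, y, n_perm=499, seed=3)
        t2, p2 = permutation_t_test(y, x, n_perm=499, seed=3)
        assert t1 == pytest.approx(-t2)
        assert p1 == p2

    def test_zero_variance_conventions(self):
        t, p = permutation_t_test([1.0, 1.0], [1.0, 1.0], n_perm=99, seed=0)
        assert t == 0.0 and p == 1.0
        t, _ = permutation_t_test([1.0, 1.0], [2.0, 2.0], n_perm=99, seed=0)
        assert np.isinf(t)

    def test_null_calibration_small(self, rng):
        """Null p-values should reject at roughly the nominal rate."""
        hits = 0
        n_tests = 400
        for i in range(n_tests):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            _, p = permutation_t_test(x, y, n_perm=199, seed=i)
            hits += p <= 0.05
        rate = hits / n_tests
        se = np.sqrt(0.05 * 0.95 / n_tests)
        assert abs(rate - 0.05) < 3.3 * se


class TestBHAdjust:
    def test_hand_stepup_example(self):
        q = bh_adjust([0.01, 0.02, 0.04, 0.5])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04 * 4 / 3, 0.5])

    def test_all_equal_and_single(self):
        np.testing.assert_allclose(bh_adjust([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])
        np.testing.assert_allclose(bh_adjust([0.07]), [0.07])

    def test_matches_bruteforce_on_random_vectors(self, rng):
        for _ in range(300):
            p = rng.uniform(1e-6, 1, size=rng.integers(1, 15))
            np.testing.assert_allclose(bh_adjust(p), oracles.bh_stepup(p), rtol=1e-12)

    @given(
        st.lists(st.floats(min_value=1e-9, max_value=1.0, exclude_min=False),
                 min_size=1, max_size=20)
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_stepup_properties(self, p):
        q = bh_adjust(p)
        assert (q >= np.asarray(p) - 1e-15).all()
        assert (q <= 1.0).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()  # monotone after sorting
        np.testing.assert_allclose(q, oracles.bh_stepup(np.asarray(p)), rtol=1e-9)

    def test_invalid_p_rejected(self):
        with pytest.raises(DatasetError):
            bh_adjust([0.0, 0.5])


class TestFisherClusterEnrichment:
    def test_two_by_two_enumeration_value(self):
        res = fisher_cluster_enrichment(_assignment([0, 0, 1, 1]),
                                        [True, True, False, False])
        by_id = {r.unit_id: r for r in res}
        assert by_id["0"].p_value == pytest.approx(1 / 6)
        assert by_id["1"].p_value == pytest.approx(1.0)

    def test_no_significant_anywhere_gives_p1(self):
        res = fisher_cluster_enrichment(_assignment([0, 0, 1]), [False] * 3)
        assert all(r.p_value == pytest.approx(1.0) for r in res)

    def test_whole_population_cluster_warns_p1(self):
        with pytest.warns(UserWarning, match="whole population"):
            res = fisher_cluster_enrichment(_assignment([0, 0, 0]), [True, False, True])
        assert res[0].p_value == 1.0

    def test_matches_hypergeometric_enumeration(self, rng):
        for _ in range(120):
            n = int(rng.integers(4, 13))
            labels = rng.integers(0, 3, size=n)
            labels[:3] = [0, 1, 2]
            sig = rng.random(size=n) < 0.5
            res = fisher_cluster_enrichment(_assignment(labels), sig)
            for r in res:
                a, b, c, d = r.counts
                assert r.p_value == pytest.approx(
                    oracles.fisher_greater(a, b, c, d), rel=1e-9
                )


class TestPathwayEnrichment:
    def _annotation(self, members):
        return PathwayAnnotation({"pw": ("desc", frozenset(members))})

    def test_combinatorial_example(self):
        population = [f"m{i}" for i in range(10)]
        annotation = self._annotation(population[:3])
        res = pathway_enrichment(annotation, set(population[:3] + population[3:5]),
                                 population)
        assert res[0].p_value == pytest.approx(21 / 252)

    def test_zero_overlap_upper_tail_is_one(self):
        population = [f"m{i}" for i in range(8)]
        annotation = self._annotation(population[:3])
        res = pathway_enrichment(annotation, set(population[5:7]), population)
        # members and significant sets are disjoint is not forced; force k=0
        res = pathway_enrichment(annotation, {population[5]}, population)
        assert res[0].counts[3] == 0
        assert res[0].p_value == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(120):
            N = int(rng.integers(3, 13))
            population = [f"m{i}" for i in range(N)]
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(0, N + 1))
            members = rng.choice(population, size=K, replace=False)
            sig = set(rng.choice(population, size=n, replace=False))
            res = pathway_enrichment(self._annotation(members), sig, population)
            _, KK, nn, k = res[0].counts
            assert res[0].p_value == pytest.approx(
                oracles.hypergeom_upper_tail(N, KK, nn, k), rel=1e-9
            )

    def test_pathway_outside_population_skipped(self):
        population = ["a", "b"]
        annotation = self._annotation(["zzz"])
        with pytest.warns(UserWarning, match="skipped"):
            assert pathway_enrichment(annotation, {"a"}, population) == []


class TestFisherPathwayInCluster:
    def test_all_members_in_matching_cluster(self):
        labels = [0, 0, 0] + [i + 1 for i in range(7)]
        assign = _assignment(labels)
        res = fisher_pathway_in_cluster(assign, {"m0", "m1", "m2"})
        by_id = {r.unit_id: r for r in res}
        assert by_id["0"].p_value == pytest.approx(1 / 120)

    def test_uniform_spread_not_enriched(self):
        assign = _assignment([0, 0, 0, 1, 1, 1])
        res = fisher_pathway_in_cluster(assign, {"m0", "m3"})
        assert all(r.p_value >= 0.5 for r in res)

    def test_empty_intersection_p1(self):
        assign = _assignment([0, 0, 1, 1])
        res = fisher_pathway_in_cluster(assign, {"zzz"})
        assert all(r.p_value == pytest.approx(1.0) for r in res)


class TestDifferentialAnalysis:
    def _planted_table(self, rng, shift_sd=2.0, n_signal=10, m=100, n_per=40):
        X = rng.normal(size=(2 * n_per, m))
        X[:n_per, :n_signal] += shift_sd
        return make_table(X, state="covariate_adjusted",
                          labels=["case"] * n_per + ["control"] * n_per)

    def test_planted_shift_fully_recovered_and_seed_stable(self, rng):
        table = self._planted_table(rng)
        diff = differential_analysis(table, fdr=0.075, n_perm=999, seed=7)
        flagged = set(diff.significant_ids)
        assert {f"met{j}" for j in range(10)} <= flagged
        again = differential_analysis(table, fdr=0.075, n_perm=999, seed=7)
        np.testing.assert_array_equal(diff.frame["p_value"], again.frame["p_value"])

    def test_identical_groups_give_no_significance(self):
        X = np.tile(np.arange(8, dtype=float).reshape(-1, 1), (1, 5))
        table = make_table(X, state="covariate_adjusted",
                           labels=["case", "control"] * 4)
        diff = differential_analysis(table, n_perm=199, seed=0)
        assert diff.significant_ids == []

    def test_qvalues_dominate_pvalues_and_floor(self):
        rng = np.random.default_rng(0)
        table = self._planted_table(rng, shift_sd=1.0, n_signal=5, m=30, n_per=10)
        diff = differential_analysis(table, n_perm=199, seed=1)
        f = diff.frame
        assert (f["q_value"] >= f["p_value"] - 1e-15).all()
        assert (f["p_value"] >= 1 / 200).all()

    def test_mean_log_fc_sign_follows_case_shift(self, rng):
        table = self._planted_table(rng, shift_sd=3.0, n_signal=3, m=10, n_per=15)
        diff = differential_analysis(table, n_perm=99, seed=0)
        assert (diff.frame["mean_log_fc"].iloc[:3] > 0).all()
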