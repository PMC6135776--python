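"""Chi-squared distance, k-medoids clustering, k selection and naming."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from phenonet.phenotyping import (
    PhenotypeModel,
    assign_phenotypes,
    chi_squared_distance,
    kmedoids,
    name_phenotypes,
    pairwise_chi_squared,
    select_k,
)
from phenonet.synthetic import sample_frequency_vectors


def brute_force_kmedoids(dist: np.ndarray, k: int):
    """Exhaustive minimisation over all k-subsets of medoids."""
    n = dist.shape[0]
    best_cost, best_set = np.inf, None
    for subset in combinations(range(n), k):
        cost = dist[:, subset].min(axis=1).sum()
        if cost < best_cost - 1e-12:
            best_cost, best_set = cost, subset
    return best_cost, best_set


def random_simplex(rng, n, p=10):
    return rng.dirichlet(np.ones(p), size=n)


class TestChiSquaredDistance:
    def test_hand_values(self):
        h = np.zeros(10)
        h[:2] = [0.5, 0.5]
        m = np.zeros(10)
        m[:2] = [0.25, 0.75]
        assert chi_squared_distance(h, h) == 0.0
        e1, e2 = np.eye(10)[0], np.eye(10)[1]
        assert chi_squared_distance(e1, e2) == pytest.approx(2.0, abs=1e-12)
        assert chi_squared_distance(h, m) == pytest.approx(
            0.0625 / 0.75 + 0.0625 / 1.25, abs=1e-12
        )

    def test_negative_components_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            chi_squared_distance(np.array([-0.1, 1.1]), np.array([0.5, 0.5]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_metric_like_properties_on_simplex(self, seed):
        rng = np.random.default_rng(seed)
        a, b = random_simplex(rng, 2)
        dab = chi_squared_distance(a, b)
        assert dab == pytest.approx(chi_squared_distance(b, a), abs=1e-12)
        assert 0.0 <= dab <= 2.0 + 1e-12
        assert chi_squared_distance(a, a) == 0.0

    def test_pairwise_matches_scalar(self):
        rng = np.random.default_rng(3)
        x = random_simplex(rng, 6)
        d = pairwise_chi_squared(x)
        for i in range(6):
            for j in range(6):
                assert d[i, j] == pytest.approx(
                    chi_squared_distance(x[i], x[j]), abs=1e-12
                )


class TestKMedoids:
    def test_k1_medoid_minimises_total_distance(self):
        rng = np.random.default_rng(5)
        x = random_simplex(rng, 12)
        model = kmedoids(x, 1, n_restarts=5, seed=0)
        dist = pairwise_chi_squared(x)
        assert model.cost == pytest.approx(dist.sum(axis=0).min(), abs=1e-12)
        assert model.medoid_indices[0] == int(np.argmin(dist.sum(axis=0)))

    def test_two_tight_triples_match_exhaustive_search(self):
        rng = np.random.default_rng(1)
        a = np.tile([0.8, 0.2] + [0.0] * 8, (3, 1)) + rng.uniform(0, 0.01, (3, 10))
        b = np.tile([0.0] * 8 + [0.2, 0.8], (3, 1)) + rng.uniform(0, 0.01, (3, 10))
        x = np.vstack([a, b])
        model = kmedoids(x, 2, n_restarts=20, seed=0)
        labels = assign_phenotypes(model, x)
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert set(labels) == {1, 2}
        best_cost, _ = brute_force_kmedoids(pairwise_chi_squared(x), 2)
        assert model.cost == pytest.approx(best_cost, abs=1e-12)

    def test_single_vector_cost_zero(self):
        x = np.array([[0.5, 0.5] + [0.0] * 8])
        model = kmedoids(x, 1, n_restarts=1, seed=0)
        assert model.cost == 0.0

    def test_k_exceeding_distinct_vectors_rejected(self):
        x = np.tile([0.5, 0.5] + [0.0] * 8, (4, 1))
        with pytest.raises(ValueError, match="distinct"):
            kmedoids(x, 2, n_restarts=1, seed=0)

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_exhaustive_init_matches_global_optimum(self, k):
        rng = np.random.default_rng(k)
        for _ in range(10):
            x = random_simplex(rng, int(rng.integers(max(4, k + 1), 9)))
            model = kmedoids(x, k, init="exhaustive")
            best_cost, _ = brute_force_kmedoids(pairwise_chi_squared(x), k)
            assert model.cost == pytest.approx(best_cost, abs=1e-10)

    def test_best_replicate_and_determinism(self):
        rng = np.random.default_rng(9)
        x = random_simplex(rng, 40)
        m1 = kmedoids(x, 3, n_restarts=30, seed=4)
        m2 = kmedoids(x, 3, n_restarts=30, seed=4)
        assert m1.cost == min(m1.replicate_costs)
        np.testing.assert_array_equal(m1.medoid_indices, m2.medoid_indices)

    def test_cost_non_increasing_in_k(self):
        rng = np.random.default_rng(11)
        x = random_simplex(rng, 50)
        costs = [kmedoids(x, k, n_restarts=20, seed=1).cost for k in (2, 3, 4, 5)]
        assert all(c2 <= c1 + 1e-9 for c1, c2 in zip(costs, costs[1:]))

    def test_medoids_are_members(self, planted_vectors):
        x, _ = planted_vectors
        model = kmedoids(x[:120], 4, n_restarts=10, seed=2)
        for idx, medoid in zip(model.medoid_indices, model.medoids):
            np.testing.assert_array_equal(medoid, x[idx])


class TestAssignment:
    def test_medoid_assigned_to_itself(self):
        rng = np.random.default_rng(2)
        x = random_simplex(rng, 20)
        model = kmedoids(x, 3, n_restarts=10, seed=0)
        labels = assign_phenotypes(model, model.medoids)
        assert labels.tolist() == [1, 2, 3]

    def test_tie_broken_by_lowest_medoid_index(self):
        medoids = np.array([[1.0] + [0.0] * 9, [0.0, 1.0] + [0.0] * 8])
        model = PhenotypeModel(
            k=2, medoids=medoids, medoid_indices=np.array([0, 1]),
            cost=0.0, replicate_costs=np.zeros(1),
        )
        equidistant = np.array([[0.5, 0.5] + [0.0] * 8])
        assert assign_phenotypes(model, equidistant).item() == 1

    def test_planted_cluster_uniformly_labeled(self, archetypes):
        x, labels = sample_frequency_vectors(archetypes[:1], 50, 200.0, seed=3)
        model = kmedoids(x, 1, n_restarts=5, seed=0)
        assert set(assign_phenotypes(model, x)) == {1}


class TestRecoveryAndSelectK:
    def test_six_archetypes_recovered(self, planted_vectors):
        x, truth = planted_vectors
        model = kmedoids(x, 6, n_restarts=100, seed=11)
        pred = assign_phenotypes(model, x)
        assert adjusted_rand_score(truth, pred) >= 0.95

    def test_vacuous_criteria_select_max_k(self, planted_vectors):
        x, _ = planted_vectors
        rng = np.random.default_rng(0)
        sub = rng.choice(len(x), 120, replace=False)
        cases = rng.choice([f"c{i}" for i in range(10)], size=120)
        res = select_k(
            x[sub], cases, k_range=range(2, 5), dist_threshold=0.0,
            corr_threshold=1.0, n_restarts=5, seed=1,
        )
        assert res.selected_k == 4

    def test_two_profiles_select_two(self, archetypes):
        # two well-separated archetypes; per-case ratios decorrelated by
        # tissue-area denominators exceeding the phenotyped-tile count
        x, _ = sample_frequency_vectors(archetypes[:2], 80, 150.0, seed=5)
        rng = np.random.default_rng(6)
        cases = rng.choice([f"c{i}" for i in range(16)], size=len(x))
        areas = pd.Series(
            {c: n / rng.uniform(0.3, 0.9) for c, n in pd.Series(cases).value_counts().items()}
        )
        res = select_k(
            x, cases, k_range=range(2, 5), n_restarts=10, seed=2, tissue_area=areas
        )
        assert res.selected_k == 2
        diag = res.diagnostics.set_index("k")
        assert not diag.loc[3, "admissible"] and not diag.loc[4, "admissible"]

    def test_no_admissible_k_status(self, planted_vectors):
        x, _ = planted_vectors
        rng = np.random.default_rng(1)
        cases = rng.choice(["a", "b", "c", "d"], size=len(x))
        res = select_k(
            x, cases, k_range=range(2, 4), dist_threshold=2.5, n_restarts=3, seed=0
        )
        assert res.selected_k is None
        assert res.status == "no admissible k"


class TestNaming:
    def test_heuristic_names_recover_archetypes(self, planted_vectors, archetypes):
        x, truth = planted_vectors
        model = kmedoids(x, 6, n_restarts=100, seed=11)
        names = name_phenotypes(model)
        # each medoid's heuristic name matches the archetype that generated it
        pred = assign_phenotypes(model, x)
        for phenotype in range(1, 7):
            truth_labels = pd.Series(truth[pred == phenotype])
            assert names[phenotype - 1] == truth_labels.mode().item()

    def test_user_mapping_overrides(self, planted_vectors):
        x, _ = planted_vectors
        model = kmedoids(x[:60], 2, n_restarts=5, seed=0)
        names = name_phenotypes(model, mapping={1: "alpha", 2: "beta"})
        assert names == ["alpha", "beta"]

    def test_names_never_affect_assignment(self, planted_vectors):
        x, _ = planted_vectors
        model = kmedoids(x[:60], 2, n_restarts=5, seed=0)
        before = assign_phenotypes(model, x[:60]).copy()
        name_phenotypes(model)
        np.testing.assert_array_equal(before, assign_phenotypes(model, x[:60]))


class TestSerialization:
    def test_round_trip(self, tmp_path, planted_vectors):
        x, _ = planted_vectors
        model = kmedoids(x[:90], 3, n_restarts=5, seed=7)
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = PhenotypeModel.from_json(path)
        np.testing.assert_array_equal(loaded.medoids, model.medoids)
        assert loaded.cost == model.cost
        np.testing.assert_array_equal(
            assign_phenotypes(loaded, x), assign_phenotypes(model, x)
        )
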