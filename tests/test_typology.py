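"""Farm profiles, Ward.D2 clustering and the intensity index."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from grassmilk.errors import ConfigurationError, InputError
from grassmilk.evaluation import adjusted_rand_index
from grassmilk.typology import (
    MONTH_COLUMNS,
    FarmProfileSet,
    build_profiles,
    cut_and_summarize,
    flag_skimmed,
    intensity_index,
    ward_d2_cluster,
)


def brute_force_ward_d2(X):
    """Agglomerate by recomputing the Ward.D2 criterion from scratch.

    Returns one (merged leaf set, height) pair per merge step.
    """
    clusters = {i: [i] for i in range(len(X))}
    next_id = len(X)
    merges = []

    def ward_dist(a, b):
        ca, cb = X[a].mean(axis=0), X[b].mean(axis=0)
        na, nb = len(a), len(b)
        return np.sqrt(2.0 * na * nb / (na + nb)) * np.linalg.norm(ca - cb)

    while len(clusters) > 1:
        best = None
        for i, j in combinations(sorted(clusters), 2):
            d = ward_dist(clusters[i], clusters[j])
            if best is None or d < best[0] - 1e-12:
                best = (d, i, j)
        d, i, j = best
        merged = clusters.pop(i) + clusters.pop(j)
        merges.append((frozenset(merged), d))
        clusters[next_id] = merged
        next_id += 1
    return merges


def linkage_merge_sets(Z, n):
    sets = {i: frozenset([i]) for i in range(n)}
    out = []
    for step, (left, right, height, _) in enumerate(Z):
        merged = sets[int(left)] | sets[int(right)]
        sets[n + step] = merged
        out.append((merged, height))
    return out


def profile_set(matrix, farm_ids=None, years=None):
    matrix = np.asarray(matrix, dtype=float)
    n = len(matrix)
    df = pd.DataFrame(matrix, columns=MONTH_COLUMNS)
    df.insert(0, "year", years if years is not None else 2020)
    df.insert(0, "farm_id", farm_ids if farm_ids is not None else [f"F{i}" for i in range(n)])
    return FarmProfileSet(profiles=df, n_excluded=0)


class TestBuildProfiles:
    def test_incomplete_farm_year_excluded(self):
        rows = [
            {"farm_id": "A", "year": 2020, "month": m, "probability": 0.5}
            for m in range(1, 13)
        ] + [
            {"farm_id": "B", "year": 2020, "month": m, "probability": 0.5}
            for m in range(1, 12)  # only 11 months
        ]
        result = build_profiles(pd.DataFrame(rows))
        assert len(result) == 1
        assert result.n_excluded == 1
        assert result.profiles["farm_id"].tolist() == ["A"]

    def test_multiple_records_per_month_averaged(self):
        rows = []
        for m in range(1, 13):
            rows.append({"farm_id": "A", "year": 2020, "month": m, "probability": 0.2})
            rows.append({"farm_id": "A", "year": 2020, "month": m, "probability": 0.6})
        result = build_profiles(pd.DataFrame(rows))
        assert np.allclose(result.matrix, 0.4)

    def test_cardinality(self):
        rows = [
            {"farm_id": f"F{i}", "year": y, "month": m, "probability": 0.5}
            for i in range(5)
            for y in (2020, 2021)
            for m in range(1, 13)
        ]
        assert len(build_profiles(pd.DataFrame(rows))) == 10


class TestWardClustering:
    def test_identical_profiles_merge_at_zero_height(self):
        X = np.vstack([np.full(12, 0.3), np.full(12, 0.3), np.full(12, 0.9)])
        Z = ward_d2_cluster(profile_set(X))
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_tree_matches_brute_force_agglomeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        X = rng.random((n, 12))
        Z = ward_d2_cluster(profile_set(X))
        expected = brute_force_ward_d2(X)
        actual = linkage_merge_sets(Z, n)
        for (set_a, h_a), (set_e, h_e) in zip(actual, expected):
            assert set_a == set_e
            assert h_a == pytest.approx(h_e, abs=1e-9)

    def test_merge_heights_monotone(self):
        rng = np.random.default_rng(11)
        Z = ward_d2_cluster(profile_set(rng.random((15, 12))))
        assert np.all(np.diff(Z[:, 2]) >= -1e-12)

    def test_separated_archetypes_dominate_final_merge(self):
        rng = np.random.default_rng(12)
        low = 0.1 + 0.02 * rng.random((10, 12))
        high = 0.9 + 0.02 * rng.random((10, 12))
        Z = ward_d2_cluster(profile_set(np.vstack([low, high])))
        assert Z[-1, 2] > 5 * Z[-2, 2]

    def test_fewer_than_two_profiles_rejected(self):
        with pytest.raises(InputError):
            ward_d2_cluster(profile_set(np.ones((1, 12))))

    def test_partition_invariant_to_input_order(self):
        rng = np.random.default_rng(13)
        X = rng.random((20, 12))
        ps = profile_set(X)
        labels = cut_and_summarize(ward_d2_cluster(ps), 4, ps).assignments
        perm = rng.permutation(20)
        ps_perm = profile_set(X[perm], farm_ids=[f"F{i}" for i in perm])
        labels_perm = cut_and_summarize(ward_d2_cluster(ps_perm), 4, ps_perm).assignments
        merged = labels.merge(labels_perm, on=["farm_id", "year"])
        assert adjusted_rand_index(merged["cluster_x"], merged["cluster_y"]) == 1.0


class TestCutAndSummarize:
    def test_singleton_boundary(self):
        rng = np.random.default_rng(1)
        ps = profile_set(rng.random((6, 12)))
        sol = cut_and_summarize(ward_d2_cluster(ps), 6, ps)
        assert sol.cluster_sizes.tolist() == [1] * 6
        curves = sol.monthly_curves.sort_values("cluster")
        # each singleton cluster's curve is its own profile
        for _, row in sol.assignments.iterrows():
            expected = ps.profiles.loc[
                ps.profiles["farm_id"] == row["farm_id"], MONTH_COLUMNS
            ].to_numpy()[0]
            got = curves.loc[
                curves["cluster"] == row["cluster"], MONTH_COLUMNS
            ].to_numpy()[0]
            assert np.allclose(got, expected)

    def test_single_cluster_equals_global_mean(self):
        rng = np.random.default_rng(2)
        X = rng.random((8, 12))
        ps = profile_set(X)
        sol = cut_and_summarize(ward_d2_cluster(ps), 1, ps)
        assert np.allclose(sol.monthly_curves[MONTH_COLUMNS].to_numpy()[0], X.mean(0))

    def test_sizes_sum_to_profile_count(self):
        rng = np.random.default_rng(3)
        ps = profile_set(rng.random((17, 12)))
        sol = cut_and_summarize(ward_d2_cluster(ps), 5, ps)
        assert sol.cluster_sizes.sum() == 17

    def test_k_out_of_range_rejected(self):
        ps = profile_set(np.random.default_rng(0).random((4, 12)))
        tree = ward_d2_cluster(ps)
        with pytest.raises(InputError):
            cut_and_summarize(tree, 0, ps)
        with pytest.raises(InputError):
            cut_and_summarize(tree, 5, ps)


class TestFlagSkimmed:
    def _solution_with_fat(self, fats):
        summary = pd.DataFrame(
            {"cluster": range(1, len(fats) + 1), "fat": fats}
        )
        return type(
            "S", (), {"trait_summary": summary}
        )()

    def test_near_zero_fat_flagged(self):
        sol = self._solution_with_fat([4.1, 0.25, 3.9])
        assert flag_skimmed(sol, 1.0) == [2]

    def test_normal_fat_not_flagged(self):
        sol = self._solution_with_fat([4.1, 3.7])
        assert flag_skimmed(sol, 1.0) == []

    def test_zero_threshold_flags_nothing(self):
        sol = self._solution_with_fat([0.25, 4.1])
        assert flag_skimmed(sol, 0.0) == []


class TestIntensityIndex:
    def test_constant_intensive_farm(self):
        assignments = pd.DataFrame(
            {"farm_id": "A", "year": range(2010, 2021), "cluster": 1}
        )
        out = intensity_index(assignments, {1: -1})
        assert out.loc[0, "sum"] == -11
        assert out.loc[0, "category"] == "always-intensive"

    def test_alternating_farm_is_intermediate(self):
        assignments = pd.DataFrame(
            {"farm_id": "A", "year": range(2010, 2020), "cluster": [1, 2] * 5}
        )
        out = intensity_index(assignments, {1: -1, 2: 1})
        assert out.loc[0, "sum"] == 0
        assert out.loc[0, "category"] == "intermediate"

    def test_hand_computed_five_farm_fixture(self):
        rows = []
        plan = {
            "A": [1, 1, 1],      # always intensive: sum -3
            "B": [2, 2, 2],      # always extensive: sum +3
            "C": [1, 2, 2],      # intermediate: sum +1
            "D": [2, 1, 2],      # intermediate: sum +1
            "E": [3, 1, 1],      # cluster 3 flagged: 2 usable years, sum -2
        }
        for farm, clusters in plan.items():
            for year, c in zip((2019, 2020, 2021), clusters):
                rows.append({"farm_id": farm, "year": year, "cluster": c})
        out = intensity_index(
            pd.DataFrame(rows), {1: -1, 2: 1}, flagged=[3]
        ).set_index("farm_id")
        assert out.loc["A", "sum"] == -3 and out.loc["A", "category"] == "always-intensive"
        assert out.loc["B", "sum"] == 3 and out.loc["B", "category"] == "always-extensive"
        assert out.loc["C", "sum"] == 1 and out.loc["C", "category"] == "intermediate"
        assert out.loc["D", "sum"] == 1 and out.loc["D", "category"] == "intermediate"
        assert out.loc["E", "sum"] == -2 and out.loc["E", "category"] == "always-intensive"
        assert (out["sum"].abs() <= out["n_years"]).all()

    def test_unmapped_cluster_rejected(self):
        assignments = pd.DataFrame(
            {"farm_id": ["A", "A"], "year": [2020, 2021], "cluster": [1, 9]}
        )
        with pytest.raises(ConfigurationError):
            intensity_index(assignments, {1: -1})
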