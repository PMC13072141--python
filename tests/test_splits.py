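"""Covariate binning, K-modes clustering against exhaustive-partition
minima, elbow selection, and the fold-construction protocol."""

import itertools

import numpy as np
import pandas as pd
import pytest

from morphomil.errors import InfeasibleKError, MissingDataError
from morphomil.splits import (
    BIN_COLUMNS,
    BinScheme,
    bin_covariates,
    build_folds,
    elbow_select_k,
    get_fold,
    kmodes,
)


def cohort_frame(ages, sexes, bmis, incomes):
    return pd.DataFrame({
        "patient_id": [f"P{i}" for i in range(len(ages))],
        "age": ages, "sex": sexes, "bmi": bmis, "income": incomes,
    })


class TestBinning:
    def test_age_boundary(self):
        df = bin_covariates(cohort_frame([64.9, 65.0], ["M", "F"],
                                         [22, 22], [1, 1]))
        assert list(df["age_bin"]) == ["<65", ">=65"]

    def test_bmi_bins_contiguous(self):
        df = bin_covariates(cohort_frame([50] * 4, ["M"] * 4,
                                         [24.9, 25.0, 27.0, 30.0], [1] * 4))
        assert list(df["bmi_bin"]) == ["<25", "25-30", "25-30", ">=30"]

    def test_income_boundary_goes_up(self):
        df = bin_covariates(cohort_frame([50, 50], ["M", "M"], [22, 22],
                                         [43_193.99, 43_194.0]))
        assert list(df["income_bin"]) == ["<43194", ">=43194"]

    def test_missing_covariate_lists_patients(self):
        df = cohort_frame([50, np.nan], ["M", "F"], [22, 23], [1, 2])
        with pytest.raises(MissingDataError, match="P1"):
            bin_covariates(df)

    def test_gapped_scheme_selectable(self):
        df = bin_covariates(cohort_frame([50] * 3, ["M"] * 3,
                                         [23.0, 27.0, 31.0], [1] * 3),
                            BinScheme(bmi_mode="gapped"))
        assert list(df["bmi_bin"]) == ["<24", "24-30", ">30"]


def brute_force_kmodes_cost(X, K):
    """Exhaustive minimum matching-dissimilarity over all K-partitions."""
    n = len(X)
    best = np.inf
    for assignment in itertools.product(range(K), repeat=n):
        if len(set(assignment)) != K:
            continue
        cost = 0
        for k in range(K):
            members = X[np.array(assignment) == k]
            for j in range(X.shape[1]):
                vals, counts = np.unique(members[:, j], return_counts=True)
                cost += len(members) - counts.max()
        best = min(best, cost)
    return best


class TestKModes:
    def test_k_equals_distinct_rows_is_zero_cost(self, rng):
        X = rng.integers(0, 3, size=(30, 4))
        distinct = np.unique(X, axis=0)
        res = kmodes(X, K=len(distinct), seed=0)
        assert res.cost == 0

    def test_identical_rows_single_cluster(self):
        X = np.tile([1, 0, 2, 1], (12, 1))
        res = kmodes(X, K=1, seed=0)
        assert res.cost == 0
        assert set(res.labels) == {0}

    @pytest.mark.parametrize("seed", range(5))
    def test_small_instances_match_exhaustive_minimum(self, seed):
        rng = np.random.Generator(np.random.PCG64(seed))
        X = rng.integers(0, 2, size=(6, 4))
        while len(np.unique(X, axis=0)) < 2:
            X = rng.integers(0, 2, size=(6, 4))
        res = kmodes(X, K=2, seed=seed, n_init=20)
        assert res.cost == brute_force_kmodes_cost(X, 2)

    def test_infeasible_k_raises(self):
        X = np.tile([0, 1, 0, 1], (5, 1))
        with pytest.raises(InfeasibleKError):
            kmodes(X, K=2, seed=0)

    def test_deterministic_given_seed(self, rng):
        X = rng.integers(0, 3, size=(40, 4))
        a = kmodes(X, K=3, seed=11)
        b = kmodes(X, K=3, seed=11)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.cost == b.cost

    def test_cost_equals_recomputed_assignment_cost(self, rng):
        X = rng.integers(0, 3, size=(50, 4))
        res = kmodes(X, K=4, seed=2)
        recomputed = int(
            (X != res.modes[res.labels]).sum()
        )
        assert res.cost == recomputed


class TestElbow:
    def chord_knee(self, ks, costs):
        """Independent chord-distance computation."""
        p1 = np.array([ks[0], costs[0]], dtype=float)
        p2 = np.array([ks[-1], costs[-1]], dtype=float)
        chord = (p2 - p1) / np.linalg.norm(p2 - p1)
        best_k, best_d = ks[0], -1.0
        for k, c in zip(ks, costs):
            v = np.array([k, c], dtype=float) - p1
            d = np.linalg.norm(v - (v @ chord) * chord)
            if d > best_d + 1e-12:
                best_d, best_k = d, k
        return best_k

    def test_matches_geometric_oracle_on_synthetic_curve(self, monkeypatch):
        costs = {k: c for k, c in zip(range(1, 7), [100, 40, 20, 15, 14, 13])}
        import morphomil.splits as sp

        class FakeAssign:
            def __init__(self, cost): self.cost = cost

        monkeypatch.setattr(sp, "kmodes",
                            lambda X, k, seed=0, n_init=10: FakeAssign(costs[k]))
        X = np.array([[0, 0, 0, 0], [0, 0, 0, 1], [0, 0, 1, 0],
                      [0, 1, 0, 0], [1, 0, 0, 0], [1, 1, 1, 1]])
        got = sp.elbow_select_k(X, k_range=range(1, 7), seed=0)
        assert got == self.chord_knee(list(range(1, 7)),
                                      [100, 40, 20, 15, 14, 13])

    def test_linear_curve_returns_k_min(self, monkeypatch):
        import morphomil.splits as sp

        class FakeAssign:
            def __init__(self, cost): self.cost = cost

        monkeypatch.setattr(sp, "kmodes",
                            lambda X, k, seed=0, n_init=10: FakeAssign(60 - 10 * k))
        X = np.array([[0, 0, 0, 0], [0, 0, 0, 1], [0, 0, 1, 0],
                      [0, 1, 0, 0], [1, 0, 0, 0], [1, 1, 1, 1]])
        with pytest.warns(UserWarning, match="linear"):
            assert sp.elbow_select_k(X, k_range=range(1, 7), seed=0) == 1

    def test_flat_curve_warns_and_returns_k_min(self):
        X = np.tile([0, 1, 2, 0], (10, 1))  # one distinct row: only K=1 feasible
        with pytest.warns(UserWarning):
            assert elbow_select_k(X, seed=0) == 1


class TestBuildFolds:
    def random_binned(self, rng, n):
        return bin_covariates(cohort_frame(
            rng.uniform(40, 90, n),
            rng.choice(["M", "F"], n),
            rng.uniform(18, 40, n),
            rng.uniform(20_000, 90_000, n),
        ))

    @pytest.mark.parametrize("n", [11, 57, 123, 500])
    def test_test_folds_partition_cohort(self, rng, n):
        binned = self.random_binned(rng, n)
        folds = build_folds(binned, K=3, seed=0)
        assert sorted(folds["test_fold"].unique()) == [0, 1, 2, 3, 4]
        # every patient in exactly one test fold
        assert len(folds) == n
        assert folds["patient_id"].is_unique

    @pytest.mark.parametrize("n", [57, 123, 500])
    def test_train_val_test_disjoint_and_exhaustive(self, rng, n):
        binned = self.random_binned(rng, n)
        folds = build_folds(binned, K=3, seed=0)
        for f in range(5):
            ids = get_fold(folds, f)
            all_ids = ids["train"] + ids["val"] + ids["test"]
            assert len(all_ids) == n
            assert len(set(all_ids)) == n

    def test_per_cluster_fold_share_within_one(self, rng):
        binned = self.random_binned(rng, 200)
        folds = build_folds(binned, K=4, seed=1)
        for k in folds["cluster_id"].unique():
            sizes = folds[folds["cluster_id"] == k]["test_fold"].value_counts()
            sizes = sizes.reindex(range(5), fill_value=0)
            expected = (folds["cluster_id"] == k).sum() / 5
            assert np.all(np.abs(sizes - expected) <= 1)

    def test_validation_is_ten_percent_of_total(self, rng):
        binned = self.random_binned(rng, 100)
        folds = build_folds(binned, K=1, seed=0)
        for f in range(5):
            ids = get_fold(folds, f)
            assert len(ids["test"]) == 20
            assert len(ids["val"]) == 10
            assert len(ids["train"]) == 70
            # validation drawn from the non-test pool only
            assert not set(ids["val"]) & set(ids["test"])

    def test_labels_never_consulted(self, rng):
        """Fold assignment is a function of covariates only: an outcome
        column must not change the split."""
        binned = self.random_binned(rng, 80)
        a = build_folds(binned, K=3, seed=4)
        binned2 = binned.copy()
        binned2["label"] = np.tile([0, 1], 40)
        b = build_folds(binned2, K=3, seed=4)
        pd.testing.assert_frame_equal(a, b)
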