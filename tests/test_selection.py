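"""Folds, cross-validation error, bitmask search and usage rates."""

import numpy as np
import pytest

from enoseml import (
    CombinationMask,
    SubsetSearch,
    cv_error,
    decode_mask,
    encode_mask,
    enumerate_combinations,
    evaluate_unknowns,
    make_folds,
    optimize_hyperparameters,
    search_combinations,
    usage_rates,
)
from enoseml.regression import kernel_matrix
from enoseml.selection import SearchResult, usage_rate_table

from conftest import make_feature_matrix


def brute_force_cv(X, A, folds, lam, sigma):
    """Independent fold loop with explicit matrix inversion."""
    total = 0.0
    for s in range(1, folds.S + 1):
        te = folds.test_indices(s)
        tr = folds.train_indices(s)
        K = kernel_matrix(X[tr], X[tr], sigma)
        inv = np.linalg.inv(K + lam * np.eye(len(tr)))
        preds = kernel_matrix(X[te], X[tr], sigma) @ inv @ A[tr]
        total += np.mean((A[te] - preds) ** 2)
    return total / folds.S


class TestFolds:
    def test_96_rows_24_folds_all_size_four(self):
        folds = make_folds(96, 24, seed=0)
        sizes = [len(folds.test_indices(s)) for s in range(1, 25)]
        assert sizes == [4] * 24

    def test_leave_one_out(self):
        folds = make_folds(10, 10, seed=1)
        assert all(len(folds.test_indices(s)) == 1 for s in range(1, 11))

    def test_deterministic_under_seed(self):
        a = make_folds(50, 7, seed=42)
        b = make_folds(50, 7, seed=42)
        assert np.array_equal(a.assignment, b.assignment)

    def test_folds_partition_rows(self):
        folds = make_folds(53, 8, seed=3)
        all_idx = np.concatenate(
            [folds.test_indices(s) for s in range(1, 9)])
        assert sorted(all_idx) == list(range(53))
        sizes = [len(folds.test_indices(s)) for s in range(1, 9)]
        assert max(sizes) - min(sizes) <= 1

    def test_sample_grouping_keeps_cycles_together(self):
        names = [f"s{i}" for i in range(32) for _ in range(3)]
        folds = make_folds(96, 24, seed=5, grouping="sample",
                           sample_names=names)
        for i in range(32):
            rows = folds.assignment[3 * i: 3 * i + 3]
            assert len(set(rows)) == 1

    def test_invalid_requests_rejected(self):
        with pytest.raises(ValueError):
            make_folds(5, 6, seed=0)
        with pytest.raises(ValueError):
            make_folds(10, 1, seed=0)
        with pytest.raises(ValueError):
            make_folds(10, 3, seed=0, grouping="sample")


class TestCVError:
    def test_identical_rows_equal_targets_zero_error(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0]])
        A = np.array([7.0, 7.0])
        folds = make_folds(2, 2, seed=0)
        assert cv_error(X, A, folds, lam=0.0, sigma=1.0) == pytest.approx(0.0)

    def test_two_point_shrinkage_closed_form(self):
        # constant targets a0, large sigma: each fold predicts a0/(1+lam),
        # so Delta = (a0 * lam / (1 + lam))^2
        a0, lam = 20.0, 5.0
        X = np.array([[0.0], [1.0]])
        A = np.array([a0, a0])
        folds = make_folds(2, 2, seed=0)
        got = cv_error(X, A, folds, lam=lam, sigma=1e6)
        assert got == pytest.approx((a0 * lam / (1 + lam)) ** 2, rel=1e-6)

    def test_matches_independent_fold_loop(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(12, 3))
        A = rng.uniform(0, 40, size=12)
        folds = make_folds(12, 4, seed=2)
        for lam, sigma in [(0.1, 1.0), (1.0, 0.5), (1e-4, 3.0)]:
            assert cv_error(X, A, folds, lam, sigma) == pytest.approx(
                brute_force_cv(X, A, folds, lam, sigma), rel=1e-8)

    def test_invariant_under_consistent_row_permutation(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(12, 2))
        A = rng.normal(size=12)
        folds = make_folds(12, 3, seed=0)
        perm = rng.permutation(12)
        permuted = type(folds)(S=3, assignment=folds.assignment[perm],
                               seed=0, grouping="row")
        assert cv_error(X[perm], A[perm], permuted, 0.1, 1.0) == pytest.approx(
            cv_error(X, A, folds, 0.1, 1.0), rel=1e-10)

    def test_invariant_under_fold_relabeling(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(9, 2))
        A = rng.normal(size=9)
        folds = make_folds(9, 3, seed=1)
        relabel = {1: 3, 2: 1, 3: 2}
        relabeled = type(folds)(
            S=3,
            assignment=np.array([relabel[s] for s in folds.assignment]),
            seed=1, grouping="row")
        assert cv_error(X, A, relabeled, 0.5, 2.0) == pytest.approx(
            cv_error(X, A, folds, 0.5, 2.0), rel=1e-12)


class TestOptimize:
    def test_singleton_grid(self):
        rng = np.random.default_rng(1)
        X, A = rng.normal(size=(8, 2)), rng.normal(size=8)
        folds = make_folds(8, 4, seed=0)
        cv = optimize_hyperparameters(X, A, folds, [(0.1, 1.0)])
        assert (cv.lambda_star, cv.sigma_star) == (0.1, 1.0)
        assert cv.delta_star == pytest.approx(
            cv_error(X, A, folds, 0.1, 1.0))

    def test_duplicate_optimum_first_occurrence_wins(self):
        rng = np.random.default_rng(2)
        X, A = rng.normal(size=(8, 2)), rng.normal(size=8)
        folds = make_folds(8, 4, seed=0)
        grid = [(0.1, 1.0), (0.1, 1.0), (5.0, 0.1)]
        cv = optimize_hyperparameters(X, A, folds, grid)
        deltas = cv.deltas
        assert deltas[0] == deltas[1]
        if deltas[0] <= deltas[2]:
            assert cv.delta_star == deltas[0]

    def test_optimum_not_beaten_anywhere_on_grid(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(15, 2))
        A = X @ np.array([3.0, -1.0]) + rng.normal(0, 0.1, size=15)
        folds = make_folds(15, 5, seed=0)
        grid = [(l, s) for l in (1e-4, 1e-2, 1.0) for s in (0.3, 1.0, 3.0)]
        cv = optimize_hyperparameters(X, A, folds, grid)
        assert np.nanmin(cv.deltas) == cv.delta_star

    def test_empty_grid_rejected(self):
        folds = make_folds(4, 2, seed=0)
        with pytest.raises(ValueError):
            optimize_hyperparameters(np.zeros((4, 1)), np.zeros(4), folds, [])


class TestMasks:
    def test_parameters_134_encode_to_13(self):
        assert encode_mask({1, 3, 4}) == 13
        assert decode_mask(13) == {1, 3, 4}
        assert CombinationMask(13, 4).binary == "1101"

    def test_boundary_masks(self):
        assert encode_mask({1}) == 1
        assert encode_mask({1, 2, 3, 4}) == 15

    def test_encode_decode_bijective_over_all_subsets(self):
        seen = set()
        for m in range(1, 16):
            params = decode_mask(m, 4)
            assert encode_mask(params, 4) == m
            seen.add(frozenset(params))
        assert len(seen) == 15

    def test_invalid_masks_rejected(self):
        with pytest.raises(ValueError):
            decode_mask(0, 4)
        with pytest.raises(ValueError):
            decode_mask(16, 4)
        with pytest.raises(ValueError):
            encode_mask(set())
        with pytest.raises(ValueError):
            encode_mask({5}, 4)

    def test_enumeration_counts(self):
        assert len(enumerate_combinations(4)) == 15
        assert len(enumerate_combinations(16)) == 65535
        assert [m.mask for m in enumerate_combinations(1)] == [1]


class TestSearch:
    def _tiny(self, seed=0, n=12):
        rng = np.random.default_rng(seed)
        X = np.column_stack([
            np.linspace(0, 40, n) / 40.0,            # informative
            rng.normal(size=n),                      # noise
        ])
        A = np.linspace(0, 40, n)
        return make_feature_matrix(X, A, columns=["ch:p1", "ch:p2"])

    def test_matches_nested_loop_recomputation(self):
        fm = self._tiny()
        folds = make_folds(12, 4, seed=0)
        grid = [(0.01, 0.5), (0.01, 2.0), (1.0, 0.5), (1.0, 2.0)]
        results = search_combinations(fm, folds, grid)
        X = fm.X.to_numpy()
        for r in results:
            cols = list(r.mask.bits)
            expected = min(
                brute_force_cv(X[:, cols], fm.A, folds, lam, sigma)
                for lam, sigma in grid
            )
            assert r.delta == pytest.approx(expected, rel=1e-8)
        deltas = [r.delta for r in results]
        assert deltas == sorted(deltas)
        assert [r.rank for r in results] == [1, 2, 3]

    def test_informative_column_always_selected(self):
        fm = self._tiny()
        folds = make_folds(12, 4, seed=0)
        grid = [(0.01, 0.5), (0.01, 2.0)]
        results = search_combinations(fm, folds, grid)
        assert 0 in results[0].mask.bits  # informative column in best mask

    def test_duplicate_best_column_tie_broken_by_smaller_mask(self):
        n = 10
        x = np.linspace(0, 1, n)
        fm = make_feature_matrix(np.column_stack([x, x]),
                                 A=np.linspace(0, 40, n),
                                 columns=["ch:p1", "ch:p2"])
        folds = make_folds(n, 5, seed=0)
        results = search_combinations(fm, folds, [(0.1, 1.0)])
        singles = [r for r in results if len(r.mask) == 1]
        assert singles[0].delta == pytest.approx(singles[1].delta, rel=1e-12)
        # equal Delta: the smaller mask integer must rank first
        assert singles[0].mask.mask == 1
        assert singles[0].rank < singles[1].rank

    def test_search_counts_single_and_multi_channel(self):
        rng = np.random.default_rng(6)
        fm4 = make_feature_matrix(rng.normal(size=(12, 4)),
                                  A=rng.uniform(0, 40, 12))
        folds = make_folds(12, 4, seed=0)
        assert len(search_combinations(fm4, folds, [(0.1, 1.0)])) == 15


class TestUsageRates:
    def _result(self, mask, rank, labels=("ch:p1", "ch:p2", "ch:p3", "ch:p4")):
        return SearchResult(mask=CombinationMask(mask, len(labels)), cv=None,
                            column_labels=tuple(labels), rank=rank)

    def test_single_top_result(self):
        results = [self._result(1, 1), self._result(15, 2)]
        rates = usage_rates(results, top_k=1)
        assert rates["ch:p1"] == 100.0
        assert rates["ch:p2"] == rates["ch:p3"] == rates["ch:p4"] == 0.0

    def test_counting_over_top_two(self):
        results = [self._result(1, 1), self._result(5, 2)]  # {p1}, {p1,p3}
        rates = usage_rates(results, top_k=2)
        assert rates["ch:p1"] == 100.0
        assert rates["ch:p3"] == 50.0

    def test_exhaustive_two_column_rates(self):
        labels = ("ch:p1", "ch:p2")
        results = [
            SearchResult(mask=CombinationMask(m, 2), cv=None,
                         column_labels=labels, rank=i + 1)
            for i, m in enumerate([1, 2, 3])
        ]
        rates = usage_rates(results, top_k=3)
        assert rates["ch:p1"] == pytest.approx(200.0 / 3)
        assert rates["ch:p2"] == pytest.approx(200.0 / 3)

    def test_pivoted_table_shape(self):
        rates = usage_rates([self._result(13, 1)], top_k=1)
        table = usage_rate_table(rates)
        assert table.loc["p1", "ch"] == 100.0
        assert table.loc["p2", "ch"] == 0.0

    def test_invalid_top_k_rejected(self):
        results = [self._result(1, 1)]
        with pytest.raises(ValueError):
            usage_rates(results, top_k=0)
        with pytest.raises(ValueError):
            usage_rates(results, top_k=2)


class TestUninformativeParameter:
    def test_quasi_equilibrium_slope_without_information_is_penalized(self):
        """When every component equilibrates before the t_a+1 s anchor, the
        quasi-equilibrium slope (p2) is pure sensor noise: adding it to any
        subset never lowers Delta, it is the least-used feature in the top
        masks, and on its own it ranks last."""
        from enoseml.schedule import AcquisitionSchedule
        from enoseml.signals import extract_features, normalize_features
        from enoseml.synth import (GeneratorConfig, build_default_sample_table,
                                   default_channels, simulate_dataset)

        channel = default_channels()[0]
        channel.tau_ads[:] = 0.2  # all kinetics faster than the 1 s anchor
        config = GeneratorConfig(
            schedule=AcquisitionSchedule(), channels=[channel],
            samples=build_default_sample_table(seed=0), seed=0)
        signals, metadata = simulate_dataset(config)
        fm = normalize_features(extract_features(signals, metadata))
        grid = [(l, s) for l in (1e-4, 1e-2, 1.0) for s in (0.5, 1.0, 3.0)]
        res = SubsetSearch(fm, S=24, seed=0, grouping="sample",
                           grid=grid).fit()

        delta = {r.mask.mask: r.delta for r in res.results}
        p2_bit = 1 << 1
        for mask in delta:
            if not mask & p2_bit and mask | p2_bit in delta:
                assert delta[mask | p2_bit] >= delta[mask]
        assert res.results[-1].mask.mask == p2_bit  # p2 alone is worst
        rates = usage_rates(res.results, top_k=5)
        assert rates["C18-like:p2"] < min(
            rates["C18-like:p1"], rates["C18-like:p3"], rates["C18-like:p4"])


class TestUnknownEvaluation:
    def _features_with_unknowns(self):
        rng = np.random.default_rng(10)
        x = np.linspace(0, 1, 18)
        X = np.column_stack([x, rng.normal(size=18)])
        A = 40.0 * x
        names = [f"s{i // 3}" for i in range(18)]
        known = np.array([i < 9 for i in range(18)])
        return make_feature_matrix(X, A, sample_names=names, known=known,
                                   columns=["ch:p1", "ch:p2"])

    def test_record_count_three_samples_three_cycles(self):
        fm = self._features_with_unknowns()
        folds = make_folds(9, 3, seed=0)
        results = search_combinations(fm.subset_rows(np.arange(9)), folds,
                                      [(0.01, 1.0)])
        parity = evaluate_unknowns(fm, results[0])
        assert len(parity) == 9  # 3 unknown samples x 3 cycles
        assert not parity["known"].any()

    def test_unknown_identical_to_training_row_interpolates(self):
        X = np.array([[0.0], [1.0], [2.0], [1.0]])
        A = np.array([0.0, 10.0, 20.0, 99.0])  # last row's target is ignored
        fm = make_feature_matrix(X, A, known=[True, True, True, False],
                                 columns=["ch:p1"])
        result = SearchResult(
            mask=CombinationMask(1, 1), cv=None, column_labels=("ch:p1",))
        parity = evaluate_unknowns(fm, result, lam=0.0, sigma=1.0)
        assert parity["predicted"].iloc[0] == pytest.approx(10.0, abs=1e-8)

    def test_subset_search_model_wrapper(self):
        fm = self._features_with_unknowns()
        res = SubsetSearch(fm, S=3, seed=0, grouping="sample",
                           grid=[(0.01, 1.0), (1.0, 1.0)]).fit()
        assert len(res.results) == 3
        assert res.best.delta <= res.results[-1].delta
        assert "Delta" in res.summary()
        unknowns = res.evaluate_unknowns()
        assert len(unknowns) == 9
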