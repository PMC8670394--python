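"""Partition functional: the closed-form value, local search against
exhaustive enumeration, threshold scanning and group/time dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from absflow.criteria import ConstantColumnError
from absflow.datasets import CohortConfig, CohortDataset, generate

from absflow.partition import (
    exhaustive_partition,
    functional_dynamics,
    functional_value,
    is_one_move_optimal,
    link_matrix,
    optimize_partition,
    scan_threshold,
    select_threshold,
)
from tests.conftest import make_block_data


def random_link(rng, n=7):
    A = rng.random((n, n))
    A = (A + A.T) / 2.0
    np.fill_diagonal(A, 0.0)
    return A


def oracle_functional(A, labels, a):
    """Independent pair-enumeration double loop."""
    total = 0.0
    n = A.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            if labels[i] == labels[j]:
                total += A[i, j] - a
    return total


class TestLinkMatrix:
    def test_perfect_correlation_gives_unit_link(self, rng):
        x = rng.standard_normal(30)
        X = np.column_stack([x, 3 * x + 2, rng.standard_normal(30)])
        lm = link_matrix(X)
        assert lm.matrix[0, 1] == pytest.approx(1.0)
        assert np.allclose(lm.matrix, lm.matrix.T)
        assert np.all(np.diag(lm.matrix) == 0)

    def test_hand_computed_pearson_example(self):
        X = np.array([[1.0, 2.0, 1.0], [2.0, 1.0, 2.0],
                      [3.0, 4.0, 2.0], [4.0, 3.0, 5.0]])
        lm = link_matrix(X, method="signed")
        # col0 vs col1: dx=(-1.5,-.5,.5,1.5), dy=(-.5,-1.5,1.5,.5)
        # r = (0.75+0.75+0.75+0.75)/sqrt(5*5) = 0.6
        assert lm.matrix[0, 1] == pytest.approx(0.6)

    def test_absolute_mode_flips_negative_links(self, rng):
        x = rng.standard_normal(40)
        X = np.column_stack([x, -x + 0.01 * rng.standard_normal(40)])
        assert link_matrix(X, method="signed").matrix[0, 1] < -0.99
        assert link_matrix(X, method="abs").matrix[0, 1] > 0.99

    def test_constant_column_is_an_error(self, rng):
        X = rng.standard_normal((20, 3))
        X[:, 2] = 1.0
        with pytest.raises(ConstantColumnError):
            link_matrix(X)


class TestFunctionalValue:
    def test_all_singletons_score_zero(self, rng):
        A = random_link(rng)
        assert functional_value(A, np.arange(7), a=0.3) == 0.0

    def test_direct_substitution_example(self):
        A = np.array([[0.0, 0.8], [0.8, 0.0]])
        assert functional_value(A, [0, 0], a=0.3) == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_pair_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        A = random_link(rng, n=6)
        labels = rng.integers(0, 3, size=6)
        a = float(rng.random())
        assert functional_value(A, labels, a) == pytest.approx(
            oracle_functional(A, labels, a))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.floats(0.0, 1.0),
           st.lists(st.integers(0, 4), min_size=4, max_size=9))
    def test_oracle_agreement_for_arbitrary_partitions(self, seed, a, labs):
        A = random_link(np.random.default_rng(seed), n=len(labs))
        labels = np.asarray(labs)
        assert functional_value(A, labels, a) == pytest.approx(
            oracle_functional(A, labels, a))

    def test_fixed_partition_slope_is_minus_pair_count(self, rng):
        A = random_link(rng)
        labels = np.array([0, 0, 0, 1, 1, 2, 2])
        pairs = 3 + 1 + 1  # within-class unordered pairs
        f1 = functional_value(A, labels, 0.2)
        f2 = functional_value(A, labels, 0.5)
        assert f1 - f2 == pytest.approx(0.3 * pairs)

    def test_invalid_partition_rejected(self, rng):
        A = random_link(rng)
        with pytest.raises(ValueError):
            functional_value(A, [[0, 1], [1, 2], [3, 4, 5, 6]], a=0.1)


class TestOptimizePartition:
    def test_threshold_above_all_links_gives_singletons(self, rng):
        A = random_link(rng)
        res = optimize_partition(A, a=1.1, restarts=5, seed=0)
        assert res.n_classes == 7 and res.functional == 0.0

    def test_zero_threshold_with_positive_links_gives_one_class(self, rng):
        A = random_link(rng) + 0.05
        np.fill_diagonal(A, 0.0)
        res = optimize_partition(A, a=0.0, restarts=5, seed=0)
        assert res.n_classes == 1

    def test_result_is_one_move_optimal(self, rng):
        for seed in range(10):
            A = random_link(np.random.default_rng(seed))
            res = optimize_partition(A, a=0.45, restarts=10, seed=seed)
            assert is_one_move_optimal(A, res.labels, 0.45)

    def test_local_search_matches_exhaustive_on_most_instances(self):
        hits = 0
        for seed in range(40):
            A = random_link(np.random.default_rng(seed))
            a = 0.2 + 0.6 * np.random.default_rng(seed + 1000).random()
            local = optimize_partition(A, a, restarts=20, seed=seed)
            exact = exhaustive_partition(A, a)
            hits += abs(local.functional - exact.functional) < 1e-9
        assert hits >= 38  # >= 95 percent of seeded instances

    def test_estimator_interface_recovers_planted_blocks(self, rng):
        from absflow.partition import LinkPartitioner

        X, labels = make_block_data(rng, n_rows=400, sizes=(4, 3, 3),
                                    rho_in=0.7, rho_out=0.1)
        lp = LinkPartitioner(threshold=0.4, restarts=10).fit(X)
        assert adjusted_rand_score(labels, lp.labels_) == 1.0
        auto = LinkPartitioner(restarts=10).fit(X)  # plateau-selected threshold
        assert adjusted_rand_score(labels, auto.labels_) == 1.0
        assert lp.get_params()["threshold"] == 0.4

    def test_planted_blocks_recovered(self, rng):
        X, labels = make_block_data(rng, n_rows=400, sizes=(6, 6, 5, 4),
                                    rho_in=0.7, rho_out=0.1)
        lm = link_matrix(X)
        res = optimize_partition(lm, a=0.4, restarts=20, seed=0)
        assert adjusted_rand_score(labels, res.labels) == 1.0


class TestThresholdScan:
    def test_grid_above_max_link_gives_singletons_everywhere(self, rng):
        A = random_link(rng)
        scan = scan_threshold(A, [A.max() + 0.01], restarts=5, seed=0)
        assert scan.results[0].functional == 0.0
        assert scan.results[0].n_classes == 7

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError):
            scan_threshold(random_link(rng), [])

    def test_class_count_non_decreasing_on_planted_blocks(self, rng):
        X, _ = make_block_data(rng, n_rows=500, sizes=(4, 3, 3),
                               rho_in=0.7, rho_out=0.1)
        lm = link_matrix(X)
        scan = scan_threshold(lm, np.arange(0.05, 0.9, 0.05), restarts=10, seed=0)
        counts = [r.n_classes for r in scan.results]
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_plateau_selection_recovers_planted_partition(self, rng):
        X, labels = make_block_data(rng, n_rows=400, sizes=(6, 6, 5, 4),
                                    rho_in=0.7, rho_out=0.1)
        lm = link_matrix(X)
        sel = select_threshold(scan_threshold(lm, np.arange(0.0, 0.92, 0.02),
                                              restarts=10, seed=0))
        assert adjusted_rand_score(labels, sel.labels) == 1.0
        assert 0.1 < sel.threshold < 0.7


class TestFunctionalDynamics:
    def test_time_constant_data_has_no_shift(self):
        ds = generate(CohortConfig(n_patients_per_group=(60, 60, 60), seed=3,
                                   missing_rate=0.0))
        frozen = ds.values.copy()
        for t in range(1, 6):
            frozen[:, :, t] = frozen[:, :, 0]
        static = CohortDataset(values=frozen, mask=np.zeros_like(ds.mask),
                               groups=ds.groups, parameters=ds.parameters)
        fd = functional_dynamics(static, restarts=5, seed=0,
                                 include_overall=False)
        for g in (1, 2, 3):
            assert fd.time_variance(g, "F_ref") == pytest.approx(0.0)
            assert fd.time_variance(g, "a") == pytest.approx(0.0)

    def test_default_cohort_reproduces_critical_periods(self, imputed_cohort):
        fd = functional_dynamics(imputed_cohort, restarts=10, seed=0,
                                 include_overall=False)
        assert fd.critical_period(1) == (5, 6)
        assert fd.critical_period(2) == (5, 6)
        assert fd.time_variance(2) > fd.time_variance(1)
        assert fd.time_variance(2, "a") > fd.time_variance(1, "a")
        assert fd.time_variance(3) <= min(fd.time_variance(1), fd.time_variance(2))
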