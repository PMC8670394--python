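"""Criteria function: correlation estimation, the quadratic form, the
monotone branch-and-bound subset search and group/time dynamics."""

import numpy as np
import pytest
from sklearn.covariance import EmpiricalCovariance

from absflow.criteria import (
    CFResult,
    ConstantColumnError,
    CriteriaFunction,
    best_subset_cf,
    best_subset_profile,
    cf_dynamics,
    compute_cf,
    estimate_correlation,
    exhaustive_best_subset,
)
from absflow.datasets import CohortConfig, generate
from absflow.impute import impute_cohort
from tests.conftest import make_block_data


class TestEstimateCorrelation:
    def test_matches_textbook_pearson_on_hand_example(self):
        # r = sum(dx dy) / sqrt(sum dx^2 sum dy^2) = 8 / sqrt(10 * 10) = 0.8
        data = np.array([[1, 2], [2, 1], [3, 4], [4, 3], [5, 5]], dtype=float)
        s = estimate_correlation(data)
        assert s.matrix[0, 1] == pytest.approx(0.8)
        assert np.allclose(s.matrix @ s.precision, np.eye(2), atol=1e-8)

    def test_independent_large_sample_is_near_identity(self, rng):
        X = rng.standard_normal((10000, 5))
        s = estimate_correlation(X)
        off = s.matrix[~np.eye(5, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_perfectly_correlated_columns_get_regularized(self, rng):
        x = rng.standard_normal(50)
        X = np.column_stack([x, 2 * x + 1, rng.standard_normal(50)])
        s = estimate_correlation(X)
        assert s.ridge > 0
        assert np.isfinite(s.precision).all()

    def test_constant_column_error_names_the_column(self, rng):
        X = rng.standard_normal((20, 3))
        X[:, 1] = 7.0
        with pytest.raises(ConstantColumnError, match="pCO2"):
            estimate_correlation(X, names=("pH", "pCO2", "Lac"))


class TestComputeCF:
    def test_identity_correlation_reduces_to_squared_norm(self):
        assert compute_cf(np.array([1.0, 2.0]), np.eye(2)) == pytest.approx(5.0)

    def test_one_dimensional_case(self):
        assert compute_cf(np.array([3.0]), np.eye(1)) == pytest.approx(9.0)

    def test_equicorrelated_closed_form_and_solve_oracle(self):
        S = np.full((3, 3), 0.5)
        np.fill_diagonal(S, 1.0)
        x = np.ones(3)
        # closed form for equicorrelation: m / (1 + (m-1) r) = 3 / 2
        assert compute_cf(x, S) == pytest.approx(1.5)
        assert compute_cf(x, S) == pytest.approx(float(x @ np.linalg.solve(S, x)))

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            compute_cf(np.ones(3), np.eye(2))

    def test_matches_sklearn_mahalanobis(self, rng):
        X, _ = make_block_data(rng, n_rows=200, sizes=(3, 3))
        z = (X - X.mean(0)) / X.std(0, ddof=1)
        cf = CriteriaFunction().fit(X).score_samples(X)
        oracle = EmpiricalCovariance().fit(z).mahalanobis(z)
        # same quadratic form up to the n vs n-1 covariance denominator
        assert np.allclose(cf, oracle * (X.shape[0] - 1) / X.shape[0], rtol=1e-6)

    def test_monotone_under_nested_subsets(self, rng):
        X, _ = make_block_data(rng, n_rows=80, sizes=(4, 4))
        s = estimate_correlation(X)
        z = (X - s.mean) / s.scale
        for _ in range(20):
            size_b = int(rng.integers(2, 9))
            b = sorted(rng.choice(8, size=size_b, replace=False).tolist())
            a = sorted(rng.choice(b, size=int(rng.integers(1, size_b)),
                                  replace=False).tolist())
            row = z[int(rng.integers(0, 80))]
            cf_a = compute_cf(row[a], s.matrix[np.ix_(a, a)])
            cf_b = compute_cf(row[b], s.matrix[np.ix_(b, b)])
            assert cf_a <= cf_b + 1e-9

    def test_in_sample_mean_cf_is_exactly_m_scaled(self, rng):
        # trace identity: average in-sample CF = m (n-1) / n for every subset
        X, _ = make_block_data(rng, n_rows=50, sizes=(3, 3))
        n = X.shape[0]
        cf = CriteriaFunction().fit(X).score_samples(X)
        assert cf.mean() == pytest.approx(6 * (n - 1) / n, rel=1e-9)

    def test_out_of_sample_mean_cf_is_near_m(self, rng):
        X, _ = make_block_data(rng, n_rows=10000, sizes=(3, 3))
        fresh, _ = make_block_data(np.random.default_rng(99), n_rows=10000,
                                   sizes=(3, 3))
        cf = CriteriaFunction().fit(X).score_samples(fresh)
        assert abs(cf.mean() - 6) / 6 < 0.05  # Mahalanobis property


class TestBestSubset:
    def test_full_set_is_the_only_size_n_subset(self, rng):
        X, _ = make_block_data(rng, n_rows=40, sizes=(3, 2))
        res = best_subset_cf(X, 5)
        assert res.subset.indices == (0, 1, 2, 3, 4)

    def test_objective_profile_is_non_decreasing_in_m(self, rng):
        est, _ = make_block_data(rng, n_rows=50, sizes=(3, 3))
        ev, _ = make_block_data(rng, n_rows=50, sizes=(3, 3))
        prof = best_subset_profile(est, [1, 2, 3, 4, 5], eval_data=ev)
        assert (np.diff(prof["objective"]) >= -1e-9).all()

    @pytest.mark.parametrize("seed", range(10))
    def test_branch_and_bound_equals_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        est, _ = make_block_data(rng, n_rows=60, sizes=(4, 3, 3))
        ev = est + 0.8 * rng.standard_normal(est.shape)
        m = int(rng.integers(2, 6))
        bb = best_subset_cf(est, m, eval_data=ev)
        ex = exhaustive_best_subset(est, m, eval_data=ev)
        assert bb.subset.indices == ex.subset.indices
        assert bb.objective == pytest.approx(ex.objective, rel=1e-12)

    def test_candidate_pool_screening_stays_exact_inside_the_pool(self, rng):
        est, _ = make_block_data(rng, n_rows=60, sizes=(4, 4, 4))
        ev = est + 0.5 * rng.standard_normal(est.shape)
        pooled = best_subset_cf(est, 3, eval_data=ev, candidate_pool=6)
        assert len(pooled.subset.indices) == 3

    def test_infeasible_m_raises(self, rng):
        X, _ = make_block_data(rng, n_rows=30, sizes=(2, 2))
        with pytest.raises(ValueError):
            best_subset_cf(X, 5)


@pytest.fixture(scope="module")
def small_imputed():
    return impute_cohort(generate(CohortConfig(
        n_patients_per_group=(45, 45, 45), seed=8)))


class TestCFDynamics:

    def test_summary_covers_groups_timepoints_and_overall(self, small_imputed):
        res = cf_dynamics(small_imputed)
        assert isinstance(res, CFResult)
        assert set(res.summary["group"]) == {0, 1, 2, 3}
        assert set(res.summary["timepoint"]) == {1, 2, 3, 4, 5, 6}
        assert (res.per_patient["cf"] >= 0).all()

    def test_permuting_patients_leaves_the_table_unchanged(self, small_imputed):
        ds = small_imputed
        perm = np.random.default_rng(0).permutation(ds.n_patients)
        shuffled = type(ds)(values=ds.values[perm], mask=ds.mask[perm],
                            groups=ds.groups[perm], parameters=ds.parameters,
                            patient_ids=ds.patient_ids[perm])
        a = cf_dynamics(ds).summary.sort_values(["group", "timepoint"])
        b = cf_dynamics(shuffled).summary.sort_values(["group", "timepoint"])
        assert np.allclose(a[["mean_cf", "sd_cf"]], b[["mean_cf", "sd_cf"]])

    def test_duplicated_patients_get_identical_cf(self, rng):
        # consistency of the scoring: identical records score identically
        base, _ = make_block_data(rng, n_rows=15, sizes=(3, 2))
        doubled = np.vstack([base, base])
        cf = CriteriaFunction().fit(doubled).score_samples(doubled)
        assert np.allclose(cf[:15], cf[15:])

    def test_incomplete_dataset_is_rejected(self):
        ds = generate(CohortConfig(n_patients_per_group=(20, 20, 20), seed=1))
        with pytest.raises(ValueError, match="impute"):
            cf_dynamics(ds)
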