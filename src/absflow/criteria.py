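"""Criteria function: a Mahalanobis-type quadratic form CF = x' S^{-1} x.

The criteria function measures how consistently one patient's standardized
parameter vector x sits inside the correlation structure S of a reference
sample: CF is small when the parameters move together the way the sample
says they should, and grows when the patient's parameter system loses that
internal consistency.  It is monotone under adding parameters (the value
over a subset never exceeds the value over a superset), which is what makes
exact branch-and-bound subset search possible.

A fundamental identity constrains in-sample averages: when S is estimated
from the very rows being scored, the average CF equals m(n-1)/n for EVERY
m-parameter subset (trace identity of the quadratic form), so subset search
is only informative against a separate evaluation sample — see
:func:`best_subset_cf`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datasets import CohortDataset

OVERALL = 0  # group code for rows pooled over all groups


class ConstantColumnError(ValueError):
    def __init__(self, name: str | int):
        self.column = name
        super().__init__(f"column {name!r} is constant; correlation is undefined")


@dataclass(frozen=True)
class CorrelationStructure:
    """Estimated correlation matrix with its inverse and standardization."""

    matrix: np.ndarray
    precision: np.ndarray
    mean: np.ndarray
    scale: np.ndarray
    ridge: float = 0.0
    names: tuple[str, ...] | None = None

    @property
    def m(self) -> int:
        return self.matrix.shape[0]


def estimate_correlation(data: np.ndarray, names: tuple[str, ...] | None = None,
                         ridge: float = 1e-6,
                         cond_threshold: float = 1e10) -> CorrelationStructure:
    """Pearson correlation of standardized columns, ridge-regularized when
    ill-conditioned (condition number above ``cond_threshold``)."""
    X = np.asarray(data, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need a 2D matrix with at least 3 rows")
    if np.isnan(X).any():
        raise ValueError("correlation estimation requires complete data; impute first")
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    const = np.nonzero(scale == 0)[0]
    if const.size:
        label = names[const[0]] if names else int(const[0])
        raise ConstantColumnError(label)
    z = (X - mean) / scale
    corr = (z.T @ z) / (X.shape[0] - 1)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    used_ridge = 0.0
    if np.linalg.cond(corr) > cond_threshold:
        used_ridge = ridge
        corr = corr + ridge * np.eye(corr.shape[0])
    precision = np.linalg.inv(corr)
    return CorrelationStructure(matrix=corr, precision=precision, mean=mean,
                                scale=scale, ridge=used_ridge,
                                names=tuple(names) if names else None)


def compute_cf(x: np.ndarray, structure: CorrelationStructure | np.ndarray) -> float:
    """The quadratic form x' S^{-1} x for one standardized patient vector."""
    x = np.asarray(x, dtype=float)
    if isinstance(structure, CorrelationStructure):
        precision = structure.precision
    else:
        precision = np.linalg.inv(np.asarray(structure, dtype=float))
    if x.shape[0] != precision.shape[0]:
        raise ValueError(
            f"dimension mismatch: vector has {x.shape[0]}, matrix {precision.shape[0]}")
    return float(x @ precision @ x)


class CriteriaFunction(BaseEstimator):
    """Scikit-learn style estimator of per-record criteria-function values.

    ``fit`` estimates the standardization and correlation structure from a
    reference sample; ``score_samples`` returns CF for each row of a
    (possibly different) sample, standardized by the reference statistics.
    """

    def __init__(self, ridge: float = 1e-6, cond_threshold: float = 1e10):
        self.ridge = ridge
        self.cond_threshold = cond_threshold

    def fit(self, X: np.ndarray, y=None, names: tuple[str, ...] | None = None):
        self.structure_ = estimate_correlation(X, names=names, ridge=self.ridge,
                                               cond_threshold=self.cond_threshold)
        self.n_features_in_ = self.structure_.m
        return self

    def score_samples(self, X: np.ndarray) -> np.ndarray:
        s = self.structure_
        z = (np.asarray(X, dtype=float) - s.mean) / s.scale
        return np.einsum("ij,jk,ik->i", z, s.precision, z)


@dataclass(frozen=True)
class FeatureSubset:
    """An ordered, duplicate-free subset of parameter names."""

    names: tuple[str, ...]
    indices: tuple[int, ...]

    @property
    def m(self) -> int:
        return len(self.names)


@dataclass
class BestSubsetResult:
    subset: FeatureSubset
    objective: float
    n_evaluated: int  # objective evaluations spent by the search


def _subset_objective_factory(est_data: np.ndarray, eval_data: np.ndarray | None,
                              ridge: float, cond_threshold: float):
    """Mean CF over evaluation rows as a function of the feature subset.

    Correlation and standardization come from ``est_data``; the objective
    for subset A is trace(R_A^{-1} G_A) with G the Gram matrix of the
    standardized evaluation rows, i.e. the mean quadratic form.
    """
    structure = estimate_correlation(est_data, ridge=ridge,
                                     cond_threshold=cond_threshold)
    rows = est_data if eval_data is None else np.asarray(eval_data, dtype=float)
    z = (rows - structure.mean) / structure.scale
    gram = (z.T @ z) / z.shape[0]
    corr = structure.matrix

    def objective(subset: tuple[int, ...]) -> float:
        idx = np.asarray(subset)
        sub = corr[np.ix_(idx, idx)]
        return float(np.trace(np.linalg.solve(sub, gram[np.ix_(idx, idx)])))

    return objective


def best_subset_cf(est_data: np.ndarray, m: int, eval_data: np.ndarray | None = None,
                   names: tuple[str, ...] | None = None, ridge: float = 1e-6,
                   cond_threshold: float = 1e10,
                   candidate_pool: int | None = None) -> BestSubsetResult:
    """Exact branch-and-bound search for the m-parameter subset maximizing
    the mean criteria function.

    The search removes parameters from the full set depth-first; because CF
    is monotone under nesting, the objective of the current (super)set is an
    upper bound for every subset below it, and a branch whose bound falls
    strictly below the incumbent is pruned without losing optimality.  Ties
    resolve to the lexicographically smallest index subset.

    The removal tree grows exponentially in the parameter count, so for
    high-dimensional inputs ``candidate_pool`` screens the parameters down
    to the pool with the largest single-parameter objectives and runs the
    exact search inside that pool.

    Without a separate ``eval_data`` sample the objective is the in-sample
    mean CF, which the trace identity makes constant in the subset; the
    search then simply certifies that degeneracy by returning the first
    size-m subset.
    """
    est_data = np.asarray(est_data, dtype=float)
    p = est_data.shape[1]
    if not 1 <= m <= p:
        raise ValueError(f"infeasible subset size m={m} for {p} parameters")
    objective = _subset_objective_factory(est_data, eval_data, ridge, cond_threshold)

    pool = tuple(range(p))
    if candidate_pool is not None and candidate_pool < p:
        if candidate_pool < m:
            raise ValueError("candidate_pool must be at least m")
        marginals = np.array([objective((i,)) for i in range(p)])
        pool = tuple(sorted(np.argsort(-marginals)[:candidate_pool].tolist()))
        full_objective = objective
        objective = lambda subset: full_objective(tuple(pool[i] for i in subset))
        p = len(pool)

    best_subset: tuple[int, ...] | None = None
    best_val = -np.inf
    n_eval = 0

    # greedy backward-elimination warm start gives the pruning rule a strong
    # incumbent before the exact search begins
    greedy = tuple(range(p))
    while len(greedy) > m:
        drops = [greedy[:i] + greedy[i + 1:] for i in range(len(greedy))]
        greedy = max(drops, key=objective)
    best_subset, best_val = None, objective(greedy) - 1e-12

    def visit(subset: tuple[int, ...], start: int) -> None:
        nonlocal best_subset, best_val, n_eval
        val = objective(subset)
        n_eval += 1
        if len(subset) == m:
            if val > best_val or (val == best_val
                                  and (best_subset is None or subset < best_subset)):
                best_val, best_subset = val, subset
            return
        if val < best_val:
            return  # monotone bound: every descendant scores <= val
        for pos in range(start, len(subset)):
            if len(subset) - 1 < m:
                break
            child = subset[:pos] + subset[pos + 1:]
            # removing position pos keeps enough elements iff the remaining
            # removals can still reach size m
            if len(child) >= m:
                visit(child, pos)

    visit(tuple(range(p)), 0)
    assert best_subset is not None
    best_subset = tuple(pool[i] for i in best_subset)
    subset_names = tuple(names[i] for i in best_subset) if names else tuple(
        str(i) for i in best_subset)
    return BestSubsetResult(FeatureSubset(subset_names, best_subset), best_val, n_eval)


def exhaustive_best_subset(est_data: np.ndarray, m: int,
                           eval_data: np.ndarray | None = None,
                           ridge: float = 1e-6,
                           cond_threshold: float = 1e10) -> BestSubsetResult:
    """Plain enumeration over all size-m subsets (reference implementation)."""
    est_data = np.asarray(est_data, dtype=float)
    objective = _subset_objective_factory(est_data, eval_data, ridge, cond_threshold)
    best, best_val, count = None, -np.inf, 0
    for subset in itertools.combinations(range(est_data.shape[1]), m):
        val = objective(subset)
        count += 1
        if val > best_val:
            best, best_val = subset, val
    assert best is not None
    return BestSubsetResult(FeatureSubset(tuple(str(i) for i in best), best),
                            best_val, count)


def best_subset_profile(est_data: np.ndarray, ms: list[int],
                        eval_data: np.ndarray | None = None,
                        names: tuple[str, ...] | None = None,
                        candidate_pool: int | None = 10) -> pd.DataFrame:
    """Objective-vs-m sweep; the objective is non-decreasing in m."""
    rows = []
    for m in ms:
        res = best_subset_cf(est_data, m, eval_data=eval_data, names=names,
                             candidate_pool=candidate_pool)
        rows.append({"m": m, "objective": res.objective,
                     "subset": ",".join(res.subset.names)})
    return pd.DataFrame(rows)


@dataclass
class CFResult:
    """Per-patient criteria-function values and their group/time summary."""

    per_patient: pd.DataFrame  # patient_id, group, timepoint, cf
    summary: pd.DataFrame  # group (0 = overall), timepoint, mean_cf, sd_cf, n
    subset: FeatureSubset

    def patient_means(self) -> pd.DataFrame:
        """One mean CF per patient across time points (keeps group label)."""
        return (self.per_patient.groupby(["patient_id", "group"], as_index=False)
                ["cf"].mean())


def cf_dynamics(dataset: CohortDataset, subset: FeatureSubset | None = None,
                ridge: float = 1e-6, cond_threshold: float = 1e10) -> CFResult:
    """Criteria-function dynamics per group and time point.

    Each group-by-time cell is standardized against itself and scored
    against its own correlation matrix, so CF measures within-cell
    consistency of each patient's parameter system.
    """
    if not dataset.is_complete():
        raise ValueError("dataset has missing values; impute before computing CF")
    if subset is None:
        idx = tuple(range(dataset.n_parameters))
        subset = FeatureSubset(tuple(dataset.parameters), idx)
    cols = list(subset.indices)
    records = []
    for g in dataset.group_labels:
        sel = dataset.groups == g
        pids = dataset.patient_ids[sel]
        for t in range(1, dataset.n_timepoints + 1):
            cell = dataset.cell(g, t)[:, cols]
            cf = CriteriaFunction(ridge, cond_threshold).fit(
                cell, names=subset.names).score_samples(cell)
            for pid, v in zip(pids, cf):
                records.append((pid, g, t, float(v)))
    per_patient = pd.DataFrame(records, columns=["patient_id", "group",
                                                 "timepoint", "cf"])
    group_rows = (per_patient.groupby(["group", "timepoint"])["cf"]
                  .agg(mean_cf="mean", sd_cf="std", n="size").reset_index())
    overall = (per_patient.groupby("timepoint")["cf"]
               .agg(mean_cf="mean", sd_cf="std", n="size").reset_index())
    overall.insert(0, "group", OVERALL)
    summary = pd.concat([group_rows, overall], ignore_index=True)
    return CFResult(per_patient=per_patient, summary=summary, subset=subset)
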