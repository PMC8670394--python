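"""K-nearest-neighbour imputation with Euclidean distance.

This is the algorithm the knowledge base selects for continuous data with
missing-not-at-random gaps.  Distances between records use the coordinates
both records observe, rescaled by ``sqrt(p / n_shared)`` so records with
different overlaps stay comparable; a missing entry is replaced by the
(optionally distance-weighted) mean of the k nearest donor records that
observe that column.  Ties in distance are broken by donor row index, so
the result is deterministic.

The estimator follows the scikit-learn transformer protocol; donors are
the rows seen at :meth:`fit` time.  Cohort-level imputation runs one
imputer per time point (donors never cross time points, so post-operative
dynamics cannot leak into the fill-in values).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .datasets import CohortDataset


@dataclass(frozen=True)
class ImputationSpec:
    """Neighbour count, aggregation and standardization choices."""

    k: int = 5
    weights: str = "uniform"  # or "distance"
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.weights not in ("uniform", "distance"):
            raise ValueError("weights must be 'uniform' or 'distance'")


class EuclideanKNNImputer(TransformerMixin, BaseEstimator):
    """Impute missing entries from the k nearest donor rows.

    Parameters
    ----------
    k : number of donor neighbours (default 5).
    weights : "uniform" for the plain neighbour mean, "distance" for
        inverse-distance weighting (an exact-match donor short-circuits to
        its value).
    standardize : standardize columns by the donor mean/SD before distance
        computation, so parameters on wildly different scales contribute
        comparably.  Imputed values are returned on the original scale.
    """

    def __init__(self, k: int = 5, weights: str = "uniform", standardize: bool = True):
        self.k = k
        self.weights = weights
        self.standardize = standardize

    # ------------------------------------------------------------------ fit
    def fit(self, X: np.ndarray, y=None) -> "EuclideanKNNImputer":
        ImputationSpec(self.k, self.weights, self.standardize)  # validate
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2D rows-by-parameters matrix")
        obs = ~np.isnan(X)
        if (~obs).all(axis=1).any():
            bad = int(np.nonzero((~obs).all(axis=1))[0][0])
            raise ValueError(f"donor row {bad} has no observed values")
        short = np.nonzero(obs.sum(axis=0) < self.k)[0]
        if short.size:
            raise ValueError(
                f"column {int(short[0])} has fewer than k={self.k} observed donor values")
        self.donors_ = X
        self.donor_mask_ = obs
        if self.standardize:
            self.mean_ = np.nanmean(X, axis=0)
            scale = np.nanstd(X, axis=0)
            scale[scale == 0] = 1.0
            self.scale_ = scale
        else:
            self.mean_ = np.zeros(X.shape[1])
            self.scale_ = np.ones(X.shape[1])
        return self

    # ------------------------------------------------------------ transform
    def transform(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "donors_"):
            raise RuntimeError("imputer is not fitted")
        X = np.asarray(X, dtype=float)
        out = X.copy()
        obs = ~np.isnan(X)
        if (~obs).all(axis=1).any():
            bad = int(np.nonzero((~obs).all(axis=1))[0][0])
            raise ValueError(f"row {bad} has no observed values")
        donors = (self.donors_ - self.mean_) / self.scale_
        donors = np.where(self.donor_mask_, donors, 0.0)
        p = X.shape[1]
        in_sample = X is self.donors_ or (
            X.shape == self.donors_.shape and np.array_equal(X, self.donors_,
                                                             equal_nan=True))
        for i in np.nonzero(~obs.all(axis=1))[0]:
            row = (X[i] - self.mean_) / self.scale_
            row_obs = obs[i]
            shared = self.donor_mask_ & row_obs  # (n_donors, p)
            n_shared = shared.sum(axis=1)
            diff = np.where(shared, donors - np.where(row_obs, row, 0.0), 0.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                dist = np.sqrt(p / n_shared * (diff ** 2).sum(axis=1))
            dist[n_shared == 0] = np.inf
            if in_sample:
                dist[i] = np.inf  # a record never donates to itself
            for j in np.nonzero(~row_obs)[0]:
                cand = self.donor_mask_[:, j] & np.isfinite(dist)
                if cand.sum() < self.k:
                    raise ValueError(
                        f"column {j} has fewer than k={self.k} usable donors")
                cand_idx = np.nonzero(cand)[0]
                order = cand_idx[np.argsort(dist[cand_idx], kind="stable")]
                nearest = order[: self.k]
                vals = self.donors_[nearest, j]
                if self.weights == "distance":
                    d = dist[nearest]
                    if np.any(d == 0):
                        fill = vals[d == 0].mean()
                    else:
                        w = 1.0 / d
                        fill = float(np.average(vals, weights=w))
                else:
                    fill = float(vals.mean())
                out[i, j] = fill
        return out

    def fit_transform(self, X: np.ndarray, y=None, **kwargs) -> np.ndarray:
        return self.fit(X).transform(X)


def knn_impute(matrix: np.ndarray, spec: ImputationSpec | None = None,
               k: int | None = None) -> np.ndarray:
    """Complete a rows-by-parameters matrix in place of its NaN entries."""
    spec = spec or ImputationSpec()
    if k is not None:
        spec = ImputationSpec(k=k, weights=spec.weights, standardize=spec.standardize)
    imp = EuclideanKNNImputer(k=spec.k, weights=spec.weights,
                              standardize=spec.standardize)
    return imp.fit_transform(np.asarray(matrix, dtype=float))


def mean_impute(matrix: np.ndarray) -> np.ndarray:
    """Column-mean baseline used for benchmarking against the KNN imputer."""
    X = np.asarray(matrix, dtype=float).copy()
    means = np.nanmean(X, axis=0)
    idx = np.nonzero(np.isnan(X))
    X[idx] = means[idx[1]]
    return X


def impute_cohort(dataset: CohortDataset, spec: ImputationSpec | None = None) -> CohortDataset:
    """Impute a cohort one time point at a time.

    Donor records are all patients at the same time point (across groups);
    observed entries are left untouched.
    """
    spec = spec or ImputationSpec()
    if dataset.is_complete():
        return dataset
    values = dataset.values.copy()
    for t in range(dataset.n_timepoints):
        values[:, :, t] = knn_impute(dataset.values[:, :, t], spec)
    return dataset.with_values(values)
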