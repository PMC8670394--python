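"""Kupershtokh-Mirkin-Trofimov partition functional over parameter links.

Parameters are partitioned into disjoint classes ("functional subsystems")
so as to locally maximize

    F(a, R) = sum over classes R_s, sum over pairs i < j in R_s of (a_ij - a)

where a_ij is the link indicator between parameters i and j (by default the
absolute Pearson correlation) and a is the link-importance threshold: pairs
with a_ij > a strengthen a class, weaker pairs penalize it.  The
all-singleton partition scores exactly zero, which anchors the scale.

Optimization is greedy agglomeration followed by steepest-ascent local
search (single-element relocations and class merges) restarted from random
partitions; the returned partition is certified 1-move optimal.  Scanning
the threshold grid yields the three indicators tracked over time — the
functional value, the selected threshold and the class count — whose
largest between-point change marks the critical period of the system.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

from .criteria import OVERALL, ConstantColumnError
from .datasets import CohortDataset


@dataclass(frozen=True)
class LinkMatrix:
    """Symmetric matrix of link indicators; the diagonal is ignored."""

    matrix: np.ndarray
    names: tuple[str, ...]
    method: str = "abs"

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def max_link(self) -> float:
        off = ~np.eye(self.n, dtype=bool)
        return float(self.matrix[off].max())


def link_matrix(data: np.ndarray, names: tuple[str, ...] | None = None,
                method: str = "abs") -> LinkMatrix:
    """Pairwise Pearson links between parameters (columns of ``data``).

    ``method='abs'`` (default) takes absolute correlations — a strong
    negative physiological coupling is still a coupling; ``'signed'`` keeps
    the sign.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need a 2D matrix with at least 3 rows")
    if np.isnan(X).any():
        raise ValueError("link matrix requires complete data; impute first")
    sd = X.std(axis=0)
    const = np.nonzero(sd == 0)[0]
    if const.size:
        label = names[const[0]] if names else int(const[0])
        raise ConstantColumnError(label)
    corr = np.corrcoef(X.T)
    corr = (corr + corr.T) / 2.0
    if method == "abs":
        corr = np.abs(corr)
    elif method != "signed":
        raise ValueError("method must be 'abs' or 'signed'")
    np.fill_diagonal(corr, 0.0)
    if names is None:
        names = tuple(str(i) for i in range(X.shape[1]))
    return LinkMatrix(matrix=corr, names=tuple(names), method=method)


def _as_labels(partition, n: int) -> np.ndarray:
    """Accept a label vector or an iterable of index classes; validate."""
    if isinstance(partition, np.ndarray) or (
            isinstance(partition, (list, tuple)) and partition
            and np.isscalar(partition[0])):
        labels = np.asarray(partition, dtype=int)
        if labels.shape != (n,):
            raise ValueError("label vector length does not match the matrix")
        return labels
    labels = np.full(n, -1, dtype=int)
    for s, cls in enumerate(partition):
        for i in cls:
            if labels[i] != -1:
                raise ValueError(f"element {i} appears in two classes")
            labels[i] = s
    if (labels == -1).any():
        raise ValueError("partition does not cover all elements")
    return labels


def canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel classes by first occurrence so equal partitions compare equal."""
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def functional_value(link: LinkMatrix | np.ndarray, partition, a: float) -> float:
    """F(a, R): sum of (a_ij - a) over unordered within-class pairs."""
    A = link.matrix if isinstance(link, LinkMatrix) else np.asarray(link, dtype=float)
    n = A.shape[0]
    labels = _as_labels(partition, n)
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(n, k=1)
    sel = same[iu]
    return float((A[iu][sel] - a).sum())


@dataclass
class PartitionResult:
    """A locally optimal partition with the three reported indicators."""

    labels: np.ndarray
    functional: float  # F
    threshold: float  # a
    names: tuple[str, ...]

    @property
    def n_classes(self) -> int:
        return int(len(np.unique(self.labels)))

    def classes(self) -> list[tuple[str, ...]]:
        labs = canonical_labels(self.labels)
        return [tuple(np.asarray(self.names)[labs == s])
                for s in range(labs.max() + 1)]

    def to_dict(self) -> dict:
        return {"threshold": self.threshold, "functional": self.functional,
                "n_classes": self.n_classes,
                "classes": [list(c) for c in self.classes()]}


def _class_sums(M: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """W[i, s] = sum of M[i, j] over j in class s (diagonal of M is zero)."""
    n_classes = labels.max() + 1
    ind = np.zeros((labels.size, n_classes))
    ind[np.arange(labels.size), labels] = 1.0
    return M @ ind


def _local_search(M: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Steepest-ascent relocations and class merges to a 1-move optimum."""
    n = labels.size
    labels = canonical_labels(labels)
    while True:
        labels = canonical_labels(labels)
        n_classes = labels.max() + 1
        W = _class_sums(M, labels)
        current = W[np.arange(n), labels]
        # relocation gains: move i to class s (or to a fresh singleton = 0)
        gains = W - current[:, None]
        gains[np.arange(n), labels] = 0.0
        singleton_gain = -current  # moving out into a new singleton class
        best_gain = 0.0
        best_move = None
        flat = np.argmax(gains)
        i, s = np.unravel_index(flat, gains.shape)
        if gains[i, s] > best_gain + 1e-12:
            best_gain, best_move = gains[i, s], ("move", int(i), int(s))
        j = int(np.argmax(singleton_gain))
        if singleton_gain[j] > best_gain + 1e-12:
            best_gain, best_move = singleton_gain[j], ("split", j, n_classes)
        # merge gains between classes
        ind = np.zeros((n, n_classes))
        ind[np.arange(n), labels] = 1.0
        between = ind.T @ M @ ind
        np.fill_diagonal(between, -np.inf)
        if n_classes > 1:
            ss, tt = np.unravel_index(np.argmax(between), between.shape)
            if between[ss, tt] > best_gain + 1e-12:
                best_gain = between[ss, tt]
                best_move = ("merge", int(min(ss, tt)), int(max(ss, tt)))
        if best_move is None:
            return labels
        kind, x, y = best_move
        if kind == "merge":
            labels = labels.copy()
            labels[labels == y] = x
        else:
            labels = labels.copy()
            labels[x] = y


def optimize_partition(link: LinkMatrix | np.ndarray, a: float,
                       restarts: int = 20, seed: int = 0,
                       names: tuple[str, ...] | None = None) -> PartitionResult:
    """Best 1-move-optimal partition over seeded restarts.

    Restart 0 is greedy agglomeration from singletons (merge the pair of
    classes with the largest positive gain until none remains); further
    restarts polish random partitions.  Ties between equally good optima
    resolve to the canonically smallest label vector.
    """
    if isinstance(link, LinkMatrix):
        A, names = link.matrix, link.names
    else:
        A = np.asarray(link, dtype=float)
        names = names or tuple(str(i) for i in range(A.shape[0]))
    n = A.shape[0]
    M = A - a
    np.fill_diagonal(M, 0.0)
    rng = np.random.default_rng(seed)

    best: np.ndarray | None = None
    best_f = -np.inf
    starts: list[np.ndarray] = [_greedy_agglomeration(M)]
    for _ in range(max(0, restarts - 1)):
        k = int(rng.integers(1, n + 1))
        starts.append(rng.integers(0, k, size=n))
    for start in starts:
        labels = _local_search(M, canonical_labels(np.asarray(start)))
        f = functional_value(A, labels, a)
        if f > best_f + 1e-12 or (abs(f - best_f) <= 1e-12 and best is not None
                                  and tuple(labels) < tuple(best)):
            best, best_f = labels, max(f, best_f)
    assert best is not None
    return PartitionResult(labels=best, functional=functional_value(A, best, a),
                           threshold=a, names=tuple(names))


def _greedy_agglomeration(M: np.ndarray) -> np.ndarray:
    n = M.shape[0]
    labels = np.arange(n)
    while True:
        labels = canonical_labels(labels)
        n_classes = labels.max() + 1
        if n_classes == 1:
            return labels
        ind = np.zeros((n, n_classes))
        ind[np.arange(n), labels] = 1.0
        between = ind.T @ M @ ind
        np.fill_diagonal(between, -np.inf)
        s, t = np.unravel_index(np.argmax(between), between.shape)
        if between[s, t] <= 1e-12:
            return labels
        labels = labels.copy()
        labels[labels == max(s, t)] = min(s, t)


def is_one_move_optimal(link: LinkMatrix | np.ndarray, labels: np.ndarray,
                        a: float, tol: float = 1e-9) -> bool:
    """Certificate: no relocation, split or class merge improves F."""
    A = link.matrix if isinstance(link, LinkMatrix) else np.asarray(link, dtype=float)
    M = A - a
    np.fill_diagonal(M, 0.0)
    labels = canonical_labels(np.asarray(labels))
    n = labels.size
    n_classes = labels.max() + 1
    W = _class_sums(M, labels)
    current = W[np.arange(n), labels]
    gains = W - current[:, None]
    gains[np.arange(n), labels] = -np.inf
    if gains.size and gains.max() > tol:
        return False
    if (-current).max() > tol:  # split into a fresh singleton
        return False
    ind = np.zeros((n, n_classes))
    ind[np.arange(n), labels] = 1.0
    between = ind.T @ M @ ind
    np.fill_diagonal(between, -np.inf)
    if n_classes > 1 and between.max() > tol:
        return False
    return True


def exhaustive_partition(link: LinkMatrix | np.ndarray, a: float) -> PartitionResult:
    """Global maximum of F by enumerating all set partitions (small n only)."""
    A = link.matrix if isinstance(link, LinkMatrix) else np.asarray(link, dtype=float)
    names = link.names if isinstance(link, LinkMatrix) else tuple(
        str(i) for i in range(A.shape[0]))
    n = A.shape[0]
    if n > 10:
        raise ValueError("exhaustive enumeration is limited to n <= 10")
    M = A - a
    np.fill_diagonal(M, 0.0)
    best, best_f = None, -np.inf
    labels = np.zeros(n, dtype=int)

    def rec(i: int, n_used: int, f: float) -> None:
        nonlocal best, best_f
        if i == n:
            if f > best_f:
                best, best_f = labels.copy(), f
            return
        for s in range(n_used + 1):
            gain = M[i, :i][labels[:i] == s].sum() if s < n_used else 0.0
            labels[i] = s
            rec(i + 1, max(n_used, s + 1), f + gain)

    rec(0, 0, 0.0)
    assert best is not None
    return PartitionResult(labels=best, functional=best_f, threshold=a,
                           names=tuple(names))


@dataclass
class ThresholdScan:
    """Optimized indicators along a grid of link-importance thresholds."""

    grid: np.ndarray
    results: list[PartitionResult]

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "a": self.grid,
            "F": [r.functional for r in self.results],
            "n_classes": [r.n_classes for r in self.results],
        })


def scan_threshold(link: LinkMatrix | np.ndarray, grid: np.ndarray,
                   restarts: int = 20, seed: int = 0) -> ThresholdScan:
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("threshold grid is empty")
    results = [optimize_partition(link, float(a), restarts=restarts, seed=seed)
               for a in grid]
    return ThresholdScan(grid=grid, results=results)


def select_threshold(scan: ThresholdScan) -> PartitionResult:
    """Stability (plateau) rule for the reported threshold.

    The selected a* is the midpoint of the widest consecutive grid run on
    which the optimized class count is constant and non-trivial (more than
    one class, fewer than n); trivial runs are used only as fallbacks.  The
    reported F and class count come from the grid point nearest a*.
    """
    counts = np.array([r.n_classes for r in scan.results])
    n = scan.results[0].labels.size
    runs: list[tuple[int, int]] = []
    start = 0
    for i in range(1, counts.size + 1):
        if i == counts.size or counts[i] != counts[start]:
            runs.append((start, i - 1))
            start = i
    def width(run):
        return scan.grid[run[1]] - scan.grid[run[0]]

    for predicate in (lambda s: 1 < s < n, lambda s: s > 1, lambda s: True):
        cand = [r for r in runs if predicate(counts[r[0]])]
        if cand:
            run = max(cand, key=width)
            mid = (scan.grid[run[0]] + scan.grid[run[1]]) / 2.0
            idx = run[0] + int(np.argmin(np.abs(scan.grid[run[0]: run[1] + 1] - mid)))
            chosen = scan.results[idx]
            return PartitionResult(labels=chosen.labels, functional=chosen.functional,
                                   threshold=float(mid), names=chosen.names)
    raise RuntimeError("unreachable: at least one run always exists")


DEFAULT_GRID = np.round(np.arange(0.0, 0.92, 0.02), 10)


class LinkPartitioner(ClusterMixin, BaseEstimator):
    """Scikit-learn style clusterer over *parameters* (feature clustering).

    ``fit(X)`` takes a samples-by-parameters matrix, builds the link matrix
    and partitions the parameters.  With an explicit ``threshold`` the
    partition is optimized at that threshold; with ``threshold=None`` the
    grid is scanned and the plateau rule selects it.

    Fitted attributes: ``labels_`` (class index per parameter),
    ``functional_``, ``threshold_``, ``n_classes_``, ``partition_``.
    """

    def __init__(self, threshold: float | None = None, method: str = "abs",
                 restarts: int = 20, seed: int = 0,
                 grid: np.ndarray | None = None):
        self.threshold = threshold
        self.method = method
        self.restarts = restarts
        self.seed = seed
        self.grid = grid

    def fit(self, X: np.ndarray, y=None,
            names: tuple[str, ...] | None = None) -> "LinkPartitioner":
        lm = link_matrix(np.asarray(X, dtype=float), names=names,
                         method=self.method)
        if self.threshold is not None:
            result = optimize_partition(lm, float(self.threshold),
                                        restarts=self.restarts, seed=self.seed)
        else:
            grid = DEFAULT_GRID if self.grid is None else np.asarray(self.grid)
            result = select_threshold(scan_threshold(lm, grid,
                                                     restarts=self.restarts,
                                                     seed=self.seed))
        self.partition_ = result
        self.labels_ = result.labels
        self.functional_ = result.functional
        self.threshold_ = result.threshold
        self.n_classes_ = result.n_classes
        return self


@dataclass
class FunctionalDynamics:
    """Indicators per group and time point, with critical periods.

    ``F`` and ``a`` are the functional value and threshold selected per
    cell; ``F_ref`` re-evaluates each cell at the group's common reference
    threshold ``a_ref`` (the grid point nearest the median selected
    threshold), which makes functional values comparable across time —
    critical periods are read off ``F_ref`` so that threshold movement does
    not confound the between-point change.
    """

    table: pd.DataFrame  # group (0 = overall), timepoint, F, a, n_classes, F_ref, a_ref
    partitions: dict[tuple[int, int], PartitionResult]

    def critical_period(self, group: int, indicator: str = "F_ref") -> tuple[int, int]:
        """Consecutive time-point pair with the largest absolute change."""
        sub = (self.table[self.table["group"] == group]
               .sort_values("timepoint")[indicator].to_numpy())
        deltas = np.abs(np.diff(sub))
        t = int(np.argmax(deltas)) + 1
        return (t, t + 1)

    def time_variance(self, group: int, indicator: str = "F_ref") -> float:
        sub = self.table[self.table["group"] == group].sort_values("timepoint")
        return float(np.var(sub[indicator].to_numpy(), ddof=1))


def functional_dynamics(dataset: CohortDataset, grid: np.ndarray | None = None,
                        restarts: int = 10, seed: int = 0,
                        method: str = "abs",
                        include_overall: bool = True) -> FunctionalDynamics:
    """Three indicators (F, a, class count) per group and time point.

    Each group-by-time cell yields a link matrix, a threshold scan and a
    plateau-selected partition; the critical period of a group is the
    consecutive time-point interval with the largest absolute change in the
    functional (or, separately, in the threshold).
    """
    if not dataset.is_complete():
        raise ValueError("dataset has missing values; impute before the functional")
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    rows = []
    partitions: dict[tuple[int, int], PartitionResult] = {}
    group_codes = dataset.group_labels + ([OVERALL] if include_overall else [])
    for g in group_codes:
        scans: list[ThresholdScan] = []
        selected: list[PartitionResult] = []
        for t in range(1, dataset.n_timepoints + 1):
            cell = (dataset.timepoint_matrix(t) if g == OVERALL
                    else dataset.cell(g, t))
            lm = link_matrix(cell, names=dataset.parameters, method=method)
            scan = scan_threshold(lm, grid, restarts=restarts, seed=seed)
            sel = select_threshold(scan)
            partitions[(g, t)] = sel
            scans.append(scan)
            selected.append(sel)
        a_ref = float(np.median([s.threshold for s in selected]))
        ref_idx = int(np.argmin(np.abs(grid - a_ref)))
        for t, (scan, sel) in enumerate(zip(scans, selected), start=1):
            ref = scan.results[ref_idx]
            rows.append({"group": g, "timepoint": t, "F": sel.functional,
                         "a": sel.threshold, "n_classes": sel.n_classes,
                         "F_ref": ref.functional, "a_ref": float(grid[ref_idx])})
    return FunctionalDynamics(table=pd.DataFrame(rows), partitions=partitions)
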