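"""Synthetic acid-base-state cohorts with planted statistical structure.

The generator emulates the structure the downstream consistency analysis
assumes: three patient groups measured at six post-operative time points on
21 blood-gas/electrolyte parameters, where

* parameters form correlated functional blocks (equicorrelated within a
  block, weakly correlated across blocks) — the ground truth the partition
  functional is expected to recover;
* the within-block correlation level follows a per-group time schedule
  whose largest jump sits between time points 5 and 6 for groups 1 and 2,
  with group 2 given larger perturbations than group 1 and group 3 held
  nearly constant — the planted "critical period";
* each patient carries a lognormal instability scale (how far the patient
  departs from the group profile), larger on average in group 2, which is
  what makes per-patient criteria-function values differ between groups;
* a patient-level random effect induces moderate correlation of the same
  parameter across time points, which is what gives the missingness screen
  leverage; and
* missingness is missing-not-at-random: the probability that an entry is
  missing grows with the magnitude of its own standardized value.

Group and time mean shifts are generated as well (largest between points 5
and 6 for groups 1 and 2); they matter for data realism, not for the
criteria function, which standardizes within each group-by-time cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .knowledge import abs_parameter_names

DEFAULT_BLOCK_SIZES = (6, 6, 5, 4)

# within-block correlation per group and time point; the 5->6 drop is the
# planted critical period for groups 1 and 2, group 2 additionally wobbles
# between points and group 3 is held constant
DEFAULT_WITHIN_SCHEDULE = (
    (0.70, 0.70, 0.70, 0.70, 0.70, 0.48),
    (0.70, 0.59, 0.73, 0.60, 0.72, 0.30),
    (0.70, 0.70, 0.70, 0.70, 0.70, 0.70),
)

# additive mean shift (in SD units) per group and time point
DEFAULT_MEAN_SHIFTS = (
    (0.0, 0.10, 0.15, 0.10, 0.15, 0.70),
    (0.0, 0.20, 0.35, 0.20, 0.30, 0.90),
    (0.0, 0.05, 0.05, 0.05, 0.05, 0.10),
)


@dataclass(frozen=True)
class CohortConfig:
    """Generation parameters for a synthetic cohort.

    Defaults reproduce the study conditions: 391 patients in three groups,
    six time points, the 21 acid-base-state parameters in four planted
    blocks.
    """

    n_patients_per_group: tuple[int, ...] = (131, 130, 130)
    n_timepoints: int = 6
    parameters: tuple[str, ...] = field(default_factory=lambda: tuple(abs_parameter_names()))
    block_sizes: tuple[int, ...] = DEFAULT_BLOCK_SIZES
    rho_within: float = 0.70
    rho_between: float = 0.10
    within_schedule: tuple[tuple[float, ...], ...] | None = DEFAULT_WITHIN_SCHEDULE
    mean_shifts: tuple[tuple[float, ...], ...] | None = DEFAULT_MEAN_SHIFTS
    patient_effect_weight: float = 0.15
    instability_sigma: tuple[float, ...] = (0.10, 1.00, 0.10)
    missing_rate: float = 0.08
    mnar_coefficient: float = 1.5
    heavy_tailed: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho_between < self.rho_within <= 1.0):
            raise ValueError("need 0 <= rho_between < rho_within <= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if sum(self.block_sizes) != len(self.parameters):
            raise ValueError("block sizes must partition the parameter list")
        if len(self.n_patients_per_group) != len(self.instability_sigma):
            raise ValueError("one instability sigma per group is required")
        if not 0.0 <= self.patient_effect_weight < 1.0:
            raise ValueError("patient_effect_weight must be in [0, 1)")

    @property
    def n_groups(self) -> int:
        return len(self.n_patients_per_group)

    @property
    def n_patients(self) -> int:
        return int(sum(self.n_patients_per_group))

    def group_schedule(self, kind: str, group_index: int) -> np.ndarray:
        """Per-time-point schedule row, padded with the baseline if needed."""
        table = self.within_schedule if kind == "within" else self.mean_shifts
        base = self.rho_within if kind == "within" else 0.0
        if table is None or group_index >= len(table):
            return np.full(self.n_timepoints, base)
        row = np.asarray(table[group_index], dtype=float)
        if row.size >= self.n_timepoints:
            return row[: self.n_timepoints]
        return np.concatenate([row, np.full(self.n_timepoints - row.size, base)])

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "CohortConfig":
        def tt(x):
            return tuple(tuple(r) for r in x) if x is not None else None

        data = dict(data)
        for key in ("within_schedule", "mean_shifts"):
            if key in data:
                data[key] = tt(data[key])
        for key in ("n_patients_per_group", "parameters", "block_sizes", "instability_sigma"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of a generated cohort: the planted partition and schedules."""

    labels: tuple[int, ...]  # block index per parameter
    blocks: tuple[tuple[str, ...], ...]
    within_schedule: tuple[tuple[float, ...], ...]
    mean_shifts: tuple[tuple[float, ...], ...]


def planted_truth(config: CohortConfig) -> PlantedTruth:
    """Planted partition and shift schedules; independent of the seed."""
    labels: list[int] = []
    blocks: list[tuple[str, ...]] = []
    start = 0
    for b, size in enumerate(config.block_sizes):
        labels.extend([b] * size)
        blocks.append(tuple(config.parameters[start: start + size]))
        start += size
    within = tuple(tuple(config.group_schedule("within", g)) for g in range(config.n_groups))
    shifts = tuple(tuple(config.group_schedule("shift", g)) for g in range(config.n_groups))
    return PlantedTruth(tuple(labels), tuple(blocks), within, shifts)


def block_correlation(labels: np.ndarray, rho_within: float, rho_between: float) -> np.ndarray:
    """Planted block correlation matrix; raises if not positive definite."""
    same = labels[:, None] == labels[None, :]
    sigma = np.where(same, rho_within, rho_between)
    np.fill_diagonal(sigma, 1.0)
    # cheap PD check via Cholesky
    try:
        np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:
        raise ValueError("implied correlation matrix is not positive definite") from exc
    return sigma


@dataclass
class CohortDataset:
    """Patients x parameters x time points with group labels and missing mask.

    ``values`` holds NaN where ``mask`` is True (missing).  For generated
    cohorts ``complete_values`` retains the pre-masking truth so imputation
    error can be scored; it is absent for data loaded from file.
    """

    values: np.ndarray  # (n_patients, n_parameters, n_timepoints)
    mask: np.ndarray  # bool, True = missing
    groups: np.ndarray  # int group label per patient, 1-based
    parameters: tuple[str, ...]
    patient_ids: np.ndarray | None = None
    complete_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.patient_ids is None:
            self.patient_ids = np.arange(1, self.values.shape[0] + 1)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if self.values.shape[1] != len(self.parameters):
            raise ValueError("parameter axis does not match parameter names")

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    @property
    def n_parameters(self) -> int:
        return self.values.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[2]

    @property
    def group_labels(self) -> list[int]:
        return sorted(np.unique(self.groups).tolist())

    @property
    def missing_fraction(self) -> float:
        return float(self.mask.mean())

    def missing_fraction_per_parameter(self) -> dict[str, float]:
        frac = self.mask.mean(axis=(0, 2))
        return {p: float(f) for p, f in zip(self.parameters, frac)}

    def is_complete(self) -> bool:
        return not bool(self.mask.any())

    def cell(self, group: int, timepoint: int) -> np.ndarray:
        """Values of one group at one time point (patients x parameters)."""
        idx = self.groups == group
        return self.values[idx, :, timepoint - 1]

    def timepoint_matrix(self, timepoint: int) -> np.ndarray:
        return self.values[:, :, timepoint - 1]

    def pooled_matrix(self) -> np.ndarray:
        """All patient-by-time records stacked (n_patients*T, n_parameters)."""
        return np.concatenate([self.values[:, :, t] for t in range(self.n_timepoints)])

    def with_values(self, values: np.ndarray) -> "CohortDataset":
        return CohortDataset(values=values, mask=np.zeros_like(self.mask),
                             groups=self.groups, parameters=self.parameters,
                             patient_ids=self.patient_ids,
                             complete_values=self.complete_values)

    # -------------------------------------------------------------- long form
    def to_long(self) -> pd.DataFrame:
        n, p, t = self.values.shape
        pid = np.repeat(self.patient_ids, p * t)
        grp = np.repeat(self.groups, p * t)
        par = np.tile(np.repeat(np.arange(p), t), n)
        tp = np.tile(np.arange(1, t + 1), n * p)
        val = self.values.reshape(-1)
        return pd.DataFrame({
            "patient_id": pid,
            "group": grp,
            "timepoint": tp,
            "parameter": np.asarray(self.parameters)[par],
            "value": val,
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_long().to_csv(path, index=False)

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "CohortDataset":
        params = tuple(pd.unique(df["parameter"]))
        pids = pd.unique(df["patient_id"])
        tps = sorted(pd.unique(df["timepoint"]))
        pivot = df.pivot_table(index="patient_id", columns=["parameter", "timepoint"],
                               values="value", dropna=False)
        pivot = pivot.reindex(index=pids)
        values = np.full((len(pids), len(params), len(tps)), np.nan)
        for j, par in enumerate(params):
            for k, tp in enumerate(tps):
                values[:, j, k] = pivot[(par, tp)].to_numpy()
        groups = df.drop_duplicates("patient_id").set_index("patient_id").loc[pids, "group"]
        return cls(values=values, mask=np.isnan(values),
                   groups=groups.to_numpy().astype(int), parameters=params,
                   patient_ids=np.asarray(pids))

    @classmethod
    def read_csv(cls, path: str | Path) -> "CohortDataset":
        return cls.from_long(pd.read_csv(path))


def generate(config: CohortConfig | None = None) -> CohortDataset:
    """Draw a cohort from the planted block-correlation model.

    Per group g and time point t the parameter vector of patient p is

        x = mu[g, t] + tau_p * (sqrt(phi) * L0 u_p + sqrt(1 - phi) * L[g, t] e)

    with L0, L[g,t] Cholesky factors of the baseline and scheduled block
    correlation matrices, u_p a patient random effect shared across time,
    e fresh noise, and tau_p the patient's lognormal instability scale.
    Missing entries are then drawn with probability increasing in the
    magnitude of the standardized value (missing-not-at-random).
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    truth = planted_truth(config)
    labels = np.asarray(truth.labels)
    n, p, t = config.n_patients, len(config.parameters), config.n_timepoints
    phi = config.patient_effect_weight

    chol_base = np.linalg.cholesky(
        block_correlation(labels, config.rho_within, config.rho_between))

    def draw(shape):
        if config.heavy_tailed:
            df = 5.0
            return rng.standard_t(df, size=shape) / np.sqrt(df / (df - 2.0))
        return rng.standard_normal(shape)

    groups = np.repeat(np.arange(1, config.n_groups + 1),
                       config.n_patients_per_group)
    values = np.empty((n, p, t))
    start = 0
    for g in range(config.n_groups):
        size = config.n_patients_per_group[g]
        rows = slice(start, start + size)
        start += size
        tau = np.exp(config.instability_sigma[g] * rng.standard_normal(size))
        u = draw((size, p)) @ chol_base.T  # patient random effect
        within = config.group_schedule("within", g)
        shifts = config.group_schedule("shift", g)
        for k in range(t):
            chol_t = np.linalg.cholesky(
                block_correlation(labels, float(within[k]), config.rho_between))
            eps = draw((size, p)) @ chol_t.T
            x = np.sqrt(phi) * u + np.sqrt(1.0 - phi) * eps
            values[rows, :, k] = shifts[k] + tau[:, None] * x

    mask = np.zeros((n, p, t), dtype=bool)
    if config.missing_rate > 0:
        # standardize within group x time cells so the missingness driver is
        # the patient's deviation magnitude, then calibrate the intercept so
        # the realized marginal rate matches the configured one
        z = np.empty_like(values)
        for g in range(1, config.n_groups + 1):
            rows = groups == g
            for k in range(t):
                cell = values[rows, :, k]
                z[rows, :, k] = (cell - cell.mean(axis=0)) / cell.std(axis=0)
        absz = np.abs(z).reshape(-1)
        beta = config.mnar_coefficient

        def rate(alpha: float) -> float:
            return float(expit(alpha + beta * absz).mean()) - config.missing_rate

        alpha = brentq(rate, -40.0, 40.0)
        prob = expit(alpha + beta * np.abs(z))
        mask = rng.random(size=prob.shape) < prob
        # keep at least one observed entry per patient x time record
        empty_rows = mask.all(axis=1)
        for pi, ti in zip(*np.nonzero(empty_rows)):
            keep = int(np.argmin(np.abs(z[pi, :, ti])))
            mask[pi, keep, ti] = False

    observed = values.copy()
    observed[mask] = np.nan
    return CohortDataset(values=observed, mask=mask, groups=groups,
                         parameters=tuple(config.parameters),
                         complete_values=values)
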