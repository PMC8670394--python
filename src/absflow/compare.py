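"""Mann-Whitney comparisons of criteria-function values.

The U statistic counts pairs (x_i, y_j) with x_i > y_j plus half the ties,
so U_x + U_y = n1 * n2 always.  For small samples (n1 + n2 <= 20) the
p-value is exact, from full enumeration of the permutation distribution of
U conditional on the pooled values (ties included); larger samples use the
normal approximation with tie correction.

The comparison suite mirrors the conclusions-style report: pairwise group
contrasts on per-patient criteria-function levels, and time point 1 against
each later point within every group and overall.  No multiplicity
correction is applied by default (Holm is available behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

from .criteria import OVERALL, CFResult

EXACT_LIMIT = 20  # exact permutation distribution up to this pooled size


@dataclass(frozen=True)
class ComparisonResult:
    label: str
    u: float
    p: float
    n1: int
    n2: int
    method: str  # "exact" | "asymptotic"

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p < alpha


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n1 = x.size
    return float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)


@lru_cache(maxsize=32)
def _combination_masks(n: int, n1: int) -> np.ndarray:
    """All (n choose n1) boolean masks selecting the first sample."""
    masks = np.zeros((0, n), dtype=bool)
    rows = []
    for comb in combinations(range(n), n1):
        row = np.zeros(n, dtype=bool)
        row[list(comb)] = True
        rows.append(row)
    return np.array(rows) if rows else masks


def _exact_p(x: np.ndarray, y: np.ndarray, u: float, alternative: str) -> float:
    pooled = np.concatenate([x, y])
    n1 = x.size
    ranks = rankdata(pooled)
    masks = _combination_masks(pooled.size, n1)
    # U for every relabelling, in one matrix product over the rank vector
    u_all = masks @ ranks - n1 * (n1 + 1) / 2.0
    mu = n1 * y.size / 2.0
    eps = 1e-9
    if alternative == "two-sided":
        hits = np.abs(u_all - mu) >= np.abs(u - mu) - eps
    elif alternative == "greater":
        hits = u_all >= u - eps
    elif alternative == "less":
        hits = u_all <= u + eps
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(hits.mean())


def mann_whitney(x, y, alternative: str = "two-sided",
                 label: str = "") -> ComparisonResult:
    """Mann-Whitney U test; exact for small samples, else tie-corrected normal."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    u = _u_statistic(x, y)
    if x.size + y.size <= EXACT_LIMIT:
        p = _exact_p(x, y, u, alternative)
        method = "exact"
    else:
        res = mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
        p, method = float(res.pvalue), "asymptotic"
    return ComparisonResult(label=label, u=u, p=min(p, 1.0),
                            n1=int(x.size), n2=int(y.size), method=method)


def holm_adjust(pvalues: list[float]) -> list[float]:
    order = np.argsort(pvalues)
    m = len(pvalues)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvalues[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()


def comparison_suite(cf: CFResult, alpha: float = 0.05,
                     holm: bool = False) -> pd.DataFrame:
    """All conclusion-style contrasts on per-patient criteria-function values.

    Group contrasts use each patient's mean CF across time points; the
    within-group (and overall) time contrasts compare per-patient CF at
    point 1 against each later point.
    """
    rows: list[dict] = []
    means = cf.patient_means()
    groups = sorted(g for g in means["group"].unique())
    for g1, g2 in combinations(groups, 2):
        res = mann_whitney(means.loc[means["group"] == g1, "cf"],
                           means.loc[means["group"] == g2, "cf"],
                           label=f"group {g1} vs group {g2}")
        rows.append({"comparison": "group", "scope": res.label,
                     "u": res.u, "p": res.p, "method": res.method})
    per = cf.per_patient
    timepoints = sorted(per["timepoint"].unique())
    scopes = [(OVERALL, per)] + [(g, per[per["group"] == g]) for g in groups]
    for g, sub in scopes:
        base = sub.loc[sub["timepoint"] == timepoints[0], "cf"]
        for t in timepoints[1:]:
            res = mann_whitney(base, sub.loc[sub["timepoint"] == t, "cf"],
                               label=f"point 1 vs point {t}")
            scope = "overall" if g == OVERALL else f"group {g}"
            rows.append({"comparison": "timepoint", "scope": f"{scope}: {res.label}",
                         "u": res.u, "p": res.p, "method": res.method})
    report = pd.DataFrame(rows)
    pcol = holm_adjust(report["p"].tolist()) if holm else report["p"]
    report["significant"] = np.asarray(pcol) < alpha
    return report


def format_report(report: pd.DataFrame, alpha: float = 0.05) -> str:
    """Human-readable conclusion bullets for a comparison report."""
    lines = [f"Mann-Whitney comparisons (alpha = {alpha}):"]
    for _, row in report.iterrows():
        verdict = "differ significantly" if row["significant"] else "do not differ significantly"
        lines.append(f"  - {row['scope']}: U = {row['u']:.1f}, p = {row['p']:.3g} "
                     f"({row['method']}) -> {verdict}")
    return "\n".join(lines)
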