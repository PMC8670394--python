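"""Workflow construction by stepwise knowledge-base querying.

Given a task requirement (an entity of the merged ontology) and a data
profile (the characteristics estimated from the cohort), the builder runs
the four-step query procedure — stages, available processes, suitable
processes per stage, suitable algorithm per process — followed by the
query-execute-estimate cycle: once a preprocessing algorithm is selected
its process's outputs replace its inputs in the profile state, and
readiness for the next stage is re-checked.

Algorithm suitability is realized strictly through the ``suitableFor``
relation: a candidate's score is the number of profile characteristics
(plus the task itself) it is declared suitable for, and all co-optimal
candidates are reported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np

from .datasets import CohortDataset
from .kb import (
    Atom,
    Closure,
    CycleError,
    KBError,
    KnowledgeBase,
    UnresolvableNameError,
    answer_query,
    classify,
    data_property_value,
    property_fillers,
)
from .kb.query import class_satisfies

STAGE_ROOT = "DataMiningStage"
EXCLUDED_STAGES = ("Deployment",)  # the pipeline stops at Evaluation
MISSINGNESS_MECHANISMS = ("Missing_not_Random", "Missing_at_Random",
                          "Missing_Completely_at_Random")
LONG_TS_CLASS = "LongTSDataset"
LONG_TS_PROPERTY = "hasMinLength"
SMALL_SIZE_THRESHOLD = 30


class WorkflowError(KBError):
    pass


class NoCandidateError(WorkflowError):
    def __init__(self, process: str):
        self.process = process
        super().__init__(f"no candidate algorithm for required process {process!r}")


@dataclass
class DataProfile:
    """Named data characteristics plus dataset metadata."""

    characteristics: set[str]
    metadata: dict = field(default_factory=dict)

    def validate(self, kb: KnowledgeBase) -> None:
        for name in self.characteristics:
            if name not in kb:
                raise UnresolvableNameError(name)

    def normalized(self) -> set[str]:
        """Characteristics with the missing/complete dichotomy made explicit."""
        state = set(self.characteristics)
        if state & set(MISSINGNESS_MECHANISMS) or "DataWithMissingValue" in state:
            state.add("DataWithMissingValue")
            state.discard("DataWithoutMissingValue")
        else:
            state.add("DataWithoutMissingValue")
        return state


@dataclass(frozen=True)
class AlgorithmSelectionProblem:
    """The algorithm-selection quadruple (problem, features, space, mapping).

    The selection mapping S(f(x)) is realized as knowledge-base queries:
    the feature set is the data profile, the algorithm space is the set of
    algorithm classes attached to the process, and selection maximizes the
    count of satisfied ``suitableFor`` links.
    """

    task: str
    process: str
    features: frozenset[str]
    algorithm_space: tuple[str, ...]


def mnar_screen(dataset: CohortDataset, alpha: float = 0.05) -> tuple[bool, float]:
    """Logistic screen for missing-not-at-random gaps.

    For every patient/parameter/time entry the missingness indicator is
    regressed on the mean absolute standardized value of the *same*
    parameter at the adjacent observed time points (a proxy for the entry's
    own magnitude, informative because patients have stable baselines).
    A significantly positive slope flags the mechanism as MNAR.

    Returns (is_mnar, p_value).
    """
    import statsmodels.api as sm

    values, mask = dataset.values, dataset.mask
    n, p, t = values.shape
    # standardize per group x parameter x time using observed entries
    z = np.full_like(values, np.nan)
    for g in dataset.group_labels:
        rows = dataset.groups == g
        cell = values[rows]
        mu = np.nanmean(cell, axis=0, keepdims=True)
        sd = np.nanstd(cell, axis=0, keepdims=True)
        sd[sd == 0] = 1.0
        z[rows] = (cell - mu) / sd
    absz = np.abs(z)
    neighbor = np.full((n, p, t), np.nan)
    for k in range(t):
        adj = [j for j in (k - 1, k + 1) if 0 <= j < t]
        stack = np.stack([absz[:, :, j] for j in adj], axis=-1)
        counts = np.isfinite(stack).sum(axis=-1)
        sums = np.nansum(np.nan_to_num(stack, nan=0.0), axis=-1)
        neighbor[:, :, k] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    y = mask.reshape(-1).astype(float)
    x = neighbor.reshape(-1)
    keep = np.isfinite(x)
    y, x = y[keep], x[keep]
    if y.sum() == 0 or y.sum() == y.size:
        return False, 1.0
    design = sm.add_constant(x)
    try:
        fit = sm.Logit(y, design).fit(disp=0)
        coef, pval = float(fit.params[1]), float(fit.pvalues[1])
    except Exception:  # fall back to a rank test on the same association
        from scipy.stats import mannwhitneyu

        res = mannwhitneyu(x[y == 1], x[y == 0], alternative="greater")
        coef, pval = 1.0, float(res.pvalue)
    return bool(coef > 0 and pval < alpha), pval


def long_ts_threshold(kb: KnowledgeBase) -> int:
    literal = data_property_value(kb, LONG_TS_CLASS, LONG_TS_PROPERTY)
    return int(literal.as_python()) if literal is not None else 700


def profile_data(dataset: CohortDataset, kb: KnowledgeBase,
                 alpha: float = 0.05) -> DataProfile:
    """Estimate the data characteristics used for algorithm selection."""
    if dataset.n_patients == 0 or dataset.n_parameters == 0:
        raise ValueError("empty dataset")
    chars: set[str] = set()
    observed = dataset.values[~dataset.mask]
    if np.allclose(observed, np.round(observed)):
        chars.add("Discrete")
    else:
        chars.add("Continuous")
    if dataset.mask.any():
        chars.add("DataWithMissingValue")
        is_mnar, pval = mnar_screen(dataset, alpha=alpha)
        chars.add("Missing_not_Random" if is_mnar else "Missing_at_Random")
        mnar_p = pval
    else:
        chars.add("DataWithoutMissingValue")
        mnar_p = None
    if dataset.n_timepoints > long_ts_threshold(kb):
        chars.add(LONG_TS_CLASS)
    if dataset.n_patients < SMALL_SIZE_THRESHOLD:
        chars.add("SmallSizeDataset")
    chars &= set(kb.entities)  # only KB-resolvable characteristics are kept
    metadata = {
        "has_Samples": int(dataset.n_patients),
        "has_Labels": int(len(dataset.group_labels)),
        "n_timepoints": int(dataset.n_timepoints),
        "missing_fraction": float(dataset.missing_fraction),
        "missing_fraction_per_parameter": dataset.missing_fraction_per_parameter(),
        "mnar_p_value": mnar_p,
    }
    return DataProfile(characteristics=chars, metadata=metadata)


@dataclass
class WorkflowStep:
    process: str
    algorithms: list[str] = field(default_factory=list)
    parameters: dict = field(default_factory=dict)
    matched: dict = field(default_factory=dict)  # algorithm -> satisfied requirements


@dataclass
class WorkflowStage:
    name: str
    steps: list[WorkflowStep] = field(default_factory=list)


@dataclass
class Workflow:
    task: str
    objective: str | None
    stages: list[WorkflowStage]
    profile: set[str]

    def selections(self) -> list[str]:
        out: list[str] = []
        for stage in self.stages:
            for step in stage.steps:
                out.extend(step.algorithms)
        return out

    def processes(self) -> list[str]:
        return [step.process for stage in self.stages for step in stage.steps]

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "objective": self.objective,
            "profile": sorted(self.profile),
            "stages": [
                {"name": s.name,
                 "steps": [asdict(step) for step in s.steps]}
                for s in self.stages
            ],
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)


def _precedence_graph(processes: list[str], kb: KnowledgeBase,
                      closure: Closure) -> nx.DiGraph:
    graph = nx.DiGraph()
    graph.add_nodes_from(processes)
    fillers = {p: (set(property_fillers(kb, p, "hasInput", closure)),
                   set(property_fillers(kb, p, "hasOutput", closure)))
               for p in processes}
    for p in processes:
        for q in property_fillers(kb, p, "hasPostprocess", closure):
            if q in graph and q != p:
                graph.add_edge(p, q)
    for p in processes:
        for q in processes:
            if p != q and fillers[p][1] & fillers[q][0]:
                graph.add_edge(p, q)  # p's output feeds q's input
    return graph


def order_processes(processes, kb: KnowledgeBase,
                    closure: Closure | None = None) -> list[str]:
    """Total order extending the precedence partial order (lexicographic ties)."""
    if closure is None:
        closure = classify(kb)
    processes = sorted(processes)
    graph = _precedence_graph(processes, kb, closure)
    try:
        return list(nx.lexicographical_topological_sort(graph))
    except nx.NetworkXUnfeasible:
        cycle = [u for u, _ in nx.find_cycle(graph)]
        raise CycleError(cycle, "process precedence") from None


def _algorithms_employed_by(kb: KnowledgeBase, closure: Closure,
                            process: str) -> list[str]:
    """Algorithm classes declared ``employedBy`` exactly this process."""
    out = set()
    algorithms = {c for c in kb.concepts if closure.subsumed_by(c, "Algorithm")}
    for subj, prop, filler in kb.restrictions():
        if filler == process and closure.property_subsumed_by(prop, "employedBy"):
            out |= {x for x in closure.subclasses_of(subj) if x in algorithms}
    return sorted(out)


def _satisfied(kb: KnowledgeBase, closure: Closure, state: set[str],
               requirement: str) -> bool:
    return requirement in state or any(
        closure.subsumed_by(s, requirement) for s in state if s in kb)


def select_algorithms(kb: KnowledgeBase, closure: Closure, process: str,
                      requirements: set[str]) -> tuple[list[str], dict]:
    """All co-optimal candidates for a process under the suitability score."""
    candidates = _algorithms_employed_by(kb, closure, process)
    if not candidates:
        return [], {}
    matched = {
        cand: sorted(r for r in requirements
                     if class_satisfies(kb, closure, cand,
                                        Atom("some", r, prop="suitableFor")))
        for cand in candidates
    }
    best = max(len(v) for v in matched.values())
    chosen = sorted(c for c, v in matched.items() if len(v) == best)
    return chosen, {c: matched[c] for c in chosen}


def _algorithm_parameters(kb: KnowledgeBase, closure: Closure, alg: str) -> dict:
    params = {}
    for key, prop in (("employs", "employs"), ("measure", "hasMeasure"),
                      ("parameters", "hasParameter")):
        vals = property_fillers(kb, alg, prop, closure)
        if vals:
            params[key] = vals
    return params


def build_workflow(kb: KnowledgeBase, task: str, profile: DataProfile,
                   closure: Closure | None = None) -> Workflow:
    """The four query steps plus the query-execute-estimate cycle."""
    if task not in kb:
        raise UnresolvableNameError(task)
    profile.validate(kb)
    if closure is None:
        closure = classify(kb)

    # step 1: the general stages, ordered by their post-process chain
    stages = [s for s in answer_query(kb, STAGE_ROOT, closure)
              if s != STAGE_ROOT and s not in EXCLUDED_STAGES
              and kb.entity(s).kind == "class"]
    stages = order_processes(stages, kb, closure)

    state = profile.normalized()
    objective_lit = data_property_value(kb, task, "hasObjective")
    objective = objective_lit.value if objective_lit is not None else None

    built: list[WorkflowStage] = []
    for stage in stages:
        # step 2: available processes of the stage (fillers and their
        # specializations)
        available: set[str] = set()
        for filler in property_fillers(kb, stage, "hasSubprocess", closure):
            available |= {c for c in closure.subclasses_of(filler)
                          if kb.entity(c).kind == "class"}
        # step 3: suitable processes — every declared input characteristic
        # must be satisfied by the current profile state
        suitable = set()
        for proc in available:
            inputs = property_fillers(kb, proc, "hasInput", closure)
            if all(_satisfied(kb, closure, state, c) for c in inputs):
                suitable.add(proc)
        # prefer the most specific applicable process
        suitable = {p for p in suitable
                    if not any(q != p and closure.subsumed_by(q, p) for q in suitable)}
        ordered = order_processes(suitable, kb, closure)

        steps: list[WorkflowStep] = []
        for proc in ordered:
            inputs = property_fillers(kb, proc, "hasInput", closure)
            requirements = set(state) | {task}
            algorithms, matched = select_algorithms(kb, closure, proc, requirements)
            if inputs and not algorithms:
                raise NoCandidateError(proc)
            params = {alg: _algorithm_parameters(kb, closure, alg)
                      for alg in algorithms}
            steps.append(WorkflowStep(process=proc, algorithms=algorithms,
                                      parameters=params, matched=matched))
            # execute-estimate: outputs replace consumed inputs in the state
            if inputs and algorithms:
                outputs = property_fillers(kb, proc, "hasOutput", closure)
                for c in list(state):
                    if any(closure.subsumed_by(c, i) for i in inputs):
                        state.discard(c)
                if "DataWithMissingValue" in inputs:
                    state.difference_update(MISSINGNESS_MECHANISMS)
                state.update(o for o in outputs
                             if closure.subsumed_by(o, "DataCharacteristic"))
        built.append(WorkflowStage(name=stage, steps=steps))

    return Workflow(task=task, objective=objective, stages=built,
                    profile=set(profile.characteristics))
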