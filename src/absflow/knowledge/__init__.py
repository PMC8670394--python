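"""Packaged knowledge-base content and its competency-question suite.

Ships three text fixtures: the DM Core knowledge base (general data-mining
knowledge organized around the CRISP-DM stages), the medical domain
knowledge base (medical analysis tasks, in particular consistency analysis
of acid-base-state dynamics, and the domain-specific descriptive
algorithms), and the dictionary of the 21 acid-base-state parameters.

The nine competency questions exercise the knowledge base the way its
users do: DL-style conjunctive queries for suitability/employment, filler
lookups for definitional questions, and a data-property lookup for the
numeric long-time-series threshold.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

from ..kb import (
    Closure,
    KnowledgeBase,
    answer_query,
    classify,
    data_property_value,
    loads_kb,
    merge,
    property_fillers,
)

MERGED_NAMESPACE = "medical_dm"
CONSISTENCY_TASK = "ConsistencyAnalysis"


def _read_text(filename: str) -> str:
    return (resources.files(__package__) / "data" / filename).read_text(encoding="utf-8")


def load_dm_core() -> KnowledgeBase:
    """The packaged DM Core knowledge base."""
    return loads_kb(_read_text("dm_core.kb"), namespace="dm_core")


def load_medical_domain() -> KnowledgeBase:
    """The packaged medical domain knowledge base."""
    return loads_kb(_read_text("medical_domain.kb"), namespace="medical_domain")


def load_merged() -> KnowledgeBase:
    """DM Core merged with the medical domain content."""
    return merge(load_dm_core(), load_medical_domain(), MERGED_NAMESPACE)


@dataclass(frozen=True)
class ParameterRecord:
    """One acid-base-state parameter: short name plus clinical description."""

    name: str
    description: str


def abs_parameter_table() -> list[ParameterRecord]:
    """The 21 acid-base-state parameters, order preserved."""
    reader = csv.DictReader(_read_text("abs_parameters.csv").splitlines())
    return [ParameterRecord(row["name"], row["description"]) for row in reader]


def abs_parameter_names() -> list[str]:
    return [rec.name for rec in abs_parameter_table()]


@dataclass(frozen=True)
class CompetencyCase:
    """A competency question with its expected answer.

    ``kind`` is ``query`` (DL query string), ``fillers`` (payload =
    ``(subject, property)``) or ``definition`` (payload = ``(subject,
    data property)``, expected = literal value).
    """

    id: str
    question: str
    kind: str
    payload: object
    expected: frozenset | int | float | str


COMPETENCY_CASES: tuple[CompetencyCase, ...] = (
    CompetencyCase(
        "CQ1",
        "Which characteristics make an algorithm suitable for data with class imbalance?",
        "query",
        "Characteristics and suitableFor some DataWithClassImbalance",
        frozenset({"ToleranceToClassImbalance"}),
    ),
    CompetencyCase(
        "CQ2",
        "Which output models are available for binary classification tasks?",
        "query",
        "OutputModel and availableFor some BinaryClassification",
        frozenset({"BinaryClassificationModel"}),
    ),
    CompetencyCase(
        "CQ3",
        "Which characteristics does BayesianAlgorithm have?",
        "fillers",
        ("BayesianAlgorithm", "hasCharacteristic"),
        frozenset({"ToleranceToClassImbalance", "HandlingOfClassificationCosts",
                   "BiasVarianceProfile"}),
    ),
    CompetencyCase(
        "CQ4",
        "What outputs does data-mining goals identification have?",
        "fillers",
        ("DataMiningGoalsIdentification", "hasOutput"),
        frozenset({"DataMiningGoalsDescription", "DataMiningSuccessCriteriaDescription"}),
    ),
    CompetencyCase(
        "CQ5",
        "Which algorithms does the process DimensionReduction employ?",
        "query",
        "Algorithm and employedBy some DimensionReduction",
        frozenset({"PCA"}),
    ),
    CompetencyCase(
        "CQ6",
        "How is the data characteristic LongTSDataset defined?",
        "definition",
        ("LongTSDataset", "hasMinLength"),
        700,
    ),
    CompetencyCase(
        "CQ7",
        "What are the post-processes of BusinessUnderstanding?",
        "fillers",
        ("BusinessUnderstanding", "hasPostprocess"),
        frozenset({"DataUnderstanding"}),
    ),
    CompetencyCase(
        "CQ8",
        "What sub-processes does BusinessUnderstanding have?",
        "fillers",
        ("BusinessUnderstanding", "hasSubprocess"),
        frozenset({"ApplicationObjectivesIdentification", "ApplicationResourcesAssessment",
                   "DataMiningGoalsIdentification"}),
    ),
    CompetencyCase(
        "CQ9",
        "What parameters does SVC_Algorithm need?",
        "fillers",
        ("SVC_Algorithm", "hasParameter"),
        frozenset({"CapacityParameter", "KernelTypeParameter"}),
    ),
)


@dataclass(frozen=True)
class CompetencyReport:
    id: str
    passed: bool
    expected: object
    actual: object


def answer_competency_case(kb: KnowledgeBase, case: CompetencyCase,
                           closure: Closure | None = None):
    if closure is None:
        closure = classify(kb)
    if case.kind == "query":
        return frozenset(answer_query(kb, case.payload, closure))
    if case.kind == "fillers":
        subject, prop = case.payload
        return frozenset(property_fillers(kb, subject, prop, closure))
    if case.kind == "definition":
        subject, dprop = case.payload
        literal = data_property_value(kb, subject, dprop)
        return None if literal is None else literal.as_python()
    raise ValueError(f"unknown competency case kind {case.kind!r}")


def run_competency_suite(kb: KnowledgeBase | None = None) -> list[CompetencyReport]:
    """Answer every competency question against ``kb`` (default: packaged merge)."""
    if kb is None:
        kb = load_merged()
    closure = classify(kb)
    reports = []
    for case in COMPETENCY_CASES:
        actual = answer_competency_case(kb, case, closure)
        reports.append(CompetencyReport(case.id, actual == case.expected,
                                        case.expected, actual))
    return reports
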