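"""Core ontology-as-graph data model.

An ontology is held as a five-tuple O = (C, R, H^C, H^R, I): a set of
concepts C with a subsumption hierarchy H^C, a set of properties R with a
sub-property hierarchy H^R, and instantiation assertions I.  Everything is
stored as a flat list of axioms over named entities; the five-tuple views
are derived from the axiom list on demand.

Entities live in a single namespace per knowledge base and are addressed by
their local name; the full IRI is ``namespace#name``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

CLASS = "class"
OBJECT_PROPERTY = "object-property"
DATA_PROPERTY = "data-property"
INDIVIDUAL = "individual"

ENTITY_KINDS = (CLASS, OBJECT_PROPERTY, DATA_PROPERTY, INDIVIDUAL)

# axiom forms
SUBCLASS_OF = "subClassOf"
SUBPROPERTY_OF = "subPropertyOf"
RESTRICTION = "existentialRestriction"  # C1 subsumed-by (P some C2)
CLASS_ASSERTION = "classAssertion"  # individual : C
PROPERTY_ASSERTION = "propertyAssertion"  # (i, P, j)
DATA_PROPERTY_ASSERTION = "dataPropertyAssertion"  # (subject, D, literal)

AXIOM_FORMS = (
    SUBCLASS_OF,
    SUBPROPERTY_OF,
    RESTRICTION,
    CLASS_ASSERTION,
    PROPERTY_ASSERTION,
    DATA_PROPERTY_ASSERTION,
)


class KBError(Exception):
    """Base class for knowledge-base errors."""


class ParseError(KBError):
    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class DanglingReferenceError(KBError):
    def __init__(self, iri: str):
        self.iri = iri
        super().__init__(f"axiom references unknown entity {iri!r}")


class KindConflictError(KBError):
    def __init__(self, iri_a: str, kind_a: str, iri_b: str, kind_b: str):
        self.iris = (iri_a, iri_b)
        super().__init__(
            f"entity kind conflict: {iri_a!r} is a {kind_a} but {iri_b!r} is a {kind_b}"
        )


class CycleError(KBError):
    def __init__(self, cycle: list[str], relation: str = SUBCLASS_OF):
        self.cycle = list(cycle)
        super().__init__(f"{relation} cycle detected: {' -> '.join(cycle + cycle[:1])}")


class UnresolvableNameError(KBError):
    def __init__(self, name: str):
        self.name = name
        super().__init__(f"name {name!r} does not resolve against the knowledge base")


@dataclass(frozen=True)
class Entity:
    """A named ontology entity (class, property or individual)."""

    name: str
    kind: str
    namespace: str = "kb"

    def __post_init__(self) -> None:
        if self.kind not in ENTITY_KINDS:
            raise ValueError(f"unknown entity kind {self.kind!r}")
        if not self.name or any(c.isspace() for c in self.name):
            raise ValueError(f"invalid entity name {self.name!r}")

    @property
    def iri(self) -> str:
        return f"{self.namespace}#{self.name}"


@dataclass(frozen=True)
class Literal:
    """A typed literal value attached through a data property."""

    value: str
    datatype: str = "string"

    def as_python(self) -> int | float | bool | str:
        if self.datatype == "integer":
            return int(self.value)
        if self.datatype in ("float", "double", "decimal"):
            return float(self.value)
        if self.datatype == "boolean":
            return self.value.lower() in ("true", "1")
        return self.value


@dataclass(frozen=True)
class Axiom:
    """One logical statement over named entities.

    ``args`` holds local entity names; for data-property assertions the
    literal is carried separately.
    """

    form: str
    args: tuple[str, ...]
    literal: Literal | None = None

    def __post_init__(self) -> None:
        if self.form not in AXIOM_FORMS:
            raise ValueError(f"unknown axiom form {self.form!r}")
        arity = {
            SUBCLASS_OF: 2,
            SUBPROPERTY_OF: 2,
            RESTRICTION: 3,
            CLASS_ASSERTION: 2,
            PROPERTY_ASSERTION: 3,
            DATA_PROPERTY_ASSERTION: 2,
        }[self.form]
        if len(self.args) != arity:
            raise ValueError(f"{self.form} expects {arity} entity names, got {self.args}")
        if (self.literal is None) == (self.form == DATA_PROPERTY_ASSERTION):
            raise ValueError("literal is required exactly for data-property assertions")

    # expected kinds of each argument slot
    def arg_kinds(self) -> tuple[str, ...]:
        return {
            SUBCLASS_OF: (CLASS, CLASS),
            SUBPROPERTY_OF: (OBJECT_PROPERTY, OBJECT_PROPERTY),
            RESTRICTION: (CLASS, OBJECT_PROPERTY, CLASS),
            # data-property subjects may be classes as well (annotation-style
            # definitions such as a minimum-length threshold on a dataset class)
            CLASS_ASSERTION: (INDIVIDUAL, CLASS),
            PROPERTY_ASSERTION: (INDIVIDUAL, OBJECT_PROPERTY, INDIVIDUAL),
            DATA_PROPERTY_ASSERTION: (None, DATA_PROPERTY),
        }[self.form]


class KnowledgeBase:
    """A typed graph of entities and axioms.

    Attributes mirror the classical five-tuple: :attr:`concepts` (C),
    :attr:`properties` (R), :meth:`subclass_pairs` (H^C),
    :meth:`subproperty_pairs` (H^R) and :meth:`instance_pairs` (I).
    """

    def __init__(self, namespace: str = "kb"):
        self.namespace = namespace
        self._entities: dict[str, Entity] = {}
        self._axioms: list[Axiom] = []

    # ------------------------------------------------------------------ build
    def add_entity(self, name: str, kind: str) -> Entity:
        existing = self._entities.get(name)
        if existing is not None:
            if existing.kind != kind:
                raise KindConflictError(existing.iri, existing.kind,
                                        f"{self.namespace}#{name}", kind)
            return existing
        ent = Entity(name, kind, self.namespace)
        self._entities[name] = ent
        return ent

    def add_axiom(self, axiom: Axiom, declare: bool = False) -> None:
        """Append an axiom, validating its signature.

        With ``declare=True`` unknown referenced entities are declared with
        the kind the axiom slot implies; otherwise a dangling reference is an
        error.  Data-property subjects are never auto-declared (their kind is
        ambiguous), so they must exist beforehand.
        """
        kinds = axiom.arg_kinds()
        for name, kind in zip(axiom.args, kinds):
            ent = self._entities.get(name)
            if ent is None:
                if declare and kind is not None:
                    self.add_entity(name, kind)
                else:
                    raise DanglingReferenceError(f"{self.namespace}#{name}")
            elif kind is not None and ent.kind != kind:
                raise KindConflictError(ent.iri, ent.kind,
                                        f"{self.namespace}#{name}", kind)
        self._axioms.append(axiom)

    # ------------------------------------------------------------------ views
    @property
    def entities(self) -> dict[str, Entity]:
        return dict(self._entities)

    @property
    def axioms(self) -> list[Axiom]:
        return list(self._axioms)

    def __contains__(self, name: str) -> bool:
        return name in self._entities

    def __len__(self) -> int:
        return len(self._entities)

    def entity(self, name: str) -> Entity:
        try:
            return self._entities[name]
        except KeyError:
            raise UnresolvableNameError(name) from None

    def names_of_kind(self, kind: str) -> set[str]:
        return {n for n, e in self._entities.items() if e.kind == kind}

    @property
    def concepts(self) -> set[str]:
        return self.names_of_kind(CLASS)

    @property
    def properties(self) -> set[str]:
        return self.names_of_kind(OBJECT_PROPERTY) | self.names_of_kind(DATA_PROPERTY)

    def axioms_of(self, form: str) -> Iterator[Axiom]:
        return (a for a in self._axioms if a.form == form)

    def subclass_pairs(self) -> set[tuple[str, str]]:
        return {a.args for a in self.axioms_of(SUBCLASS_OF)}

    def subproperty_pairs(self) -> set[tuple[str, str]]:
        return {a.args for a in self.axioms_of(SUBPROPERTY_OF)}

    def instance_pairs(self) -> set[tuple[str, str]]:
        return {a.args for a in self.axioms_of(CLASS_ASSERTION)}

    def restrictions(self) -> Iterator[tuple[str, str, str]]:
        for a in self.axioms_of(RESTRICTION):
            yield a.args  # (subject class, property, filler class)

    def data_property_literals(self, subject: str, dprop: str) -> list[Literal]:
        return [a.literal for a in self.axioms_of(DATA_PROPERTY_ASSERTION)
                if a.args == (subject, dprop) and a.literal is not None]

    # ------------------------------------------------------------- validation
    def validate(self) -> None:
        """Check all type invariants; raises on the first violation."""
        for ax in self._axioms:
            for name, kind in zip(ax.args, ax.arg_kinds()):
                ent = self._entities.get(name)
                if ent is None:
                    raise DanglingReferenceError(f"{self.namespace}#{name}")
                if kind is not None and ent.kind != kind:
                    raise KindConflictError(ent.iri, ent.kind, ent.iri, kind)
        self._check_acyclic(self.subclass_pairs(), SUBCLASS_OF)
        self._check_acyclic(self.subproperty_pairs(), SUBPROPERTY_OF)

    @staticmethod
    def _check_acyclic(pairs: Iterable[tuple[str, str]], relation: str) -> None:
        import networkx as nx

        graph = nx.DiGraph(list(pairs))
        try:
            cycle = nx.find_cycle(graph)
        except nx.NetworkXNoCycle:
            return
        raise CycleError([u for u, _ in cycle], relation)

    # ------------------------------------------------------------- comparison
    def canonical_axioms(self) -> tuple:
        def key(a: Axiom):
            lit = ("", "") if a.literal is None else (a.literal.value, a.literal.datatype)
            return (a.form, a.args, lit)

        return tuple(sorted((key(a) for a in self._axioms)))

    def signature(self) -> set[tuple[str, str]]:
        return {(e.name, e.kind) for e in self._entities.values()}

    def copy(self, namespace: str | None = None) -> "KnowledgeBase":
        out = KnowledgeBase(namespace or self.namespace)
        for ent in self._entities.values():
            out.add_entity(ent.name, ent.kind)
        out._axioms = list(self._axioms)
        return out


@dataclass(frozen=True)
class Atom:
    """One conjunct of a DL-style query: a named class or ``P some C``."""

    kind: str  # "class" | "some"
    cls: str
    prop: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("class", "some"):
            raise ValueError(f"unknown atom kind {self.kind!r}")
        if (self.prop is None) != (self.kind == "class"):
            raise ValueError("property required exactly for 'some' atoms")


@dataclass(frozen=True)
class DLQuery:
    """Conjunction of atoms in the Manchester-like ``A and P some B`` style."""

    conjuncts: tuple[Atom, ...]

    def __post_init__(self) -> None:
        if not self.conjuncts:
            raise ValueError("a query needs at least one conjunct")

    def validate(self, kb: KnowledgeBase) -> None:
        for atom in self.conjuncts:
            if atom.cls not in kb or kb.entity(atom.cls).kind != CLASS:
                raise UnresolvableNameError(atom.cls)
            if atom.prop is not None:
                if atom.prop not in kb or kb.entity(atom.prop).kind != OBJECT_PROPERTY:
                    raise UnresolvableNameError(atom.prop)


def parse_query(text: str) -> DLQuery:
    """Parse ``Name and prop some Name and ...`` into a :class:`DLQuery`."""
    text = text.strip()
    if not text:
        raise ParseError("empty query")
    atoms: list[Atom] = []
    for part in (p.strip().strip("()") for p in text.split(" and ")):
        tokens = part.split()
        if len(tokens) == 1:
            atoms.append(Atom("class", tokens[0]))
        elif len(tokens) == 3 and tokens[1] == "some":
            atoms.append(Atom("some", tokens[2], prop=tokens[0]))
        else:
            raise ParseError(f"cannot parse query conjunct {part!r}")
    return DLQuery(tuple(atoms))
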