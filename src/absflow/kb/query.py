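"""DL-style conjunctive query answering over a classified knowledge base.

Only the constructs the workflow queries actually use are supported:
conjunction of named classes and existential restrictions over named
fillers.  A named class X satisfies ``C`` when X is (reflexively,
transitively) subsumed by C, and satisfies ``P some C`` when some
restriction axiom ``X' subsumed-by (P' some C')`` exists with X below X',
P' below P and C' below C.  Individuals satisfy atoms through their
asserted types and property assertions.
"""

from __future__ import annotations

from .model import Atom, DLQuery, KnowledgeBase, Literal, parse_query
from .ops import Closure, classify


def class_satisfies(kb: KnowledgeBase, closure: Closure, x: str, atom: Atom) -> bool:
    if atom.kind == "class":
        return closure.subsumed_by(x, atom.cls)
    assert atom.prop is not None
    for subj, prop, filler in kb.restrictions():
        if (closure.subsumed_by(x, subj)
                and closure.property_subsumed_by(prop, atom.prop)
                and closure.subsumed_by(filler, atom.cls)):
            return True
    return False


def individual_satisfies(kb: KnowledgeBase, closure: Closure, ind: str, atom: Atom) -> bool:
    types = {cls for i, cls in kb.instance_pairs() if i == ind}
    if atom.kind == "class":
        return any(closure.subsumed_by(t, atom.cls) for t in types)
    assert atom.prop is not None
    for i, prop, j in (a.args for a in kb.axioms_of("propertyAssertion")):
        if i != ind or not closure.property_subsumed_by(prop, atom.prop):
            continue
        j_types = {cls for k, cls in kb.instance_pairs() if k == j}
        if any(closure.subsumed_by(t, atom.cls) for t in j_types):
            return True
    # an individual also inherits satisfaction from its asserted types
    return any(class_satisfies(kb, closure, t, atom) for t in types)


def answer_query(kb: KnowledgeBase, query: DLQuery | str,
                 closure: Closure | None = None) -> list[str]:
    """Return the named classes and individuals satisfying every conjunct.

    The answer is sorted lexicographically, so it is deterministic and
    order-independent.  Adding a conjunct can only shrink it.
    """
    if isinstance(query, str):
        query = parse_query(query)
    query.validate(kb)
    if closure is None:
        closure = classify(kb)
    answers: set[str] = set()
    for cls in kb.concepts:
        if all(class_satisfies(kb, closure, cls, atom) for atom in query.conjuncts):
            answers.add(cls)
    for ind in kb.names_of_kind("individual"):
        if all(individual_satisfies(kb, closure, ind, atom) for atom in query.conjuncts):
            answers.add(ind)
    return sorted(answers)


def property_fillers(kb: KnowledgeBase, subject: str, prop: str,
                     closure: Closure | None = None) -> list[str]:
    """Named fillers C of restrictions ``X (P some C)`` inherited by ``subject``.

    Restrictions asserted on any superclass of ``subject`` count, as do
    subproperties of ``prop``.  Used for definition-style competency lookups
    ("what are the outputs / parameters / post-processes of ...").
    """
    if closure is None:
        closure = classify(kb)
    if subject not in kb:
        from .model import UnresolvableNameError

        raise UnresolvableNameError(subject)
    out = set()
    for subj, p, filler in kb.restrictions():
        if closure.subsumed_by(subject, subj) and closure.property_subsumed_by(p, prop):
            out.add(filler)
    return sorted(out)


def data_property_value(kb: KnowledgeBase, subject: str, dprop: str) -> Literal | None:
    lits = kb.data_property_literals(subject, dprop)
    return lits[0] if lits else None
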