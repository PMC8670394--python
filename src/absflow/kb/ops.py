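"""Ontology operations: merging, sub-ontology extraction, classification.

Merging rewrites both inputs into one fresh namespace and unifies entities
that share a local name (same name with a different kind is an error, since
shared names are exactly how domain knowledge hooks into the data-mining
knowledge).  Extraction walks the restriction path from a task entity and
keeps everything the task can reach; classification materializes the
reflexive-transitive subsumption closure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .model import (
    CycleError,
    KindConflictError,
    KnowledgeBase,
    UnresolvableNameError,
)


def merge(kb_a: KnowledgeBase, kb_b: KnowledgeBase,
          new_namespace: str = "merged") -> KnowledgeBase:
    """Merge two knowledge bases into ``new_namespace``.

    Every axiom of either input appears in the result with its entity IRIs
    rewritten; byte-identical axioms are deduplicated in a single linear
    pass, so the output axiom count is at most ``len(a) + len(b)`` with
    equality for duplicate-free inputs with disjoint signatures.
    """
    for name, ent_a in kb_a.entities.items():
        ent_b = kb_b.entities.get(name)
        if ent_b is not None and ent_b.kind != ent_a.kind:
            raise KindConflictError(ent_a.iri, ent_a.kind, ent_b.iri, ent_b.kind)

    out = KnowledgeBase(new_namespace)
    for kb in (kb_a, kb_b):
        for ent in kb.entities.values():
            out.add_entity(ent.name, ent.kind)
    seen: set = set()
    for kb in (kb_a, kb_b):
        for ax in kb.axioms:
            key = (ax.form, ax.args,
                   None if ax.literal is None else (ax.literal.value, ax.literal.datatype))
            if key in seen:
                continue
            seen.add(key)
            out.add_axiom(ax)
    return out


def extract_subontology(kb: KnowledgeBase, task: str) -> KnowledgeBase:
    """Extract the restriction-path sub-ontology seeded at ``task``.

    The kept entity set is the least fixed point of:

    * the seed is kept;
    * superclasses (and superproperties) of kept entities are kept;
    * for a restriction ``C1 subsumed-by (P some C2)``: if ``C1`` is kept,
      ``P``, ``C2`` and the whole subclass subtree below ``C2`` are kept
      (the filler names the kind of resource the kept entity needs, so its
      specializations stay available); if ``C2`` is kept, ``C1`` and ``P``
      are kept (one inbound step, after which the upward rules apply again);
    * individuals typed with a kept class are kept, and properties linking
      two kept individuals are kept.

    The result contains exactly the kept entities plus every axiom whose
    full signature lies inside the kept set.
    """
    if task not in kb:
        raise UnresolvableNameError(task)

    sub_up: dict[str, set[str]] = {}
    sub_down: dict[str, set[str]] = {}
    for c1, c2 in kb.subclass_pairs():
        sub_up.setdefault(c1, set()).add(c2)
        sub_down.setdefault(c2, set()).add(c1)
    prop_up: dict[str, set[str]] = {}
    for r1, r2 in kb.subproperty_pairs():
        prop_up.setdefault(r1, set()).add(r2)
    restrictions = list(kb.restrictions())
    instance_of: dict[str, set[str]] = {}
    for ind, cls in kb.instance_pairs():
        instance_of.setdefault(cls, set()).add(ind)

    def subtree(root: str) -> set[str]:
        out = {root}
        stack = [root]
        while stack:
            for child in sub_down.get(stack.pop(), ()):
                if child not in out:
                    out.add(child)
                    stack.append(child)
        return out

    kept: set[str] = {task}
    changed = True
    while changed:
        changed = False
        new: set[str] = set()
        for name in kept:
            new |= sub_up.get(name, set())
            new |= prop_up.get(name, set())
            new |= instance_of.get(name, set())
        for c1, prop, c2 in restrictions:
            if c1 in kept:
                new.add(prop)
                new |= subtree(c2)
            if c2 in kept:
                new.add(prop)
                new.add(c1)
        for ax in kb.axioms_of("propertyAssertion"):
            i, prop, j = ax.args
            if i in kept and j in kept:
                new.add(prop)
        if not new <= kept:
            kept |= new
            changed = True

    out = KnowledgeBase(kb.namespace)
    for name in sorted(kept):
        ent = kb.entity(name)
        out.add_entity(ent.name, ent.kind)
    for ax in kb.axioms:
        if ax.form == "dataPropertyAssertion":
            # data-property annotations travel with their kept subject
            if ax.args[0] in kept:
                out.add_entity(ax.args[1], kb.entity(ax.args[1]).kind)
                out.add_axiom(ax)
        elif all(arg in kept for arg in ax.args):
            out.add_axiom(ax)
    return out


@dataclass
class Closure:
    """Reflexive-transitive subsumption closure of a classified ontology.

    ``superclasses[X]`` is the set of named classes subsuming X, X included;
    ``superproperties`` is the analogue over the property hierarchy.
    """

    superclasses: dict[str, set[str]] = field(default_factory=dict)
    superproperties: dict[str, set[str]] = field(default_factory=dict)

    def subsumed_by(self, sub: str, sup: str) -> bool:
        return sup in self.superclasses.get(sub, {sub})

    def property_subsumed_by(self, sub: str, sup: str) -> bool:
        return sup in self.superproperties.get(sub, {sub})

    def subclasses_of(self, cls: str) -> set[str]:
        return {c for c, sups in self.superclasses.items() if cls in sups}


def classify(kb: KnowledgeBase) -> Closure:
    """Compute the subsumption closure; cycles are reported as errors."""
    closure = Closure()
    closure.superclasses = _reflexive_transitive(
        kb.concepts, kb.subclass_pairs(), "subClassOf")
    props = kb.names_of_kind("object-property")
    closure.superproperties = _reflexive_transitive(
        props, kb.subproperty_pairs(), "subPropertyOf")
    return closure


def _reflexive_transitive(nodes: set[str], pairs: set[tuple[str, str]],
                          relation: str) -> dict[str, set[str]]:
    graph = nx.DiGraph()
    graph.add_nodes_from(nodes)
    graph.add_edges_from(pairs)
    try:
        cycle = nx.find_cycle(graph)
    except nx.NetworkXNoCycle:
        pass
    else:
        raise CycleError([u for u, _ in cycle], relation)
    return {n: {n} | nx.descendants(graph, n) for n in graph.nodes}
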