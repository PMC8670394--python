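"""Random knowledge-base and query generators for property checks.

The subclass relation is generated acyclic by construction (edges only go
from higher to lower index), so random instances always satisfy the
hierarchy invariants.
"""

from __future__ import annotations

import numpy as np

from .model import Atom, Axiom, DLQuery, KnowledgeBase


def random_knowledge_base(
    rng: np.random.Generator,
    n_classes: int = 20,
    n_properties: int = 3,
    n_individuals: int = 4,
    subclass_p: float = 0.12,
    n_restrictions: int = 12,
    n_assertions: int = 6,
    namespace: str = "rand",
) -> KnowledgeBase:
    kb = KnowledgeBase(namespace)
    classes = [f"C{i}" for i in range(n_classes)]
    props = [f"P{i}" for i in range(n_properties)]
    inds = [f"i{i}" for i in range(n_individuals)]
    for c in classes:
        kb.add_entity(c, "class")
    for p in props:
        kb.add_entity(p, "object-property")
    for i in inds:
        kb.add_entity(i, "individual")

    # acyclic subclass DAG: C_i below C_j only for i > j
    for i in range(1, n_classes):
        for j in range(i):
            if rng.random() < subclass_p:
                kb.add_axiom(Axiom("subClassOf", (classes[i], classes[j])))
    if n_properties > 1:
        for i in range(1, n_properties):
            if rng.random() < 0.5:
                j = int(rng.integers(0, i))
                kb.add_axiom(Axiom("subPropertyOf", (props[i], props[j])))
    for _ in range(n_restrictions):
        c1, c2 = rng.choice(classes, size=2)
        p = str(rng.choice(props))
        kb.add_axiom(Axiom("existentialRestriction", (str(c1), p, str(c2))))
    for _ in range(n_assertions):
        ind = str(rng.choice(inds))
        if rng.random() < 0.6:
            kb.add_axiom(Axiom("classAssertion", (ind, str(rng.choice(classes)))))
        else:
            kb.add_axiom(Axiom("propertyAssertion",
                               (ind, str(rng.choice(props)), str(rng.choice(inds)))))
    return kb


def random_query(rng: np.random.Generator, kb: KnowledgeBase,
                 n_conjuncts: int = 2) -> DLQuery:
    classes = sorted(kb.concepts)
    props = sorted(kb.names_of_kind("object-property"))
    atoms = []
    for _ in range(n_conjuncts):
        if props and rng.random() < 0.5:
            atoms.append(Atom("some", str(rng.choice(classes)), prop=str(rng.choice(props))))
        else:
            atoms.append(Atom("class", str(rng.choice(classes))))
    return DLQuery(tuple(atoms))
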