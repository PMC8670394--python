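"""Knowledge-base engine: file format, merging, extraction, classification
and query answering, each checked against an independent oracle."""

import numpy as np
import pytest

from absflow.kb import (
    Atom,
    Axiom,
    CycleError,
    DanglingReferenceError,
    DLQuery,
    KindConflictError,
    KnowledgeBase,
    ParseError,
    UnresolvableNameError,
    answer_query,
    classify,
    dumps_kb,
    extract_subontology,
    loads_kb,
    merge,
    parse_query,
)
from absflow.kb.synth import random_knowledge_base, random_query


def simple_kb(axiom_lines: str) -> KnowledgeBase:
    return loads_kb(axiom_lines)


# ---------------------------------------------------------------- file format
class TestFileFormat:
    def test_empty_file_gives_empty_kb(self):
        kb = loads_kb("")
        assert len(kb) == 0 and kb.axioms == []

    def test_comments_and_blank_lines_ignored(self):
        kb = loads_kb("# a comment\n\nSUBCLASSOF\tA\tB\n")
        assert kb.subclass_pairs() == {("A", "B")}

    def test_parse_error_carries_line_number(self):
        with pytest.raises(ParseError) as err:
            loads_kb("SUBCLASSOF\tA\tB\nBOGUS\tX\n")
        assert err.value.line == 2

    def test_dataprop_on_undeclared_subject_is_dangling(self):
        with pytest.raises(DanglingReferenceError) as err:
            loads_kb("DATAPROP\tGhost\thasMinLength\t700\tinteger\n")
        assert "Ghost" in str(err.value)

    def test_kind_conflict_reports_both_iris(self):
        with pytest.raises(ParseError):
            loads_kb("SUBCLASSOF\tA\tB\nSUBPROP\tA\tR\n")

    @pytest.mark.parametrize("seed", range(5))
    def test_round_trip_preserves_axiom_multiset(self, seed):
        rng = np.random.default_rng(seed)
        kb = random_knowledge_base(rng, n_restrictions=20, n_assertions=10)
        again = loads_kb(dumps_kb(kb), namespace=kb.namespace)
        assert again.canonical_axioms() == kb.canonical_axioms()
        assert again.signature() == kb.signature()
        # a second round trip is the identity on the serialization
        assert dumps_kb(again) == dumps_kb(kb)


# --------------------------------------------------------------------- merge
class TestMerge:
    def test_merge_of_empty_kbs_is_empty(self):
        out = merge(KnowledgeBase("a"), KnowledgeBase("b"), "m")
        assert len(out) == 0 and out.axioms == []

    @pytest.mark.parametrize("seed", range(5))
    def test_disjoint_signatures_add_axiom_counts(self, seed):
        kb_a = random_knowledge_base(np.random.default_rng(seed), namespace="a")
        src = random_knowledge_base(np.random.default_rng(seed + 100))
        kb_b = KnowledgeBase("b")  # rename everything so signatures are disjoint
        for name, ent in src.entities.items():
            kb_b.add_entity("X" + name, ent.kind)
        for ax in src.axioms:
            kb_b.add_axiom(Axiom(ax.form, tuple("X" + a for a in ax.args),
                                 literal=ax.literal))
        n_a = len(set(kb_a.canonical_axioms()))
        n_b = len(set(kb_b.canonical_axioms()))
        merged = merge(kb_a, kb_b, "m")
        # duplicates within one input collapse; across disjoint inputs
        # nothing else can collapse
        assert len(merged.axioms) == n_a + n_b

    def test_merge_conserves_signature_and_axioms(self):
        kb_a = simple_kb("SUBCLASSOF\tA\tB\nRESTRICTION\tA\tp\tsome\tC\n")
        kb_b = simple_kb("SUBCLASSOF\tC\tD\n")
        merged = merge(kb_a, kb_b, "m")
        assert merged.signature() == kb_a.signature() | kb_b.signature()
        for ax in kb_a.axioms + kb_b.axioms:
            assert ax in merged.axioms
        assert merged.namespace == "m"
        assert all(e.namespace == "m" for e in merged.entities.values())

    def test_shared_local_names_unify(self):
        kb_a = simple_kb("SUBCLASSOF\tShared\tA\n")
        kb_b = simple_kb("SUBCLASSOF\tB\tShared\n")
        merged = merge(kb_a, kb_b, "m")
        assert len(merged) == 3

    def test_same_name_different_kind_is_a_conflict(self):
        kb_a = simple_kb("SUBCLASSOF\tThing\tA\n")
        kb_b = simple_kb("SUBPROP\tThing\tr\n")
        with pytest.raises(KindConflictError) as err:
            merge(kb_a, kb_b, "m")
        assert "Thing" in str(err.value)


# ---------------------------------------------------------------- extraction
def oracle_extract_entities(kb: KnowledgeBase, seed: str) -> set:
    """Independent breadth-first reachability over the same edge rules."""
    up = {}
    down = {}
    for a, b in kb.subclass_pairs():
        up.setdefault(a, set()).add(b)
        down.setdefault(b, set()).add(a)
    pup = {}
    for a, b in kb.subproperty_pairs():
        pup.setdefault(a, set()).add(b)
    inst = {}
    for i, c in kb.instance_pairs():
        inst.setdefault(c, set()).add(i)
    restr = list(kb.restrictions())
    props = list(a.args for a in kb.axioms_of("propertyAssertion"))

    def down_closure(x):
        out, frontier = {x}, [x]
        while frontier:
            for child in down.get(frontier.pop(), ()):  # noqa: B023
                if child not in out:
                    out.add(child)
                    frontier.append(child)
        return out

    kept = {seed}
    while True:
        new = set(kept)
        for x in set(kept):
            new |= up.get(x, set()) | pup.get(x, set()) | inst.get(x, set())
        for c1, p, c2 in restr:
            if c1 in kept:
                new |= {p} | down_closure(c2)
            if c2 in kept:
                new |= {p, c1}
        for i, p, j in props:
            if i in kept and j in kept:
                new.add(p)
        if new == kept:
            return kept
        kept = new


class TestExtraction:
    def test_isolated_class_extracts_alone(self):
        kb = loads_kb("CLASS\tLoner\nSUBCLASSOF\tA\tB\n")
        sub = extract_subontology(kb, "Loner")
        assert set(sub.entities) == {"Loner"} and sub.axioms == []

    def test_unknown_seed_raises(self, merged_kb):
        with pytest.raises(UnresolvableNameError):
            extract_subontology(merged_kb, "NoSuchEntity")

    def test_extraction_is_sound_and_idempotent(self, merged_kb):
        sub = extract_subontology(merged_kb, "ConsistencyAnalysis")
        assert set(sub.entities) <= set(merged_kb.entities)
        assert set(sub.canonical_axioms()) <= set(merged_kb.canonical_axioms())
        twice = extract_subontology(sub, "ConsistencyAnalysis")
        assert twice.canonical_axioms() == sub.canonical_axioms()
        assert set(twice.entities) == set(sub.entities)

    @pytest.mark.parametrize("seed", range(10))
    def test_kept_entities_match_reachability_oracle(self, seed):
        rng = np.random.default_rng(seed)
        kb = random_knowledge_base(rng, n_classes=25, n_restrictions=18)
        seed_entity = f"C{int(rng.integers(0, 25))}"
        sub = extract_subontology(kb, seed_entity)
        assert set(sub.entities) == oracle_extract_entities(kb, seed_entity)


# ------------------------------------------------------------ classification
def oracle_closure(kb: KnowledgeBase) -> dict:
    """Transitive closure by boolean matrix powers."""
    classes = sorted(kb.concepts)
    idx = {c: i for i, c in enumerate(classes)}
    n = len(classes)
    mat = np.eye(n, dtype=bool)
    for a, b in kb.subclass_pairs():
        mat[idx[a], idx[b]] = True
    for _ in range(n):
        new = mat | (mat @ mat)
        if (new == mat).all():
            break
        mat = new
    return {c: {classes[j] for j in np.nonzero(mat[idx[c]])[0]} for c in classes}


class TestClassify:
    def test_chain_transitivity(self):
        kb = simple_kb("SUBCLASSOF\tA\tB\nSUBCLASSOF\tB\tC\n")
        closure = classify(kb)
        assert closure.subsumed_by("A", "C")
        assert not closure.subsumed_by("C", "A")

    def test_empty_kb_has_empty_closure(self):
        closure = classify(KnowledgeBase())
        assert closure.superclasses == {} and closure.superproperties == {}

    def test_cycle_is_reported_with_its_members(self):
        kb = KnowledgeBase()
        kb.add_entity("A", "class")
        kb.add_entity("B", "class")
        kb.add_axiom(Axiom("subClassOf", ("A", "B")))
        kb.add_axiom(Axiom("subClassOf", ("B", "A")))
        with pytest.raises(CycleError) as err:
            classify(kb)
        assert set(err.value.cycle) == {"A", "B"}

    @pytest.mark.parametrize("seed", range(8))
    def test_closure_matches_matrix_power_oracle_and_is_idempotent(self, seed):
        kb = random_knowledge_base(np.random.default_rng(seed), n_classes=20)
        closure = classify(kb)
        assert closure.superclasses == oracle_closure(kb)
        # idempotence: closing the closed relation changes nothing
        closed = KnowledgeBase()
        for name, ent in kb.entities.items():
            closed.add_entity(name, ent.kind)
        for sub, sups in closure.superclasses.items():
            for sup in sups:
                if sub != sup:
                    closed.add_axiom(Axiom("subClassOf", (sub, sup)))
        assert classify(closed).superclasses == closure.superclasses


# ------------------------------------------------------------ query answering
def oracle_answers(kb: KnowledgeBase, query: DLQuery) -> set:
    """Brute-force evaluation of the satisfaction predicate."""
    sup = oracle_closure(kb)
    prop_sup = {}
    props = sorted(kb.names_of_kind("object-property"))
    for p in props:
        prop_sup[p] = {p}
    changed = True
    while changed:
        changed = False
        for a, b in kb.subproperty_pairs():
            add = prop_sup[b] - prop_sup[a]
            if add:
                prop_sup[a] |= add
                changed = True
    restr = list(kb.restrictions())
    types = {}
    for i, c in kb.instance_pairs():
        types.setdefault(i, set()).add(c)
    passert = [a.args for a in kb.axioms_of("propertyAssertion")]

    def cls_sat(x, atom):
        if atom.kind == "class":
            return atom.cls in sup[x]
        return any(subj in sup[x] and atom.prop in prop_sup[p]
                   and atom.cls in sup[f]
                   for subj, p, f in restr)

    def ind_sat(i, atom):
        ts = types.get(i, set())
        if atom.kind == "class":
            return any(atom.cls in sup[t] for t in ts)
        via_props = any(
            s == i and atom.prop in prop_sup[p]
            and any(atom.cls in sup[t] for t in types.get(o, set()))
            for s, p, o in passert)
        return via_props or any(cls_sat(t, atom) for t in ts)

    out = {c for c in kb.concepts
           if all(cls_sat(c, a) for a in query.conjuncts)}
    out |= {i for i in kb.names_of_kind("individual")
            if all(ind_sat(i, a) for a in query.conjuncts)}
    return out


class TestAnswerQuery:
    def test_parse_manchester_like_syntax(self):
        q = parse_query("Algorithm and suitableFor some SmallSizeDataset")
        assert q.conjuncts == (Atom("class", "Algorithm"),
                               Atom("some", "SmallSizeDataset", prop="suitableFor"))

    def test_unresolvable_name_raises(self, merged_kb):
        with pytest.raises(UnresolvableNameError):
            answer_query(merged_kb, "Algorithm and suitableFor some Nonsense")

    def test_published_competency_answers(self, merged_kb):
        assert answer_query(
            merged_kb, "Characteristics and suitableFor some DataWithClassImbalance"
        ) == ["ToleranceToClassImbalance"]
        assert answer_query(
            merged_kb, "Algorithm and employedBy some DimensionReduction") == ["PCA"]

    def test_class_without_subclasses_or_instances_plus_conjunct(self, merged_kb):
        # Deployment has no subclasses; requiring an unmatched restriction
        # empties the answer
        assert answer_query(
            merged_kb, "Deployment and suitableFor some Continuous") == []

    def test_query_monotonicity_adding_conjuncts_never_grows(self, merged_kb):
        broad = set(answer_query(merged_kb, "Algorithm"))
        narrow = set(answer_query(merged_kb, "Algorithm and suitableFor some Continuous"))
        narrower = set(answer_query(
            merged_kb,
            "Algorithm and suitableFor some Continuous and suitableFor some Missing_not_Random"))
        assert narrower <= narrow <= broad
        assert "KNN_Imputation_ED" in narrower

    @pytest.mark.parametrize("seed", range(15))
    def test_random_queries_match_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        kb = random_knowledge_base(rng, n_classes=15, n_restrictions=10)
        for _ in range(4):
            q = random_query(rng, kb)
            assert set(answer_query(kb, q)) == oracle_answers(kb, q)
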