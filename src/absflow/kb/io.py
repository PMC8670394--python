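"""Line-oriented text serialization of knowledge bases.

The format is UTF-8 text, one statement per line, tab-separated::

    CLASS<TAB>Name                      explicit class declaration
    OBJPROP<TAB>Name                    object-property declaration
    DATAPROPERTY<TAB>Name               data-property declaration
    INDIVIDUAL<TAB>Name                 individual declaration
    SUBCLASSOF<TAB>C1<TAB>C2            C1 is a subclass of C2
    SUBPROP<TAB>R1<TAB>R2               R1 is a subproperty of R2
    RESTRICTION<TAB>C1<TAB>P<TAB>some<TAB>C2   C1 is subsumed by (P some C2)
    TYPE<TAB>i<TAB>C                    individual i has type C
    PROP<TAB>i<TAB>P<TAB>j              object-property assertion
    DATAPROP<TAB>s<TAB>D<TAB>value<TAB>datatype  typed literal on s

Lines starting with ``#`` and blank lines are ignored.  Entities referenced
by axioms are declared implicitly with the kind their position implies,
except DATAPROP subjects, whose kind is ambiguous and must be known already
(otherwise a dangling-reference error names the missing IRI).
"""

from __future__ import annotations

from pathlib import Path

from .model import (
    CLASS,
    DATA_PROPERTY,
    INDIVIDUAL,
    OBJECT_PROPERTY,
    Axiom,
    DanglingReferenceError,
    KnowledgeBase,
    Literal,
    ParseError,
)

_DECLARATIONS = {
    "CLASS": CLASS,
    "OBJPROP": OBJECT_PROPERTY,
    "DATAPROPERTY": DATA_PROPERTY,
    "INDIVIDUAL": INDIVIDUAL,
}


def loads_kb(text: str, namespace: str = "kb") -> KnowledgeBase:
    kb = KnowledgeBase(namespace)
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        tag = fields[0]
        try:
            if tag in _DECLARATIONS:
                _expect(fields, 2, lineno)
                kb.add_entity(fields[1], _DECLARATIONS[tag])
            elif tag == "SUBCLASSOF":
                _expect(fields, 3, lineno)
                kb.add_axiom(Axiom("subClassOf", (fields[1], fields[2])), declare=True)
            elif tag == "SUBPROP":
                _expect(fields, 3, lineno)
                kb.add_axiom(Axiom("subPropertyOf", (fields[1], fields[2])), declare=True)
            elif tag == "RESTRICTION":
                _expect(fields, 5, lineno)
                if fields[3] != "some":
                    raise ParseError(f"expected 'some', got {fields[3]!r}", lineno)
                kb.add_axiom(
                    Axiom("existentialRestriction", (fields[1], fields[2], fields[4])),
                    declare=True,
                )
            elif tag == "TYPE":
                _expect(fields, 3, lineno)
                kb.add_axiom(Axiom("classAssertion", (fields[1], fields[2])), declare=True)
            elif tag == "PROP":
                _expect(fields, 4, lineno)
                kb.add_axiom(
                    Axiom("propertyAssertion", (fields[1], fields[2], fields[3])),
                    declare=True,
                )
            elif tag == "DATAPROP":
                _expect(fields, 5, lineno)
                if fields[1] not in kb:
                    raise DanglingReferenceError(f"{namespace}#{fields[1]}")
                kb.add_entity(fields[2], DATA_PROPERTY)
                kb.add_axiom(
                    Axiom(
                        "dataPropertyAssertion",
                        (fields[1], fields[2]),
                        literal=Literal(fields[3], fields[4]),
                    )
                )
            else:
                raise ParseError(f"unknown statement tag {tag!r}", lineno)
        except ParseError:
            raise
        except DanglingReferenceError:
            raise
        except Exception as exc:  # kind conflicts, arity errors
            raise ParseError(str(exc), lineno) from exc
    kb.validate()
    return kb


def _expect(fields: list[str], n: int, lineno: int) -> None:
    if len(fields) != n:
        raise ParseError(f"expected {n} tab-separated fields, got {len(fields)}", lineno)


def load_kb(path: str | Path, namespace: str | None = None) -> KnowledgeBase:
    """Load a knowledge base from the documented axiom file format."""
    path = Path(path)
    ns = namespace if namespace is not None else path.stem
    return loads_kb(path.read_text(encoding="utf-8"), namespace=ns)


def dumps_kb(kb: KnowledgeBase) -> str:
    """Serialize canonically (sorted); load(dump(kb)) preserves the axiom multiset."""
    lines: list[str] = []
    # declare every entity explicitly so isolated entities survive round-trips
    decl_tag = {v: k for k, v in _DECLARATIONS.items()}
    for name in sorted(kb.entities):
        lines.append(f"{decl_tag[kb.entity(name).kind]}\t{name}")
    rows: list[str] = []
    for ax in kb.axioms:
        if ax.form == "subClassOf":
            rows.append(f"SUBCLASSOF\t{ax.args[0]}\t{ax.args[1]}")
        elif ax.form == "subPropertyOf":
            rows.append(f"SUBPROP\t{ax.args[0]}\t{ax.args[1]}")
        elif ax.form == "existentialRestriction":
            rows.append(f"RESTRICTION\t{ax.args[0]}\t{ax.args[1]}\tsome\t{ax.args[2]}")
        elif ax.form == "classAssertion":
            rows.append(f"TYPE\t{ax.args[0]}\t{ax.args[1]}")
        elif ax.form == "propertyAssertion":
            rows.append(f"PROP\t{ax.args[0]}\t{ax.args[1]}\t{ax.args[2]}")
        elif ax.form == "dataPropertyAssertion":
            assert ax.literal is not None
            rows.append(
                f"DATAPROP\t{ax.args[0]}\t{ax.args[1]}\t{ax.literal.value}\t{ax.literal.datatype}"
            )
    lines.extend(sorted(rows))
    return "\n".join(lines) + ("\n" if lines else "")


def save_kb(kb: KnowledgeBase, path: str | Path) -> None:
    Path(path).write_text(dumps_kb(kb), encoding="utf-8")
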