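"""Readers and writers for the project's file formats.

Supported formats:

* OBO 1.2 flat files (a practical subset: ``[Term]`` stanzas with ``id``,
  ``name``, ``synonym``, ``def``, ``is_a`` and ``relationship`` tags, plus
  a ``property:`` tag for concept properties and an ``instance:`` tag for
  pass-through instance labels; unrecognised tags are preserved verbatim);
* a JSON dialect describing relational database schemas, mapped onto the
  same concept model (table -> concept, column -> property, foreign key ->
  ``references`` relation, binding link -> ``hasBinding`` relation);
* two-column TSV files of expert-declared equivalent concept-id pairs;
* three-column TSV alignment files (source, target, similarity);
* synonym lexicon TSV files, one tab-separated synset per line;
* learned-weight JSON and learning-trace CSV exports.
"""

from __future__ import annotations

import csv
import io as _io
import json
import re
from typing import Iterable, List, Sequence, TextIO, Tuple, Union

from .clustering import AlignedPair, Alignment
from .lexical import SynonymLexicon
from .model import Concept, ConceptGraph, UnknownConceptError, assert_dag
from .similarity import WeightVector

__all__ = [
    "FormatError",
    "read_obo",
    "write_obo",
    "read_schema",
    "read_pairs",
    "read_lexicon",
    "read_alignment",
    "write_alignment",
    "write_weights",
    "write_trace",
]


class FormatError(ValueError):
    """Malformed input file."""


TextSource = Union[str, TextIO]


def _as_text(source: TextSource) -> str:
    if isinstance(source, str):
        return source
    return source.read()


# ---------------------------------------------------------------------------
# OBO flat files
# ---------------------------------------------------------------------------

_QUOTED = re.compile(r'"((?:[^"\\]|\\.)*)"')

# Tags handled explicitly on read; everything else is preserved verbatim.
_KNOWN_TAGS = {
    "id", "name", "synonym", "def", "property", "is_a", "relationship", "instance",
}


def _strip_comment(value: str) -> str:
    # OBO allows trailing '!' comments, e.g. "is_a: T:0 ! root".
    return value.split("!", 1)[0].strip()


def _quoted_payload(value: str, tag: str, stanza: str) -> str:
    m = _QUOTED.search(value)
    if not m:
        raise FormatError(f"stanza {stanza}: {tag} tag has no quoted payload: {value!r}")
    return m.group(1).replace('\\"', '"')


def read_obo(source: TextSource) -> ConceptGraph:
    """Parse an OBO 1.2 flat file into a :class:`ConceptGraph`.

    The resulting graph is validated: all ``is_a`` and relationship targets
    must resolve and the ``is_a`` edges must be acyclic.
    """
    text = _as_text(source)
    graph_name = ""
    concepts: List[Concept] = []

    stanza_lines: List[Tuple[str, str]] = []
    stanza_kind: str | None = None
    stanza_no = 0

    def flush():
        nonlocal stanza_lines, stanza_kind
        if stanza_kind is None:
            stanza_lines = []
            return
        if stanza_kind != "Term":
            stanza_lines = []  # non-Term stanzas ignored
            stanza_kind = None
            return
        fields = dict.fromkeys(["id", "name", "def"])
        synonyms: List[str] = []
        properties: List[str] = []
        parents: List[str] = []
        relations: dict[str, List[str]] = {}
        instances: List[str] = []
        annotations: List[Tuple[str, str]] = []
        for tag, value in stanza_lines:
            if tag == "id":
                fields["id"] = _strip_comment(value)
            elif tag == "name":
                fields["name"] = _strip_comment(value)
            elif tag == "synonym":
                synonyms.append(_quoted_payload(value, tag, f"#{stanza_no}"))
            elif tag == "def":
                fields["def"] = _quoted_payload(value, tag, f"#{stanza_no}")
            elif tag == "property":
                properties.append(_strip_comment(value))
            elif tag == "is_a":
                parents.append(_strip_comment(value))
            elif tag == "relationship":
                parts = _strip_comment(value).split()
                if len(parts) != 2:
                    raise FormatError(
                        f"stanza #{stanza_no}: relationship tag needs "
                        f"'<type> <target>', got {value!r}"
                    )
                relations.setdefault(parts[0], []).append(parts[1])
            elif tag == "instance":
                instances.append(_strip_comment(value))
            else:
                annotations.append((tag, value))
        if not fields["id"]:
            raise FormatError(f"[Term] stanza #{stanza_no} is missing an id tag")
        if not fields["name"]:
            raise FormatError(
                f"[Term] stanza #{stanza_no} ({fields['id']}) is missing a name tag"
            )
        concepts.append(
            Concept(
                id=fields["id"],
                name=fields["name"],
                synonyms=synonyms,
                definition=fields["def"],
                properties=properties,
                parents=parents,
                relations=relations,
                instances=instances,
                annotations=annotations,
            )
        )
        stanza_lines = []
        stanza_kind = None

    in_header = True
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            flush()
            stanza_kind = line[1:-1]
            stanza_no += 1
            in_header = False
            continue
        if ":" not in line:
            raise FormatError(f"malformed line (no tag separator): {raw!r}")
        tag, value = line.split(":", 1)
        tag, value = tag.strip(), value.strip()
        if in_header:
            if tag == "ontology":
                graph_name = value
            continue
        stanza_lines.append((tag, value))
    flush()

    graph = ConceptGraph(name=graph_name, concepts=concepts)
    graph.validate()
    return graph


def write_obo(graph: ConceptGraph) -> str:
    """Serialise a graph to OBO text: stanzas sorted by id, fixed tag order.

    Deterministic, and the output round-trips through :func:`read_obo`.
    """
    assert_dag(graph)
    out = _io.StringIO()
    out.write("format-version: 1.2\n")
    if graph.name:
        out.write(f"ontology: {graph.name}\n")
    for cid in graph.ids():
        c = graph[cid]
        out.write("\n[Term]\n")
        out.write(f"id: {c.id}\n")
        out.write(f"name: {c.name}\n")
        for syn in c.synonyms:
            escaped = syn.replace('"', '\\"')
            out.write(f'synonym: "{escaped}" EXACT []\n')
        if c.definition is not None:
            escaped = c.definition.replace('"', '\\"')
            out.write(f'def: "{escaped}" []\n')
        for prop in c.properties:
            out.write(f"property: {prop}\n")
        for parent in sorted(c.parents):
            out.write(f"is_a: {parent}\n")
        for rel in sorted(c.relations):
            for target in c.relations[rel]:
                out.write(f"relationship: {rel} {target}\n")
        for inst in c.instances:
            out.write(f"instance: {inst}\n")
        for tag, value in c.annotations:
            out.write(f"{tag}: {value}\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# Database-schema JSON
# ---------------------------------------------------------------------------

def read_schema(source: TextSource) -> ConceptGraph:
    """Map a JSON database-schema document onto the concept model.

    Each table becomes a concept named after the table; columns become
    properties; foreign keys become ``references`` relations; binding
    links become ``hasBinding`` relations.  The result has no ``is_a``
    edges, so it is trivially a DAG.
    """
    doc = json.loads(_as_text(source))
    tables = doc.get("tables", [])
    names = [t["name"] for t in tables]
    if len(set(names)) != len(names):
        raise FormatError("table names must be unique")
    known = set(names)
    concepts = []
    for t in tables:
        relations: dict[str, List[str]] = {}
        for fk in t.get("foreign_keys", []):
            _column, target = fk
            if target not in known:
                raise UnknownConceptError(
                    f"table {t['name']!r}: foreign key target {target!r} "
                    "does not resolve"
                )
            relations.setdefault("references", []).append(target)
        for link in t.get("binding_links", []):
            target = link[-1] if isinstance(link, (list, tuple)) else link
            if target not in known:
                raise UnknownConceptError(
                    f"table {t['name']!r}: binding link target {target!r} "
                    "does not resolve"
                )
            relations.setdefault("hasBinding", []).append(target)
        concepts.append(
            Concept(
                id=t["name"],
                name=t["name"],
                properties=list(t.get("columns", [])),
                relations=relations,
            )
        )
    graph = ConceptGraph(name=doc.get("name", ""), concepts=concepts)
    graph.validate()
    return graph


# ---------------------------------------------------------------------------
# TSV formats
# ---------------------------------------------------------------------------

def _data_lines(text: str) -> Iterable[Tuple[int, str]]:
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        yield lineno, line


def read_pairs(source: TextSource) -> List[Tuple[str, str]]:
    """Read expert-declared equivalent concept-id pairs from two-column TSV.

    Lines starting with ``#`` are comments.  Duplicate pairs (in either
    orientation) are rejected.
    """
    pairs: List[Tuple[str, str]] = []
    seen: set[frozenset] = set()
    for lineno, line in _data_lines(_as_text(source)):
        cols = line.split("\t")
        if len(cols) != 2 or not all(cols):
            raise FormatError(
                f"line {lineno}: expected two tab-separated ids, got {line!r}"
            )
        key = frozenset(cols)
        if key in seen:
            raise FormatError(f"line {lineno}: duplicate pair {tuple(cols)}")
        seen.add(key)
        pairs.append((cols[0], cols[1]))
    return pairs


def read_lexicon(source: TextSource) -> SynonymLexicon:
    """Read a synonym lexicon: one synset per line, members tab-separated."""
    synsets = []
    for _lineno, line in _data_lines(_as_text(source)):
        members = [m for m in line.split("\t") if m]
        if len(members) >= 2:
            synsets.append(members)
    return SynonymLexicon(synsets)


def read_alignment(source: TextSource) -> Alignment:
    """Read a three-column alignment TSV (source, target, similarity)."""
    pairs = []
    for lineno, line in _data_lines(_as_text(source)):
        cols = line.split("\t")
        if len(cols) != 3:
            raise FormatError(
                f"line {lineno}: expected 'source<TAB>target<TAB>similarity', "
                f"got {line!r}"
            )
        try:
            sim = float(cols[2])
        except ValueError:
            raise FormatError(f"line {lineno}: bad similarity {cols[2]!r}") from None
        pairs.append(AlignedPair(cols[0], cols[1], sim))
    return Alignment(pairs=pairs)


def write_alignment(alignment: Alignment) -> str:
    """Serialise an alignment as TSV with similarities to 4 decimal places."""
    lines = ["#source_id\ttarget_id\tsimilarity"]
    for p in alignment.pairs:
        lines.append(f"{p.source}\t{p.target}\t{p.similarity:.4f}")
    return "\n".join(lines) + "\n"


def write_weights(weights: WeightVector) -> str:
    """Learned weights as JSON."""
    return json.dumps(
        {"w1": weights.w1, "w2": weights.w2, "w3": weights.w3, "w4": weights.w4},
        indent=2,
    ) + "\n"


def write_trace(trace) -> str:
    """Learning trace as CSV: iteration, w1..w4, E."""
    out = _io.StringIO()
    writer = csv.writer(out)
    writer.writerow(["iteration", "w1", "w2", "w3", "w4", "E"])
    for row in trace.to_rows():
        writer.writerow(row)
    return out.getvalue()
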