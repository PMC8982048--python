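"""OBO ontology parsing and DAG queries.

Ontologies are directed acyclic graphs of terms connected by typed
subsumption relations.  Annotations obey the true-path rule: a gene
annotated to a term is implicitly annotated to every ancestor, so
enrichment needs fast ancestor-closure queries.  Ontologies also churn:
terms are created, merged (``alt_id``) and obsoleted (``replaced_by``)
regularly, and input identifiers must be mapped through that
bookkeeping before any counting happens.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import IO, Iterable

import networkx as nx

from .errors import ObsoleteTermError, ParseError, TermNotFoundError, ValidationError

#: Relation labels whose edges participate in the ancestor closure by default.
DEFAULT_CLOSURE_RELATIONS = frozenset({"is_a", "part_of"})

_TERM_ID_RE = re.compile(r"^([A-Za-z][A-Za-z0-9_.\-]*):(\S+)$")


def normalize_term_id(value: str) -> str:
    """Canonicalize a CURIE term id.

    The prefix is case-insensitive (``go:0005783`` == ``GO:0005783``)
    and is stored upper-case; the local id is case-sensitive and kept
    verbatim.
    """
    m = _TERM_ID_RE.match(value.strip())
    if not m:
        raise ValidationError(f"not a valid term id (expected PREFIX:ID): {value!r}")
    prefix, local = m.groups()
    return f"{prefix.upper()}:{local}"


@dataclass
class OntologyTerm:
    """One ontology term with its subsumption edges and bookkeeping."""

    id: str
    name: str = ""
    namespace: str = ""
    parents: list[tuple[str, str]] = field(default_factory=list)  # (parent_id, relation)
    alt_ids: set[str] = field(default_factory=set)
    obsolete: bool = False
    replaced_by: str | None = None


class OntologyGraph:
    """Terms plus the acyclic closure graph over selected relations.

    Parameters
    ----------
    terms
        Parsed terms, including obsolete ones (kept for ``replaced_by``
        chains; they contribute no closure edges).
    relations_for_closure
        Relation labels whose edges define the ancestor closure.
        Defaults to ``{is_a, part_of}``.
    """

    def __init__(
        self,
        terms: Iterable[OntologyTerm],
        relations_for_closure: Iterable[str] = DEFAULT_CLOSURE_RELATIONS,
    ):
        self.relations_for_closure = frozenset(relations_for_closure)
        self.terms: dict[str, OntologyTerm] = {}
        self._alt_index: dict[str, str] = {}
        for term in terms:
            if term.id in self.terms:
                raise ValidationError(f"duplicate term id {term.id}")
            self.terms[term.id] = term
        for term in self.terms.values():
            for alt in term.alt_ids:
                if alt in self.terms:
                    raise ValidationError(f"alt_id {alt} collides with a primary id")
                if alt in self._alt_index and self._alt_index[alt] != term.id:
                    raise ValidationError(f"alt_id {alt} claimed by two terms")
                self._alt_index[alt] = term.id
        self._closure = nx.DiGraph()  # edges child -> parent
        self._closure.add_nodes_from(t.id for t in self.terms.values() if not t.obsolete)
        for term in self.terms.values():
            if term.obsolete:
                continue  # obsolete terms carry no subsumption edges
            for parent_id, relation in term.parents:
                if parent_id not in self.terms:
                    raise ValidationError(
                        f"term {term.id} references unknown parent {parent_id}"
                    )
                if relation in self.relations_for_closure:
                    self._closure.add_edge(term.id, parent_id, relation=relation)
        if not nx.is_directed_acyclic_graph(self._closure):
            cycle = nx.find_cycle(self._closure)
            path = " -> ".join(edge[0] for edge in cycle) + f" -> {cycle[-1][1]}"
            raise ValidationError(f"cycle among closure relations: {path}")

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    @property
    def namespaces(self) -> set[str]:
        return {t.namespace for t in self.terms.values() if t.namespace}

    def resolve_term(self, term_id: str) -> str:
        """Map any known id (primary, alt, obsolete) to a live primary id.

        Obsolete terms are followed through ``replaced_by`` chains, with
        the walk bounded by the graph size to guard against a malformed
        replacement cycle.

        Raises
        ------
        TermNotFoundError
            If the id is unknown.
        ObsoleteTermError
            If an obsolete term has no replacement.
        """
        tid = normalize_term_id(term_id)
        if tid in self._alt_index:
            tid = self._alt_index[tid]
        if tid not in self.terms:
            raise TermNotFoundError(f"unknown term id {term_id!r}")
        hops = 0
        while self.terms[tid].obsolete:
            replacement = self.terms[tid].replaced_by
            if replacement is None:
                raise ObsoleteTermError(f"term {tid} is obsolete with no replacement")
            if replacement in self._alt_index:
                replacement = self._alt_index[replacement]
            if replacement not in self.terms:
                raise TermNotFoundError(
                    f"replaced_by target {replacement!r} of {tid} is unknown"
                )
            tid = replacement
            hops += 1
            if hops > len(self.terms):
                raise ValidationError(f"replaced_by chain from {term_id!r} does not terminate")
        return tid

    def ancestors(self, term_id: str) -> set[str]:
        """All terms reachable from ``term_id`` via closure relations, excluding itself."""
        tid = self.resolve_term(term_id)
        return set(nx.descendants(self._closure, tid))

    def children(self, term_id: str) -> set[str]:
        tid = self.resolve_term(term_id)
        return {c for c, _ in self._closure.in_edges(tid)}

    def leaves(self) -> set[str]:
        """Non-obsolete terms with no closure children."""
        return {n for n in self._closure.nodes if self._closure.in_degree(n) == 0}

    def closure_edges(self) -> list[tuple[str, str, str]]:
        """(child, relation, parent) triples restricted to closure relations."""
        return sorted(
            (c, data["relation"], p) for c, p, data in self._closure.edges(data=True)
        )

    def subgraph(self, namespace: str) -> "OntologyGraph":
        """Restrict to one namespace (e.g. a single GO aspect)."""
        kept = [t for t in self.terms.values() if t.namespace == namespace]
        keep_ids = {t.id for t in kept}
        clipped = []
        for t in kept:
            c = OntologyTerm(
                id=t.id,
                name=t.name,
                namespace=t.namespace,
                parents=[(p, r) for p, r in t.parents if p in keep_ids],
                alt_ids=set(t.alt_ids),
                obsolete=t.obsolete,
                replaced_by=t.replaced_by if t.replaced_by in keep_ids else None,
            )
            clipped.append(c)
        return OntologyGraph(clipped, self.relations_for_closure)

    def to_edge_tsv(self) -> str:
        """Edge-list export for debugging: child_id, relation, parent_id."""
        lines = ["child_id\trelation\tparent_id"]
        lines += [f"{c}\t{r}\t{p}" for c, r, p in self.closure_edges()]
        return "\n".join(lines) + "\n"


def _iter_lines(stream: str | IO[str]) -> Iterable[str]:
    if isinstance(stream, str):
        return stream.splitlines()
    return (line.rstrip("\n") for line in stream)


def parse_obo(
    stream: str | IO[str],
    relations_for_closure: Iterable[str] = DEFAULT_CLOSURE_RELATIONS,
) -> OntologyGraph:
    """Parse OBO 1.2/1.4 flat-file text into an :class:`OntologyGraph`.

    Handles ``[Term]`` stanzas only; other stanza types (``[Typedef]``,
    ``[Instance]``) are skipped.  Captured tags: ``id``, ``name``,
    ``namespace``, ``is_a``, ``relationship``, ``alt_id``,
    ``is_obsolete``, ``replaced_by``.  ``intersection_of`` lines are
    logical definitions, not subsumption edges, and are ignored.

    Raises
    ------
    ParseError
        On a malformed stanza, with the offending line number.
    ValidationError
        If the closure-relation edge set contains a cycle.
    """
    terms: list[OntologyTerm] = []
    current: OntologyTerm | None = None
    in_term_stanza = False

    def flush():
        nonlocal current
        if current is not None:
            terms.append(current)
            current = None

    for lineno, raw in enumerate(_iter_lines(stream), start=1):
        line = raw.split("!")[0].strip() if not raw.lstrip().startswith("!") else ""
        if not line:
            continue
        if line.startswith("["):
            flush()
            in_term_stanza = line == "[Term]"
            if in_term_stanza:
                current = OntologyTerm(id="")
            continue
        if not in_term_stanza:
            continue  # header or non-Term stanza
        if ":" not in line:
            raise ParseError(f"expected 'tag: value', got {line!r}", line=lineno)
        tag, _, value = line.partition(":")
        tag = tag.strip()
        value = value.strip()
        assert current is not None
        try:
            if tag == "id":
                current.id = normalize_term_id(value)
            elif tag == "name":
                current.name = value
            elif tag == "namespace":
                current.namespace = value
            elif tag == "is_a":
                current.parents.append((normalize_term_id(value.split()[0]), "is_a"))
            elif tag == "relationship":
                parts = value.split()
                if len(parts) < 2:
                    raise ParseError(f"relationship needs 'relation target': {value!r}", line=lineno)
                current.parents.append((normalize_term_id(parts[1]), parts[0]))
            elif tag == "alt_id":
                current.alt_ids.add(normalize_term_id(value))
            elif tag == "is_obsolete":
                current.obsolete = value.lower() == "true"
            elif tag == "replaced_by":
                current.replaced_by = normalize_term_id(value)
            # other tags (def, synonym, xref, intersection_of, ...) ignored
        except ValidationError as exc:
            raise ParseError(str(exc), line=lineno) from exc
    flush()

    for term in terms:
        if not term.id:
            raise ParseError("[Term] stanza without an id tag")
        if term.obsolete:
            term.parents = []  # obsolete terms never feed propagation
    return OntologyGraph(terms, relations_for_closure)


def serialize_obo(graph: OntologyGraph) -> str:
    """Write the graph back out as minimal OBO text (round-trip aid)."""
    chunks = ["format-version: 1.2", ""]
    for tid in sorted(graph.terms):
        term = graph.terms[tid]
        lines = ["[Term]", f"id: {term.id}"]
        if term.name:
            lines.append(f"name: {term.name}")
        if term.namespace:
            lines.append(f"namespace: {term.namespace}")
        for alt in sorted(term.alt_ids):
            lines.append(f"alt_id: {alt}")
        for parent, relation in term.parents:
            if relation == "is_a":
                lines.append(f"is_a: {parent}")
            else:
                lines.append(f"relationship: {relation} {parent}")
        if term.obsolete:
            lines.append("is_obsolete: true")
        if term.replaced_by:
            lines.append(f"replaced_by: {term.replaced_by}")
        chunks.append("\n".join(lines))
        chunks.append("")
    return "\n".join(chunks)
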