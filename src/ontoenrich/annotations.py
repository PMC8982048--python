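"""Annotation reading, filtering and true-path-rule propagation.

An annotation corpus for one (species, ontology) pair defines the
reference universe of an enrichment run: every gene of that species
with at least one surviving annotation in that ontology.  Annotations
are propagated up the DAG before counting, so a term's gene count
includes genes annotated to any of its descendants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable

from .errors import ObsoleteTermError, ParseError, TermNotFoundError
from .ontology import OntologyGraph

logger = logging.getLogger(__name__)

#: Column order of the simple annotation TSV dialect (with header row).
TSV_COLUMNS = ("gene", "species", "term", "evidence", "qualifier")


@dataclass(frozen=True)
class AnnotationRecord:
    """One gene-to-term assertion with its provenance."""

    gene: str
    species: str
    term: str
    evidence: str
    qualifiers: frozenset[str] = frozenset()
    source: str = ""


@dataclass
class AnnotationCorpus:
    """Per-(species, ontology) annotation index after propagation.

    ``universe`` is the reference set: every gene with >= 1 annotation
    in this corpus.  ``n_terms_annotated`` is the Bonferroni multiplier
    T under the reference scope: the number of terms with >= 1
    annotated universe gene after propagation.
    """

    species: str
    ontology_key: str
    direct: dict[str, set[str]] = field(default_factory=dict)  # gene -> direct terms
    propagated_term_index: dict[str, set[str]] = field(default_factory=dict)  # term -> genes
    universe: set[str] = field(default_factory=set)
    n_terms_annotated: int = 0
    n_unresolvable_skipped: int = 0

    def flatten_direct(self) -> list[AnnotationRecord]:
        """Direct annotations as records (used to check rebuild idempotence)."""
        return [
            AnnotationRecord(gene=g, species=self.species, term=t, evidence="IEA")
            for g in sorted(self.direct)
            for t in sorted(self.direct[g])
        ]

    def dump_tsv(self) -> str:
        """Debug dump: term_id, n_genes, comma-joined gene ids."""
        lines = ["term_id\tn_genes\tgenes"]
        for term in sorted(self.propagated_term_index):
            genes = sorted(self.propagated_term_index[term])
            lines.append(f"{term}\t{len(genes)}\t{','.join(genes)}")
        return "\n".join(lines) + "\n"


def _lines(stream: str | IO[str]) -> Iterable[str]:
    if isinstance(stream, str):
        return stream.splitlines()
    return (line.rstrip("\n") for line in stream)


def _read_gaf(stream: str | IO[str]) -> list[AnnotationRecord]:
    # GAF 2.1: 17 columns; GAF 2.2 identical width. 1-based columns used:
    # 2 = DB object id, 4 = qualifier (pipe-separated), 5 = term,
    # 7 = evidence code, 13 = taxon, 15 = assigned-by.
    records = []
    for lineno, line in enumerate(_lines(stream), start=1):
        if not line.strip() or line.startswith("!"):
            continue
        cols = line.split("\t")
        if len(cols) < 15:
            raise ParseError(
                f"GAF line has {len(cols)} columns, expected >= 15", line=lineno
            )
        qualifiers = frozenset(q for q in cols[3].split("|") if q)
        taxon = cols[12].split("|")[0].strip()
        records.append(
            AnnotationRecord(
                gene=cols[1].strip(),
                species=taxon,
                term=cols[4].strip(),
                evidence=cols[6].strip(),
                qualifiers=qualifiers,
                source=cols[14].strip() if len(cols) > 14 else "",
            )
        )
    return records


def _read_tsv(stream: str | IO[str]) -> list[AnnotationRecord]:
    records = []
    header: list[str] | None = None
    for lineno, line in enumerate(_lines(stream), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if header is None:
            header = [c.strip().lower() for c in cols]
            missing = [c for c in TSV_COLUMNS if c not in header]
            if missing:
                raise ParseError(f"missing column(s) {missing} in header", line=lineno)
            continue
        if len(cols) != len(header):
            raise ParseError(
                f"expected {len(header)} columns, got {len(cols)}", line=lineno
            )
        row = dict(zip(header, (c.strip() for c in cols)))
        qualifiers = frozenset(q for q in row["qualifier"].split("|") if q)
        records.append(
            AnnotationRecord(
                gene=row["gene"],
                species=row["species"],
                term=row["term"],
                evidence=row["evidence"],
                qualifiers=qualifiers,
                source=row.get("source", ""),
            )
        )
    return records


def read_annotations(stream: str | IO[str], format: str = "tsv") -> list[AnnotationRecord]:
    """Read annotation records from GAF 2.x or the simple TSV dialect.

    Comment lines (``!`` for GAF, ``#`` for TSV) are skipped; line order
    is preserved; an empty file yields an empty list.
    """
    if format == "gaf":
        return _read_gaf(stream)
    if format == "tsv":
        return _read_tsv(stream)
    raise ValueError(f"unknown annotation format {format!r} (expected 'gaf' or 'tsv')")


def build_corpus(
    records: Iterable[AnnotationRecord],
    graph: OntologyGraph,
    species: str,
    ontology_key: str,
    evidence_exclude: Iterable[str] = (),
    namespace: str | None = None,
) -> AnnotationCorpus:
    """Filter records and build the propagated per-term gene index.

    Filtering drops, in order: records of other species, NOT-qualified
    records (a NOT annotation asserts absence of function and must not
    count as positive evidence), and records with an excluded evidence
    code.  Term ids are resolved through alt_id/replaced_by bookkeeping;
    unresolvable terms skip the record with a counted warning.  Every
    surviving (gene, term) pair is propagated to all ancestors of the
    term.  Duplicate pairs collapse (set semantics).
    """
    excluded = {e.upper() for e in evidence_exclude}
    corpus = AnnotationCorpus(species=species, ontology_key=ontology_key)
    keep_ns = None
    if namespace is not None:
        keep_ns = {t.id for t in graph.terms.values() if t.namespace == namespace}

    ancestor_cache: dict[str, set[str]] = {}
    for rec in records:
        if rec.species != species:
            continue
        if "NOT" in rec.qualifiers:
            continue
        if rec.evidence.upper() in excluded:
            continue
        try:
            term = graph.resolve_term(rec.term)
        except (TermNotFoundError, ObsoleteTermError):
            corpus.n_unresolvable_skipped += 1
            continue
        if keep_ns is not None and term not in keep_ns:
            continue
        corpus.direct.setdefault(rec.gene, set()).add(term)
        if term not in ancestor_cache:
            anc = graph.ancestors(term)
            if keep_ns is not None:
                anc &= keep_ns
            ancestor_cache[term] = anc
        for t in ancestor_cache[term] | {term}:
            corpus.propagated_term_index.setdefault(t, set()).add(rec.gene)

    if corpus.n_unresolvable_skipped:
        logger.warning(
            "%d annotation record(s) skipped: unresolvable term ids",
            corpus.n_unresolvable_skipped,
        )
    corpus.universe = set().union(*corpus.propagated_term_index.values()) if corpus.propagated_term_index else set()
    corpus.n_terms_annotated = len(corpus.propagated_term_index)
    return corpus


def term_gene_count(corpus: AnnotationCorpus, term: str) -> int:
    """Number of universe genes annotated (after propagation) to ``term``; 0 if absent."""
    return len(corpus.propagated_term_index.get(term, ()))
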