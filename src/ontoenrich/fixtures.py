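"""Seeded synthetic ontologies, corpora and gene lists.

Everything the other modules consume can be generated here without any
download: a rooted random DAG serialized as OBO, a direct-annotation
TSV, a gene table with aliases and coordinates, and a 1:1 ortholog
table to a second synthetic species.  Null and spiked input gene sets
drive the statistical checks: under null sampling the nominal P-values
must be super-uniform (the discrete test is conservative), and a
sufficiently strong spike must put the spiked term at the top of the
ranking.

Randomness is reproducible: one integer seed is split into independent
streams by component label, so e.g. the ontology can be regenerated
without consuming the annotation stream.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from math import ceil

import numpy as np

from .annotations import AnnotationCorpus
from .errors import DomainError

SPECIES_A = "synthrat"
SPECIES_B = "synthmouse"
ASSEMBLY = "synthAsm1.0"
ONTOLOGY_PREFIX = "SYN"


@dataclass(frozen=True)
class SpikeSpec:
    """Planted enrichment signal for power checks."""

    term: str
    n_input: int
    fraction_from_term: float

    def __post_init__(self):
        if not 0.0 <= self.fraction_from_term <= 1.0:
            raise DomainError("fraction_from_term must be in [0, 1]")
        if self.n_input < 1:
            raise DomainError("n_input must be >= 1")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset.

    ``annotation_density`` is the expected number of direct annotations
    per gene (Poisson, floored at 1 so every gene enters the universe).
    """

    seed: int
    n_terms: int = 50
    branching: float = 3.0
    n_genes: int = 200
    annotation_density: float = 3.0
    spike: SpikeSpec | None = None

    def __post_init__(self):
        if self.n_terms < 1 or self.n_genes < 1:
            raise DomainError("n_terms and n_genes must be >= 1")
        if self.annotation_density <= 0:
            raise DomainError("annotation_density must be > 0")


@dataclass(frozen=True)
class FixtureBundle:
    """The four text artifacts of one generated dataset."""

    obo_text: str
    annotation_tsv: str
    gene_table_tsv: str
    ortholog_tsv: str


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Independent generator for one named stream of a global seed."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(stream.encode())]))


def _term_id(i: int) -> str:
    return f"{ONTOLOGY_PREFIX}:{i:07d}"


def _gene_id(i: int) -> str:
    return f"SGENE{i + 1:05d}"


def generate_fixture(spec: FixtureSpec) -> FixtureBundle:
    """Generate a complete synthetic dataset for one seed.

    The ontology is a rooted DAG built in topological order: term 0 is
    the root and every later term picks 1–2 parents uniformly among
    earlier terms, which guarantees acyclicity by construction.  Each
    gene receives ``max(1, Poisson(density))`` direct annotations to
    uniformly chosen terms.  The gene table carries three alias types
    per gene (NCBI_GENE, ENSEMBL, SYMBOL) and coordinates on one
    synthetic assembly; the ortholog table maps every gene 1:1 to a
    second synthetic species.  Same seed, same bytes.
    """
    dag_rng = _rng(spec.seed, "ontology")
    annot_rng = _rng(spec.seed, "annotations")
    coord_rng = _rng(spec.seed, "coordinates")

    # --- ontology ---
    parents: dict[int, list[int]] = {0: []}
    for i in range(1, spec.n_terms):
        n_parents = int(dag_rng.integers(1, 3))  # 1 or 2
        choices = dag_rng.choice(i, size=min(n_parents, i), replace=False)
        parents[i] = sorted(int(c) for c in choices)

    obo_lines = ["format-version: 1.2", f"ontology: {ONTOLOGY_PREFIX.lower()}", ""]
    for i in range(spec.n_terms):
        obo_lines.append("[Term]")
        obo_lines.append(f"id: {_term_id(i)}")
        obo_lines.append(f"name: synthetic term {i}")
        obo_lines.append("namespace: synthetic_process")
        for p in parents[i]:
            obo_lines.append(f"is_a: {_term_id(p)}")
        obo_lines.append("")
    obo_text = "\n".join(obo_lines)

    # --- direct annotations ---
    annot_lines = ["gene\tspecies\tterm\tevidence\tqualifier"]
    for g in range(spec.n_genes):
        n_annot = max(1, int(annot_rng.poisson(spec.annotation_density)))
        terms = annot_rng.integers(0, spec.n_terms, size=n_annot)
        for t in sorted(set(int(x) for x in terms)):
            annot_lines.append(f"{_gene_id(g)}\t{SPECIES_A}\t{_term_id(t)}\tIDA\t")
    annotation_tsv = "\n".join(annot_lines) + "\n"

    # --- gene table with aliases and coordinates ---
    gene_lines = ["canonical_id\tsymbol\tspecies\taliases\tassembly\tchrom\tstart\tend"]
    starts = coord_rng.integers(1, 10_000_000, size=spec.n_genes)
    lengths = coord_rng.integers(500, 50_000, size=spec.n_genes)
    chroms = coord_rng.integers(1, 6, size=spec.n_genes)  # chr1..chr5
    for g in range(spec.n_genes):
        cid = _gene_id(g)
        symbol = f"Sg{g + 1}"
        aliases = f"NCBI_GENE:{100000 + g};ENSEMBL:ENSSYNG{g + 1:011d};SYMBOL:{symbol}"
        start = int(starts[g])
        end = start + int(lengths[g])
        gene_lines.append(
            f"{cid}\t{symbol}\t{SPECIES_A}\t{aliases}\t{ASSEMBLY}\tchr{int(chroms[g])}\t{start}\t{end}"
        )
    gene_table_tsv = "\n".join(gene_lines) + "\n"

    # --- 1:1 orthologs to the second species ---
    orth_lines = ["species_a\tgene_a\tspecies_b\tgene_b"]
    for g in range(spec.n_genes):
        orth_lines.append(f"{SPECIES_A}\t{_gene_id(g)}\t{SPECIES_B}\tMG{g + 1:05d}")
    ortholog_tsv = "\n".join(orth_lines) + "\n"

    return FixtureBundle(
        obo_text=obo_text,
        annotation_tsv=annotation_tsv,
        gene_table_tsv=gene_table_tsv,
        ortholog_tsv=ortholog_tsv,
    )


def sample_input_set(
    spec: FixtureSpec,
    corpus: AnnotationCorpus,
    seed: int,
    n_input: int | None = None,
) -> list[str]:
    """Draw an input gene list from a corpus, null or spiked.

    Null mode (``spec.spike is None``): a uniform sample without
    replacement of ``n_input`` genes from the universe.  Spike mode:
    ``ceil(fraction_from_term * n_input)`` genes come from the spiked
    term's propagated gene set, the remainder uniformly from the rest of
    the universe.  Deterministic per ``seed``; a zero spike fraction
    reproduces the null draw for the same seed.
    """
    if not corpus.universe:
        raise DomainError("corpus universe is empty")
    spike = spec.spike
    if n_input is None:
        n_input = spike.n_input if spike is not None else min(10, len(corpus.universe))
    if n_input > len(corpus.universe):
        raise DomainError(
            f"n_input {n_input} exceeds universe size {len(corpus.universe)}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(b"input-set")]))
    universe = sorted(corpus.universe)

    n_spiked = 0
    picked: list[str] = []
    if spike is not None and spike.fraction_from_term > 0:
        term_genes = sorted(corpus.propagated_term_index.get(spike.term, set()))
        if not term_genes:
            raise DomainError(f"spiked term {spike.term} has no genes in the corpus")
        n_spiked = min(ceil(spike.fraction_from_term * n_input), n_input, len(term_genes))
        picked = list(rng.choice(term_genes, size=n_spiked, replace=False))
    rest = [g for g in universe if g not in set(picked)]
    n_rest = n_input - n_spiked
    if n_rest > 0:
        picked += list(rng.choice(rest, size=n_rest, replace=False))
    return [str(g) for g in picked]
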