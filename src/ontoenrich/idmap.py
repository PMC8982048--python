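"""Identifier resolution, ortholog mapping and region-to-gene queries.

Input gene lists arrive under heterogeneous identifier types (NCBI gene
ids, Ensembl, UniProt, symbols, ...).  Everything downstream of this
module works on canonical per-species gene ids, so corpora never store
aliases.  Coordinates are 1-based inclusive (genome-browser
convention); BED input (0-based half-open) is converted at the reader
boundary.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import IO, Iterable

from .errors import AssemblyMismatchError, ParseError, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneLocation:
    assembly: str
    chrom: str
    start: int  # 1-based inclusive
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValidationError(f"location start {self.start} > end {self.end}")


@dataclass
class GeneRecord:
    """Canonical gene with aliases and an optional genomic location."""

    canonical_id: str
    symbol: str
    species: str
    aliases: set[tuple[str, str]] = field(default_factory=set)  # (id_type, value)
    location: GeneLocation | None = None


@dataclass
class RegionQuery:
    """1-based inclusive genomic interval on a named assembly."""

    assembly: str
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 1:
            raise ValidationError(f"region start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise ValidationError(f"region start {self.start} > end {self.end}")


_REGION_RE = re.compile(r"^(\S+):([\d,]+)-([\d,]+)$")


def parse_region(region: str, assembly: str) -> RegionQuery:
    """Parse ``chrom:start-end`` (commas in numbers tolerated)."""
    m = _REGION_RE.match(region.strip())
    if not m:
        raise ParseError(f"region must look like chrom:start-end, got {region!r}")
    chrom, start, end = m.groups()
    return RegionQuery(
        assembly=assembly,
        chrom=chrom,
        start=int(start.replace(",", "")),
        end=int(end.replace(",", "")),
    )


class OrthologTable:
    """Symmetric cross-species gene pairing.

    Stored pairs are looked up in both directions: inserting
    (rat, g1, human, h1) makes h1 an ortholog of g1 and vice versa.
    """

    def __init__(self, pairs: Iterable[tuple[str, str, str, str]] = ()):
        self._index: dict[tuple[str, str, str], list[str]] = {}
        self._seen: set[tuple[str, str, str, str]] = set()
        for species_a, gene_a, species_b, gene_b in pairs:
            self.add(species_a, gene_a, species_b, gene_b)

    def add(self, species_a: str, gene_a: str, species_b: str, gene_b: str) -> None:
        for sa, ga, sb, gb in (
            (species_a, gene_a, species_b, gene_b),
            (species_b, gene_b, species_a, gene_a),
        ):
            if (sa, ga, sb, gb) in self._seen:
                continue
            self._seen.add((sa, ga, sb, gb))
            self._index.setdefault((sa, ga, sb), []).append(gb)

    def orthologs(self, gene: str, from_species: str, to_species: str) -> list[str]:
        return list(self._index.get((from_species, gene, to_species), []))


def read_ortholog_table(stream: str | IO[str]) -> OrthologTable:
    """Read the ortholog TSV: species_a, gene_a, species_b, gene_b (header optional)."""
    table = OrthologTable()
    for lineno, line in enumerate(_lines(stream), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = [c.strip() for c in line.split("\t")]
        if len(cols) != 4:
            raise ParseError(f"expected 4 columns, got {len(cols)}", line=lineno)
        if lineno == 1 and cols[0].lower() == "species_a":
            continue
        table.add(*cols)
    return table


def _lines(stream: str | IO[str]) -> Iterable[str]:
    if isinstance(stream, str):
        return stream.splitlines()
    return (line.rstrip("\n") for line in stream)


def read_gene_table(stream: str | IO[str]) -> list[GeneRecord]:
    """Read the gene table TSV.

    Columns: canonical_id, symbol, species, aliases (semicolon-joined
    ``type:value``), assembly, chrom, start, end.  Location columns may
    be empty.  A header row with ``canonical_id`` first is skipped.
    """
    records = []
    for lineno, line in enumerate(_lines(stream), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = [c.strip() for c in line.split("\t")]
        if len(cols) != 8:
            raise ParseError(f"expected 8 columns, got {len(cols)}", line=lineno)
        if cols[0].lower() == "canonical_id":
            continue
        aliases = set()
        if cols[3]:
            for chunk in cols[3].split(";"):
                if not chunk:
                    continue
                if ":" not in chunk:
                    raise ParseError(f"alias {chunk!r} is not type:value", line=lineno)
                id_type, _, value = chunk.partition(":")
                aliases.add((id_type, value))
        location = None
        if cols[4] and cols[5] and cols[6] and cols[7]:
            location = GeneLocation(cols[4], cols[5], int(cols[6]), int(cols[7]))
        records.append(
            GeneRecord(
                canonical_id=cols[0],
                symbol=cols[1],
                species=cols[2],
                aliases=aliases,
                location=location,
            )
        )
    return records


def read_bed(stream: str | IO[str], assembly: str) -> dict[str, GeneLocation]:
    """Read BED (>= 4 columns: chrom, start, end, name) into 1-based locations.

    BED is 0-based half-open; conversion to 1-based inclusive adds 1 to
    the start only.
    """
    out: dict[str, GeneLocation] = {}
    for lineno, line in enumerate(_lines(stream), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        cols = line.split("\t")
        if len(cols) < 4:
            raise ParseError(f"BED needs >= 4 columns, got {len(cols)}", line=lineno)
        out[cols[3].strip()] = GeneLocation(
            assembly=assembly, chrom=cols[0].strip(), start=int(cols[1]) + 1, end=int(cols[2])
        )
    return out


def resolve_gene_ids(
    raw_ids: Iterable[str],
    table: Iterable[GeneRecord],
    species: str,
) -> tuple[list[str], list[str]]:
    """Map raw identifiers to canonical ids for one species.

    Matching order per raw id: exact canonical id, then exact alias
    value of any id type, then case-insensitive symbol.  Two raw ids
    hitting the same gene collapse to one entry (first occurrence kept).
    A symbol matching more than one gene is ambiguous and is reported
    unresolved rather than guessed — a silent mis-mapping would corrupt
    both the universe size and the input overlap.

    Returns
    -------
    (resolved, unresolved)
        ``resolved`` is an ordered, de-duplicated list of canonical
        ids; ``unresolved`` preserves the unmatched raw strings in
        input order.
    """
    genes = [g for g in table if g.species == species]
    canonical = {g.canonical_id: g.canonical_id for g in genes}
    alias_index: dict[str, set[str]] = {}
    symbol_index: dict[str, set[str]] = {}
    for g in genes:
        for _, value in g.aliases:
            alias_index.setdefault(value, set()).add(g.canonical_id)
        symbol_index.setdefault(g.symbol.lower(), set()).add(g.canonical_id)

    resolved: list[str] = []
    seen: set[str] = set()
    unresolved: list[str] = []
    for raw in raw_ids:
        raw = raw.strip()
        if not raw:
            continue
        hit: str | None = None
        if raw in canonical:
            hit = raw
        elif raw in alias_index:
            targets = alias_index[raw]
            if len(targets) == 1:
                hit = next(iter(targets))
            else:
                logger.warning("alias %r is ambiguous (%d genes)", raw, len(targets))
        elif raw.lower() in symbol_index:
            targets = symbol_index[raw.lower()]
            if len(targets) == 1:
                hit = next(iter(targets))
            else:
                logger.warning("symbol %r is ambiguous (%d genes)", raw, len(targets))
        if hit is None:
            unresolved.append(raw)
        elif hit in seen:
            logger.info("input ids collapse onto gene %s", hit)
        else:
            seen.add(hit)
            resolved.append(hit)
    return resolved, unresolved


def map_orthologs(
    genes: Iterable[str],
    table: OrthologTable,
    from_species: str,
    to_species: str,
) -> tuple[list[str], list[str]]:
    """Translate canonical ids across species via the ortholog table.

    One-to-many orthology fans out (all targets kept); output is
    de-duplicated in first-seen order.  Identity mapping when the two
    species are equal.
    """
    genes = list(genes)
    if from_species == to_species:
        return list(dict.fromkeys(genes)), []
    mapped: list[str] = []
    seen: set[str] = set()
    unmapped: list[str] = []
    for gene in genes:
        targets = table.orthologs(gene, from_species, to_species)
        if not targets:
            unmapped.append(gene)
            continue
        for t in targets:
            if t not in seen:
                seen.add(t)
                mapped.append(t)
    return mapped, unmapped


def genes_in_region(query: RegionQuery, table: Iterable[GeneRecord]) -> list[str]:
    """Genes overlapping the query interval by >= 1 bp on the same chromosome.

    Intervals are 1-based inclusive; overlap (not containment)
    semantics.  Result sorted by start position, then canonical id.
    Strand is ignored.
    """
    hits = []
    table = list(table)
    assemblies = {g.location.assembly for g in table if g.location is not None}
    if assemblies and query.assembly not in assemblies:
        raise AssemblyMismatchError(
            f"query assembly {query.assembly!r} not among table assembly(ies) {sorted(assemblies)}"
        )
    for g in table:
        loc = g.location
        if loc is None or loc.assembly != query.assembly or loc.chrom != query.chrom:
            continue
        if loc.start <= query.end and query.start <= loc.end:
            hits.append((loc.start, g.canonical_id))
    return [cid for _, cid in sorted(hits)]
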