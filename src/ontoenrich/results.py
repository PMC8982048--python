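"""Ordering, filtering and serialization of enrichment output, plus
set-comparison utilities for putting several tools' term lists side by
side (Venn partitions of up to four ranked lists)."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import IO, Iterable, Mapping

from .enrichment import EnrichmentResult, EnrichmentRun

#: Exact TSV column order of the downloadable result table.
TSV_COLUMNS = (
    "term_id",
    "term_name",
    "input_annotated",
    "reference_annotated",
    "input_total",
    "reference_total",
    "p_value",
    "bonferroni_p",
    "odds_ratio",
)


@dataclass
class ResultTable:
    """Display-ready slice of an enrichment run."""

    rows: list[EnrichmentResult]
    cutoff: float
    sort_key: str = "p_nominal"


def sort_and_filter(
    run: EnrichmentRun,
    cutoff: float = 0.05,
    use_corrected: bool = True,
    top_n: int | None = None,
) -> ResultTable:
    """Keep rows at or below the P-value cutoff, sorted for display.

    The cutoff applies to the Bonferroni-corrected P-value by default
    (``use_corrected=False`` switches to the nominal one).  Rows are
    sorted by ascending nominal P-value with ties broken by ascending
    term id so output order is reproducible.
    """
    if not 0.0 < cutoff <= 1.0:
        raise ValueError(f"cutoff must be in (0, 1], got {cutoff}")
    kept = [
        r
        for r in run.results
        if (r.p_bonferroni if use_corrected else r.p_nominal) <= cutoff
    ]
    kept.sort(key=lambda r: (r.p_nominal, r.term))
    if top_n is not None:
        kept = kept[:top_n]
    return ResultTable(rows=kept, cutoff=cutoff)


def _format_or(value: float) -> str:
    if math.isinf(value):
        return "Inf"
    if math.isnan(value):
        return "NA"
    return repr(value)


def _row_fields(r: EnrichmentResult) -> list[str]:
    return [
        r.term,
        r.term_name,
        str(r.counts.k),
        str(r.counts.K),
        str(r.counts.n),
        str(r.counts.N),
        repr(r.p_nominal),
        repr(r.p_bonferroni),
        _format_or(r.odds_ratio),
    ]


def write_results(
    table: ResultTable,
    format: str,
    destination: IO[str],
    run: EnrichmentRun | None = None,
) -> None:
    """Serialize the table as TSV or JSON.

    TSV columns follow :data:`TSV_COLUMNS` exactly; floats are written
    with ``repr`` so a read-back parses bit-equal.  Infinite odds ratios
    appear as the string ``Inf`` in TSV and as ``null`` plus an
    ``odds_ratio_infinite`` flag in JSON.  JSON adds run metadata
    (species, ontology, n_tests) when ``run`` is given.
    """
    if format == "tsv":
        destination.write("\t".join(TSV_COLUMNS) + "\n")
        for r in table.rows:
            destination.write("\t".join(_row_fields(r)) + "\n")
    elif format == "json":
        rows = []
        for r in table.rows:
            infinite = math.isinf(r.odds_ratio)
            rows.append(
                {
                    "term_id": r.term,
                    "term_name": r.term_name,
                    "input_annotated": r.counts.k,
                    "reference_annotated": r.counts.K,
                    "input_total": r.counts.n,
                    "reference_total": r.counts.N,
                    "p_value": r.p_nominal,
                    "bonferroni_p": r.p_bonferroni,
                    "odds_ratio": None if infinite else r.odds_ratio,
                    "odds_ratio_infinite": infinite,
                }
            )
        doc: dict = {"cutoff": table.cutoff, "results": rows}
        if run is not None:
            doc["species"] = run.species
            doc["ontology"] = run.ontology_key
            doc["n_tests"] = run.n_tests
            doc["n_input_resolved"] = run.n_input_resolved
            doc["n_input_in_universe"] = run.n_input_in_universe
        json.dump(doc, destination, indent=2)
        destination.write("\n")
    else:
        raise ValueError(f"unknown output format {format!r} (expected 'tsv' or 'json')")


def read_results_tsv(stream: str | IO[str]) -> list[dict]:
    """Parse a result TSV back into typed dicts (round-trip helper)."""
    text = stream if isinstance(stream, str) else stream.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = tuple(lines[0].split("\t"))
    if header != TSV_COLUMNS:
        raise ValueError(f"unexpected result header {header}")
    out = []
    for line in lines[1:]:
        cols = line.split("\t")
        row = dict(zip(TSV_COLUMNS, cols))
        for key in ("input_annotated", "reference_annotated", "input_total", "reference_total"):
            row[key] = int(row[key])
        for key in ("p_value", "bonferroni_p"):
            row[key] = float(row[key])
        row["odds_ratio"] = math.inf if row["odds_ratio"] == "Inf" else float(row["odds_ratio"])
        out.append(row)
    return out


@dataclass
class VennPartition:
    """Exclusive-membership counts over 1–4 labelled sets.

    ``partition`` maps each non-empty frozenset of labels to the number
    of ids belonging to exactly those lists; the counts sum to the size
    of the union.
    """

    lists: dict[str, set[str]]
    partition: dict[frozenset, int] = field(default_factory=dict)

    def pairwise_overlap(self, label_a: str, label_b: str) -> int:
        """|A ∩ B|: sum of partition cells containing both labels."""
        return sum(
            count
            for subset, count in self.partition.items()
            if label_a in subset and label_b in subset
        )


def venn_partition(lists: Mapping[str, Iterable[str]]) -> VennPartition:
    """Partition the union of up to four id sets by exact membership.

    Raises on an empty mapping or more than four labels (the diagram
    stops being readable, and the comparisons this supports never used
    more).
    """
    if not lists:
        raise ValueError("venn_partition needs at least one labelled list")
    if len(lists) > 4:
        raise ValueError(f"venn_partition supports at most 4 lists, got {len(lists)}")
    sets = {label: set(ids) for label, ids in lists.items()}
    partition: dict[frozenset, int] = {}
    labels = sorted(sets)
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            subset = frozenset(combo)
            inside = set.intersection(*(sets[l] for l in combo))
            outside = set.union(*(sets[l] for l in labels if l not in subset), set())
            partition[subset] = len(inside - outside)
    union_size = len(set.union(*sets.values()))
    assert sum(partition.values()) == union_size, "partition does not conserve the union"
    return VennPartition(lists=sets, partition=partition)
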