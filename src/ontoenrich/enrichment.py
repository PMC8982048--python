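"""Hypergeometric over-representation statistics.

The model: the input list contributes ``n`` genes drawn from the
reference universe of ``N`` annotated genes; a term annotated to ``K``
universe genes is over-represented when the observed overlap ``k``
is improbably large under sampling without replacement, i.e. when the
upper tail ``P(X >= k)`` of ``X ~ Hypergeometric(N, K, n)`` is small.
Because one run tests many terms in parallel, each nominal P-value is
Bonferroni-corrected by the number of terms T associated with genes in
the reference set.  An odds ratio — the odds of the term in the input
list over its odds in the reference set — quantifies effect size
independently of significance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import stats

from .annotations import AnnotationCorpus
from .errors import DomainError, EmptyOverlapError
from .ontology import OntologyGraph


@dataclass(frozen=True)
class ContingencyCounts:
    """The (k, n, K, N) quadruple behind one term's test.

    k: input genes annotated to the term; n: input genes in the
    universe; K: universe genes annotated to the term; N: universe size.
    """

    k: int
    n: int
    K: int
    N: int

    def validate(self) -> None:
        if self.N < 1:
            raise DomainError(f"N >= 1 violated (N={self.N})")
        if not 0 <= self.k:
            raise DomainError(f"k >= 0 violated (k={self.k})")
        if self.k > min(self.n, self.K):
            raise DomainError(
                f"k <= min(n, K) violated (k={self.k}, n={self.n}, K={self.K})"
            )
        if self.n > self.N:
            raise DomainError(f"n <= N violated (n={self.n}, N={self.N})")
        if self.K > self.N:
            raise DomainError(f"K <= N violated (K={self.K}, N={self.N})")


@dataclass
class EnrichmentResult:
    """One row of the result table."""

    term: str
    term_name: str
    counts: ContingencyCounts
    p_nominal: float
    p_bonferroni: float
    odds_ratio: float  # may be math.inf


@dataclass
class EnrichmentRun:
    """All per-term results of one analysis plus the run bookkeeping."""

    results: list[EnrichmentResult]
    n_tests: int
    n_input_resolved: int
    n_input_in_universe: int
    species: str
    ontology_key: str


def hypergeom_upper_tail(counts: ContingencyCounts) -> float:
    """Upper-tail probability P(X >= k) for X ~ Hypergeometric(N, K, n).

    Evaluated through the log-space survival function, so deeply
    significant terms on large universes do not underflow to 0
    prematurely.  ``k = 0`` returns exactly 1.
    """
    counts.validate()
    if counts.k == 0:
        return 1.0
    # sf(k-1) = P(X >= k); scipy signature hypergeom(M=N, n=K, N=n)
    p = float(stats.hypergeom.sf(counts.k - 1, counts.N, counts.K, counts.n))
    return min(max(p, 0.0), 1.0)


def bonferroni_adjust(p: float, n_tests: int) -> float:
    """Family-wise correction min(1, p * n_tests)."""
    if n_tests < 1:
        raise DomainError(f"n_tests must be >= 1, got {n_tests}")
    if not 0.0 <= p <= 1.0:
        raise DomainError(f"p must be in [0, 1], got {p}")
    return min(1.0, p * n_tests)


def odds_ratio(
    counts: ContingencyCounts,
    formula: str = "simple",
    correction: str = "none",
) -> float:
    """Enrichment odds ratio for one term.

    ``simple`` (default) is the ratio of the term's odds in the input
    list to its odds in the reference set: [k/(n-k)] / [K/(N-K)].
    ``contingency`` is the 2x2 sample odds ratio
    [k(N-n-K+k)] / [(n-k)(K-k)].  With ``correction='haldane'`` 0.5 is
    added to every cell before either formula (Haldane–Anscombe),
    removing infinities at the cost of slight shrinkage.

    A zero denominator with a nonzero numerator returns ``+inf``; a term
    absent from both input and reference (k = K = 0) is undefined.
    """
    counts.validate()
    if counts.n < 1:
        raise DomainError("odds ratio needs n >= 1")
    if counts.k == 0 and counts.K == 0:
        raise DomainError("odds ratio undefined: term absent from input and reference")
    k, n, K, N = float(counts.k), float(counts.n), float(counts.K), float(counts.N)
    if formula == "simple":
        a, b, c, d = k, n - k, K, N - K
    elif formula == "contingency":
        a, b, c, d = k, n - k, K - k, N - n - K + k
    else:
        raise ValueError(f"unknown odds-ratio formula {formula!r}")
    if correction == "haldane":
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    elif correction != "none":
        raise ValueError(f"unknown odds-ratio correction {correction!r}")
    numerator_odds = a / b if b > 0 else math.inf
    denominator_odds = c / d if d > 0 else math.inf
    if denominator_odds == 0:
        return math.inf if numerator_odds > 0 else 0.0
    if math.isinf(numerator_odds) and math.isinf(denominator_odds):
        return math.nan
    if math.isinf(numerator_odds):
        return math.inf
    return numerator_odds / denominator_odds


def enrich(
    input_genes: Iterable[str],
    corpus: AnnotationCorpus,
    graph: OntologyGraph | None = None,
    bonferroni_scope: str = "reference",
    or_formula: str = "simple",
    or_correction: str = "none",
) -> EnrichmentRun:
    """Test every term hit by the input list for over-representation.

    Input genes outside the reference universe are dropped before
    counting (the hypergeometric model is only defined on the annotated
    universe); the drop is visible as
    ``n_input_resolved - n_input_in_universe``.  Candidate terms are
    those with k >= 1 — a term with no input gene has upper-tail
    probability 1 and is never reported.  Results are returned
    unordered; ordering and display filtering belong to the results
    layer.

    ``bonferroni_scope='reference'`` multiplies by T = number of terms
    annotated in the reference corpus (after propagation);
    ``'input'`` multiplies by the number of candidate terms only.
    """
    input_list = list(dict.fromkeys(input_genes))
    in_universe = [g for g in input_list if g in corpus.universe]
    n = len(in_universe)
    if n == 0:
        raise EmptyOverlapError(
            "no input gene is in the reference universe "
            f"({len(input_list)} input genes, universe size {len(corpus.universe)})"
        )
    N = len(corpus.universe)
    input_set = set(in_universe)

    candidates: list[tuple[str, int, int]] = []
    for term, genes in corpus.propagated_term_index.items():
        k = len(input_set & genes)
        if k >= 1:
            candidates.append((term, k, len(genes)))

    if bonferroni_scope == "reference":
        n_tests = corpus.n_terms_annotated
    elif bonferroni_scope == "input":
        n_tests = len(candidates)
    else:
        raise ValueError(f"unknown bonferroni scope {bonferroni_scope!r}")
    n_tests = max(n_tests, 1)

    # one vectorized survival-function call across all candidate terms
    if candidates:
        k_arr = np.array([k for _, k, _ in candidates])
        K_arr = np.array([K for _, _, K in candidates])
        p_arr = stats.hypergeom.sf(k_arr - 1, N, K_arr, n)
        p_arr = np.clip(p_arr, 0.0, 1.0)
    else:
        p_arr = np.empty(0)

    results = []
    for (term, k, K), p in zip(candidates, p_arr):
        counts = ContingencyCounts(k=k, n=n, K=K, N=N)
        name = ""
        if graph is not None and term in graph.terms:
            name = graph.terms[term].name
        results.append(
            EnrichmentResult(
                term=term,
                term_name=name,
                counts=counts,
                p_nominal=float(p),
                p_bonferroni=bonferroni_adjust(float(p), n_tests),
                odds_ratio=odds_ratio(counts, formula=or_formula, correction=or_correction),
            )
        )
    return EnrichmentRun(
        results=results,
        n_tests=n_tests,
        n_input_resolved=len(input_list),
        n_input_in_universe=n,
        species=corpus.species,
        ontology_key=corpus.ontology_key,
    )
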