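import math
from itertools import combinations
from math import comb

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ontoenrich.annotations import AnnotationRecord, build_corpus
from ontoenrich.enrichment import (
    ContingencyCounts,
    bonferroni_adjust,
    enrich,
    hypergeom_upper_tail,
    odds_ratio,
)
from ontoenrich.errors import DomainError, EmptyOverlapError
from ontoenrich.fixtures import SPECIES_A, FixtureSpec, SpikeSpec, sample_input_set
from ontoenrich.ontology import parse_obo


def enumeration_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """Exhaustive oracle: fraction of n-subsets of N with >= k marked items.

    Enumerates all C(N, n) subsets; independent of any distribution code.
    """
    marked = set(range(K))
    hits = sum(1 for subset in combinations(range(N), n) if len(marked & set(subset)) >= k)
    return hits / comb(N, n)


class TestHypergeomUpperTail:
    def test_k_zero_is_exactly_one(self):
        assert hypergeom_upper_tail(ContingencyCounts(k=0, n=4, K=5, N=10)) == 1.0

    def test_exact_combinatorial_value(self):
        # all four draws marked: C(5,4)*C(5,0)/C(10,4) = 5/210
        p = hypergeom_upper_tail(ContingencyCounts(k=4, n=4, K=5, N=10))
        assert p == pytest.approx(5 / 210, abs=1e-12)

    def test_matches_subset_enumeration_N12(self):
        N, n = 12, 5
        for K in (0, 1, 4, 7, 12):
            for k in range(0, min(n, K) + 1):
                expected = enumeration_upper_tail(k, n, K, N)
                got = hypergeom_upper_tail(ContingencyCounts(k=k, n=n, K=K, N=N))
                assert got == pytest.approx(expected, abs=1e-12)

    def test_invariant_violation_names_inequality(self):
        with pytest.raises(DomainError, match="k <= min"):
            hypergeom_upper_tail(ContingencyCounts(k=6, n=5, K=10, N=20))
        with pytest.raises(DomainError, match="n <= N"):
            hypergeom_upper_tail(ContingencyCounts(k=1, n=30, K=10, N=20))

    @given(
        st.integers(min_value=1, max_value=60).flatmap(
            lambda N: st.tuples(
                st.just(N),
                st.integers(min_value=1, max_value=N),
                st.integers(min_value=0, max_value=N),
            )
        )
    )
    @settings(max_examples=80, derandomize=True)
    def test_p_strictly_decreases_in_k(self, nNK):
        N, n, K = nNK
        ps = [
            hypergeom_upper_tail(ContingencyCounts(k=k, n=n, K=K, N=N))
            for k in range(0, min(n, K) + 1)
        ]
        for lo, hi in zip(ps[1:], ps[:-1]):
            assert lo < hi or hi == pytest.approx(lo)  # strictly decreasing up to fp noise
        assert all(0.0 <= p <= 1.0 for p in ps)


class TestBonferroni:
    @pytest.mark.parametrize(
        "p,n_tests,expected",
        [(0.001, 10, 0.01), (0.01, 200, 1.0), (0.0, 5000, 0.0), (1.0, 1, 1.0)],
    )
    def test_adjustment(self, p, n_tests, expected):
        assert bonferroni_adjust(p, n_tests) == pytest.approx(expected)

    def test_zero_tests_rejected(self):
        with pytest.raises(DomainError):
            bonferroni_adjust(0.5, 0)


class TestOddsRatio:
    def test_no_enrichment_is_one(self):
        assert odds_ratio(ContingencyCounts(k=2, n=10, K=20, N=100)) == pytest.approx(1.0)

    def test_strong_enrichment_value(self):
        # (8/2) / (20/80) = 16
        assert odds_ratio(ContingencyCounts(k=8, n=10, K=20, N=100)) == pytest.approx(16.0)

    def test_saturated_input_is_infinite(self):
        assert math.isinf(odds_ratio(ContingencyCounts(k=10, n=10, K=20, N=100)))

    def test_haldane_correction_finite(self):
        value = odds_ratio(
            ContingencyCounts(k=10, n=10, K=20, N=100), correction="haldane"
        )
        assert math.isfinite(value)
        assert value == pytest.approx((10.5 / 0.5) / (20.5 / 80.5))

    def test_contingency_formula(self):
        # 2x2 sample OR: [k(N-n-K+k)] / [(n-k)(K-k)] = (8*78)/(2*12)
        value = odds_ratio(ContingencyCounts(k=8, n=10, K=20, N=100), formula="contingency")
        assert value == pytest.approx((8 * 78) / (2 * 12))

    def test_term_absent_everywhere_undefined(self):
        with pytest.raises(DomainError, match="absent"):
            odds_ratio(ContingencyCounts(k=0, n=10, K=0, N=100))

    def test_direction_matches_rate_comparison(self):
        enriched = ContingencyCounts(k=5, n=10, K=20, N=100)   # 0.5 > 0.2
        depleted = ContingencyCounts(k=1, n=10, K=20, N=100)   # 0.1 < 0.2
        assert odds_ratio(enriched) > 1.0
        assert odds_ratio(depleted) < 1.0


@pytest.fixture
def chain_corpus(chain_graph):
    """Universe g1..g10 all at root; only g1 at leaf/mid."""
    records = [
        AnnotationRecord(gene=f"g{i}", species="rat", term="GO:0000001", evidence="IDA")
        for i in range(1, 11)
    ] + [AnnotationRecord(gene="g1", species="rat", term="GO:0000003", evidence="IDA")]
    return build_corpus(records, chain_graph, "rat", "GO")


class TestEnrich:
    def test_single_gene_closed_form(self, chain_graph, chain_corpus):
        """Input {g1}: leaf has k=1, K=1, n=1, N=10 and p = n*K/N = 0.1."""
        run = enrich(["g1"], chain_corpus, chain_graph)
        by_term = {r.term: r for r in run.results}
        leaf = by_term["GO:0000003"]
        assert (leaf.counts.k, leaf.counts.K, leaf.counts.n, leaf.counts.N) == (1, 1, 1, 10)
        assert leaf.p_nominal == pytest.approx(0.1)
        assert run.n_tests == 3
        assert leaf.p_bonferroni == pytest.approx(0.3)

    def test_full_universe_input_saturates(self, chain_graph, chain_corpus):
        run = enrich([f"g{i}" for i in range(1, 11)], chain_corpus, chain_graph)
        for r in run.results:
            assert r.counts.k == r.counts.K
            assert r.p_nominal == pytest.approx(1.0)

    def test_genes_outside_universe_dropped_from_n(self, chain_graph, chain_corpus):
        run = enrich(["g1", "ghost"], chain_corpus, chain_graph)
        assert run.n_input_resolved == 2
        assert run.n_input_in_universe == 1

    def test_empty_overlap_raises(self, chain_graph, chain_corpus):
        with pytest.raises(EmptyOverlapError):
            enrich(["ghost1", "ghost2"], chain_corpus, chain_graph)

    def test_zero_k_terms_never_reported(self, chain_graph):
        records = [
            AnnotationRecord(gene="g1", species="rat", term="GO:0000003", evidence="IDA"),
            AnnotationRecord(gene="g2", species="rat", term="GO:0000001", evidence="IDA"),
        ]
        corpus = build_corpus(records, chain_graph, "rat", "GO")
        run = enrich(["g2"], corpus, chain_graph)
        reported = {r.term for r in run.results}
        assert "GO:0000003" not in reported and "GO:0000001" in reported

    def test_input_permutation_invariance(self, fixture_corpus, fixture_graph):
        genes = sorted(fixture_corpus.universe)[:25]
        run_a = enrich(genes, fixture_corpus, fixture_graph)
        run_b = enrich(list(reversed(genes)), fixture_corpus, fixture_graph)
        a = sorted((r.term, r.p_nominal, r.counts.k) for r in run_a.results)
        b = sorted((r.term, r.p_nominal, r.counts.k) for r in run_b.results)
        assert a == b

    def test_bonferroni_self_consistency_and_scope(self, fixture_corpus, fixture_graph):
        genes = sorted(fixture_corpus.universe)[:15]
        run = enrich(genes, fixture_corpus, fixture_graph)
        assert run.n_tests == fixture_corpus.n_terms_annotated
        for r in run.results:
            assert r.p_bonferroni == min(1.0, r.p_nominal * run.n_tests)
            assert r.p_bonferroni >= r.p_nominal
        run_input = enrich(genes, fixture_corpus, fixture_graph, bonferroni_scope="input")
        assert run_input.n_tests == len(run_input.results) <= run.n_tests

    def test_spiked_term_attains_smallest_p(self, fixture_corpus, fixture_graph):
        leaves = sorted(
            t for t in fixture_graph.leaves()
            if 12 <= len(fixture_corpus.propagated_term_index.get(t, ())) <= 40
        )
        term = leaves[0]
        spec = FixtureSpec(seed=42, spike=SpikeSpec(term=term, n_input=10, fraction_from_term=1.0))
        genes = sample_input_set(spec, fixture_corpus, seed=42)
        run = enrich(genes, fixture_corpus, fixture_graph)
        best = min(run.results, key=lambda r: (r.p_nominal, r.term))
        assert best.term == term
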