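# Methods

## Model

Over-representation analysis treats the input gene list as a draw of
`n` genes without replacement from a reference universe of `N` genes.
For a term annotated to `K` universe genes, the number of annotated
genes in the draw is hypergeometric, and the evidence for
over-representation is the upper tail `P(X ≥ k)` at the observed
overlap `k`.  Assumptions worth keeping in mind:

- **The universe is the annotated gene set**, not the genome: only
  genes of the selected species with at least one annotation in the
  selected ontology enter `N`.  This makes the null model exact for the
  population actually being tested, but it also means results are only
  comparable between runs that used the same corpus.  Input genes
  outside the universe are dropped from `n` (and reported), because the
  hypergeometric model is undefined for draws outside the population.
- **Independence of the input draw from the annotation process.**  A
  DEG list selected *because* of a pathway's regulation violates this
  in the way every ORA does; the P-value is an enrichment screen, not a
  posterior.
- **Tests are counted, not correlated.**  Bonferroni controls the
  family-wise error assuming `T` independent-ish tests; DAG-propagated
  terms are strongly nested, so the correction is conservative.

## Annotation propagation

The true-path rule is applied before any counting: every surviving
(gene, term) record is copied to all ancestors of the term over the
closure relations.  The closure relation set defaults to
`{is_a, part_of}` and is configurable per ontology load; `regulates`
and logical-definition (`intersection_of`) lines never contribute
edges.  Public annotation practice differs between resources on
whether `part_of` is propagated; including it is the common choice for
term-counting tools, and excluding it is one constructor argument away.
The same mechanism is applied to every ontology, including chemical
(ChEBI) and disease vocabularies — gene–chemical interactions are
treated as annotations and propagated up the chemical DAG.

Filtering before propagation, in order: other-species records,
NOT-qualified records (a NOT annotation asserts the *absence* of a
function and must not count as positive evidence — dropping it is the
annotation-consortium convention), records with excluded evidence
codes (none excluded by default; imports such as IEA/ISO count),
records whose term id cannot be resolved (skipped with a warning
count).  Alt-ids and `replaced_by` chains of merged/obsoleted terms are
resolved first, so an annotation to a merged id lands on the surviving
term.  Duplicate (gene, term) pairs collapse — set semantics
throughout.

## Multiple-testing multiplier

`T` is the number of terms with at least one annotated universe gene
*after* propagation (`n_terms_annotated`), i.e. the number of tests the
corpus could run, not merely the terms the input happens to hit.  That
is the stricter of the two defensible readings; `--bonferroni-scope
input` switches to the candidate-term count for users who prefer it.
`T` is counted post-propagation for consistency with the per-term gene
counts the table reports.

## Odds ratio

Two formulas circulate for "input odds over reference odds".  The
primary is the direct transliteration
`OR = [k/(n−k)] / [K/(N−K)]`, which compares the term's odds in the
input list with its odds in the whole reference set; `--or-formula
contingency` gives the 2×2 sample odds ratio
`[k(N−n−K+k)] / [(n−k)(K−k)]`.  Zero handling: a zero denominator with
a nonzero numerator reports `+inf` (serialized as `Inf` in TSV, null
plus a flag in JSON); `--or-correction haldane` adds 0.5 to all cells
instead.  A term absent from both input and reference is undefined and
raises.

## Numerical choices

- The upper tail is evaluated through the log-space survival function
  of the hypergeometric distribution (scipy), so deeply significant
  terms on large universes do not underflow; results are clipped to
  [0, 1] and `k = 0` returns exactly 1.
- Candidate terms are those with `k ≥ 1`; a term with no input gene has
  tail probability 1 and is never reported.
- Output ordering is ascending nominal P-value with ties broken by
  ascending term id, which makes runs byte-reproducible.
- Floats are serialized with `repr` in TSV so read-back is bit-exact.
- Identifier resolution tries exact canonical id, then exact alias
  value of any id type, then case-insensitive symbol; an ambiguous
  symbol is reported unresolved rather than guessed, because a silent
  mis-mapping corrupts both `N` and `k`.
- Genomic coordinates are 1-based inclusive end-to-end; BED input
  (0-based half-open) is converted at the reader.  Region queries use
  ≥ 1 bp *overlap* (not containment), ignoring strand.

## Synthetic data generator

`ontoenrich.fixtures` emulates the structural features the pipeline
depends on: a rooted random DAG (each non-root term picks 1–2 parents
among earlier terms, acyclic by construction), per-gene direct
annotation counts `max(1, Poisson(density))` to uniformly chosen terms,
a gene table with three alias types and coordinates on one synthetic
assembly, and a 1:1 ortholog table to a second synthetic species.  One
integer seed is split into independent named streams (ontology /
annotations / coordinates / input-set) so components can be regenerated
independently; the same seed yields byte-identical files.

Default study conditions, used by the statistical checks: 50 terms,
200 genes, density 3 — large enough that the term-size spectrum spans
singleton leaves to the full-universe root, small enough that thousands
of runs finish in seconds.  Null inputs are uniform 20-gene draws from
the universe; spiked inputs draw 80% of a 10-gene list from one leaf
term with 12–40 propagated genes.

What the generator does **not** emulate: realistic GO topology (depth,
fan-in skew), annotation bias toward well-studied genes, correlated
annotations from pleiotropy, or noisy/ambiguous identifier tables.
Passing calibration and recovery checks on this generator shows the
statistic and plumbing are correct under the stated null, not that any
particular biological corpus satisfies that null.

## Statistical checks and problem sizes

- Exactness: the tail equals exhaustive subset enumeration for every
  (N ≤ 12, n, K, k) — 3,094 cases — to within 1e-12.
- Calibration: over 2,000 null runs the fraction of (run, term) pairs
  with `p < α` must not exceed `α + 3·SE`; the observed fractions sit
  well *below* α because the discrete test is conservative.
- Power: the spiked term ranks first in ≥ 95% of 200 seeded runs
  (observed: 100%).
- Propagation invariants: per-term counts are monotone along every
  closure edge and corpus construction is idempotent on 100 random
  DAGs.
- Determinism: two identical CLI invocations produce byte-identical
  TSV.

## Known limitations

- Bonferroni only; no FDR, no two-sided Fisher test, no rank-based
  (GSEA-style) mode, no depletion mode.
- No OWL input and no reasoning beyond transitive closure over the
  configured relations.
- Ortholog mapping is table-driven (with one-to-many fan-out); no
  sequence-based inference, no assembly liftover.
- The Venn comparison is capped at four lists.
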