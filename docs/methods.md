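# Methods

## Scope and model

`moonpred` implements three homology-based GO-term scorers — PFP, ESG, and a
BLAST annotation-transfer baseline — plus the propagated precision/recall
protocol used to measure how well each recovers the two functions of
moonlighting proteins. All three consume the same inputs: a GO ontology
(OBO), a protein→GO annotation corpus (GAF), and per-query sequence-search
hit tables (BLAST tabular with E-values). No scorer runs a search binary;
they consume a `SearchProvider`, normally a table over parsed files. An
optional `psiblast` adapter (3 iterations, configurable BLOSUM matrix)
exists for live use and is never exercised by tests.

## Ontology semantics

* Only `is_a` edges define the hierarchy. "Parental terms" in all scoring
  and evaluation means the `is_a` ancestor closure; `part_of` and other
  relationship types are ignored. This is the minimal reading of parental
  propagation and keeps the three GO namespaces disjoint, so propagation
  never crosses aspects.
* Obsolete terms are parsed and flagged but never traversed. `alt_id`
  accessions resolve silently to primary ids at every entry point.
* Namespace roots are **included** in propagated sets by default (the
  protocol propagates "to the root"); `include_roots=False` drops the three
  roots for a stricter evaluation. All three aspects are treated uniformly;
  the evaluation accepts any truth subset, so a namespace restriction is a
  matter of filtering the truth table.

## Corpus statistics for PFP

* P(fa|fj) is computed on **direct** (asserted) annotations: co-annotation
  count over the count of fj-annotated proteins. Computing it on propagated
  sets would be degenerate — every ancestor co-occurs with everything below
  it. Co-occurrence rows are built lazily per conditioning term and cached;
  no quadratic table is materialized.
* The parental-proportion counts n(·) used by upward score transfer use the
  **propagated** view: proteins "belonging to" a parental term include those
  annotated to its descendants.
* A hit annotation absent from the corpus contributes
  `cond_prob_fallback` (default 0: no corpus evidence, no score; a nonzero
  fallback credits only the term itself).
* Evidence codes are not filtered by default; `load_gaf` accepts an
  allow-list.

## PFP numerical choices

* b must equal log10(e_max) (enforced), so the weight of a hit at the
  ceiling is exactly 0 and all scores are non-negative. Defaults b=2,
  e_max=100.
* Candidate terms are exactly those with nonzero co-occurrence against some
  hit annotation — identical result to scoring the whole ontology, at a
  fraction of the cost.
* Parental transfer sums over the **set** of directly scored descendants of
  each ancestor, once per descendant regardless of path multiplicity (the
  proportions are path-independent quantities), and only direct scores act
  as sources — cascading through already-propagated intermediates would
  count a descendant once per level. Ancestors with zero propagated count
  are skipped with a warning.
* Reported E-values of 0 are clamped to `e_floor` (default 1e-180) before
  the log, keeping every score finite.
* Ranking ties break by ascending GO accession, making cutoff sets
  deterministic. PFP's headline cutoff of 0.5 is a **list fraction**: the
  top `round(0.5 × 1000)` = 500 of the ranked raw-score list. This is the
  only reading consistent with a 1000-prediction list yielding a maximum of
  500 at 0.5; absolute score cutoffs remain available.

## ESG choices

* Within one search level, hit weights are −log10(E) normalized to sum
  to 1; hits with E > 1 clamp to zero weight rather than going negative. A
  level in which every hit clamps to zero is degenerate: an error at the
  first level, a skipped seed at the second.
* The two levels combine as a convex mixture with default weights
  (0.5, 0.5). The underlying description states only that the score is the
  total weight from the two levels while asserting a [0, 1] range; the
  convex mixture is the simplest combination guaranteeing that range, and
  the weights are config-exposed as an interpretation rather than hidden.
* The top `n_first_level = 10` first-level hits seed second-level searches
  (expansion breadth is not prescribed anywhere; 10 keeps providers small
  and is configurable). A hit's own annotations count at level one whether
  or not it is expanded; failed or missing second-level searches degrade to
  a zero level-two contribution with a warning.
* The original query is excluded from second-level hit lists, and self-hits
  are dropped at parse time (leakage guards).

## BLAST baseline choices

* "Better than E = 0.01" is strict: a boundary hit is excluded.
* A term transferred from several hits keeps its **maximum** (best-hit)
  score — per-hit provenance, distinguishing the baseline from PFP's
  additive sum. An optional cap on the number of qualifying hits exists;
  by default all are used.
* BLOSUM62/45/30 variants differ only upstream of this module; a matrix tag
  is recorded in prediction metadata for reporting.

## Evaluation protocol

* Per protein: predicted terms at a cutoff and true terms are both closed
  to the root, then TP/FP/FN are set cardinalities. Empty predictions give
  undefined precision (dropped from the precision average) and recall 0
  (kept in the recall average) — recall stays honest without 0/0.
* Averaging is macro over proteins by default; a pooled-counts micro mode
  is behind a flag. Both modes are implemented because the original
  protocol does not say which it used.
* The moonlighting truth filter keeps labels {function1, function2, both}:
  a term belonging to both functions belongs to each. The all-labels filter
  is the identity.
* Fixed operating points: PFP list-fraction 0.5, ESG score 0.35, BLAST
  E < 0.01 (ranking score ≥ 4). Grids: PFP ranks 10…1000 step 10, ESG 100
  cutoffs in [0,1], BLAST 100 scores in [4,45].

## Synthetic data: what it emulates and what it does not

The generator (`moonpred.fixtures`) emulates the *structure* of the
moonlighting benchmark: a cohort of 19 query proteins (the defaults; fully
configurable), each with three function-1 terms, three function-2 terms,
one term labeled `both` and two labeled `neither`; a background corpus of
150 proteins with 3–8 random annotations over a random 3-namespace DAG of
60 terms each (topological-order parent sampling, ≤2 parents, guaranteeing
acyclicity); and per query two hit clusters of 4 proteins whose annotations
are biased (p = 0.8 per term) toward the planted function sets.

E-values are log-uniform over 10^[−6, 10^2]. The function-1 cluster draws
from the strong half (all below the E = 0.01 transfer cutoff), the
function-2 cluster and spurious background hits from the weak half (all
above it). That placement is the planted signal: the second function is
reachable only by methods that use weak hits, which is the regime a
shallower substitution matrix opens up in a real search. Cluster members
also hit their cluster mates, giving ESG genuine second-level searches.

Not emulated: actual sequences, alignment statistics, realistic GO term
depth distributions, evidence-code structure, or annotation bias. Passing
tests therefore demonstrate correctness of the scoring arithmetic and the
qualitative weak-hit phenomenon under controlled conditions — not numeric
performance on real UniProt-era data, which would require the historical
search database.

Fixture generation is byte-deterministic in the spec (single numpy
`default_rng(seed)` stream, fixed emission order, fixed float formats), and
the emitted manifest records checksums, planted term sets, and per-term
annotation counts so tests can verify files against intent.

## Problem sizes

Unit and property tests run on toy DAGs (3–10 terms) and seeded random
instances (10 terms, ≤10 proteins, ≤5 hits); oracle-equivalence suites use
100 such instances per scorer and 1000 for the ESG bound property. The
end-to-end suites use the default study-scale dataset: 19 queries, ~300
corpus proteins, 100-point cutoff grids per method. The whole test suite
completes in a few seconds on one CPU.

## Known limitations

* The PFP band-score/p-value confidence layer of the original server is out
  of scope, as is multi-level (>2) ESG expansion.
* Whether the original PFP/ESG runs used one PSI-BLAST iteration's hit list
  or the union over three is not recoverable; the provider contract leaves
  this to the adapter, and fixtures use a single flat list per query.
* GAF parsing covers the fields the scorers need (object id, qualifier, GO
  id, evidence); taxon filtering and annotation dates are ignored.
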