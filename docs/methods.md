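# Methods

## Ranking model

The prioritizer treats published gene–disease knowledge as a bipartite
scored graph between NCBI genes and UMLS concepts (CUIs restricted to the
semantic classes *disease*, *disorder* and *finding*), reached from patient
phenotypes through three independent HPO→CUI mapping paths: direct
Metathesaurus cross-references, HPO–ORDO phenotype–disease mappings composed
through the ORDO entry's UMLS cross-reference, and phenotype–disease
annotations. The matched CUI set is the union over paths and over input
terms; a term with no mapping on any path contributes nothing (patients
routinely carry such terms, so this is tolerated, not fatal). Retrieved
associations are grouped by gene, and a gene's priority is the maximum
association score over its matched CUIs. This "highest score wins" statistic
is deliberately insensitive to how many concepts match a gene: one strong,
well-evidenced association outranks many weak ones.

Assumptions: association scores are comparable across source diseases and
already calibrated to [0, 1] (they are consumed as data, never recomputed);
the mapping tables and score semantics are those of the upstream release the
store was built from.

### Determinism conventions

* Ties in the gene ranking break by ascending NCBI gene id; evidence entries
  per gene sort by descending score then ascending CUI; PubMed ids print in
  ascending order. Repeated runs are byte-identical.
* Scores serialize as the shortest decimal that round-trips the stored
  float (`0.82` stays `0.82`).
* Duplicate (gene, CUI) association rows collapse on load to the maximum
  score with the union of PubMed evidence — consistent with the max-score
  ranking statistic, which duplicate rows could otherwise not affect anyway.
* An empty result is a success (an output file is still written) because
  diagnostic pipelines consume the file unconditionally.

## Ontology traversal

Only `is_a` edges participate. *children* mode follows child-direction edges
to depth ≤ *m*; *distance* mode walks the undirected `is_a` graph to
distance ≤ *m*. The cumulative (≤ *m*, not exactly-*m*) reading keeps
expansion monotone in *m*, which matches its purpose of widening the search
space. The seeds are always included; *m* = 0 is the identity. Obsolete
terms never carry traversal edges; an obsolete *seed* resolves once through
`replaced_by`, and an unresolvable obsolete seed is a hard error — silently
dropping a patient phenotype would be unsafe in a diagnostic setting. The
`is_a` graph must be acyclic; a cycle is reported with a witness path. OBO
1.4 is the canonical format; OWL-RDF input is a best-effort convenience that
reads `rdfs:subClassOf` between named HP classes plus `owl:deprecated` and
IAO replaced-by annotations.

## Knowledge store and minimization

The store is an in-memory indexed structure with fixed-shape join semantics
(hpo → cui per path; cui → associations); a triple-store/SPARQL layer would
add no expressive power for these queries. Two interchangeable on-disk
dialects exist — five TSV files, or Turtle with association nodes carrying
gene/disease/score/pmid predicates under this package's documented schema
IRIs — and round-trip to identical stores.

Minimization removes exactly what the query paths can never reach: an
association whose CUI appears in no mapping row, and a concept left with
neither a retained association nor a mapping row. Mapping rows are always
kept. This makes minimization idempotent and provably ranking-preserving,
which the tests verify exhaustively over every HPO term of a synthetic graph
(including deliberately injected orphan concepts).

Per-source provenance counts satisfy `loaded = retained + dropped`;
malformed rows are dropped with a logged warning rather than aborting, but a
store with zero associations is fatal.

## Synthetic knowledge graphs

The generator emulates the structure of real phenotype/gene–disease
releases at miniature scale: a rooted random `is_a` DAG (each non-root term
gets one, occasionally two, parents among earlier terms), concepts with
random semantic classes, Bernoulli-sampled associations over the
gene × concept grid, and per-term Bernoulli mapping rows (1–3 target
concepts per mapped term and path). Defaults — 100 genes, 80 concepts, 50
HPO terms, association density 0.05, mapping densities 0.35/0.2/0.4 for the
Metathesaurus/HOOM/PDA paths, uniform scores rounded to 2 decimals, Poisson
PubMed evidence with mean 2 — give a graph dense enough that most queries
return several genes yet sparse enough that minimization and missed-gene
paths are exercised. Synthetic identifiers live in reserved blocks
(`HP:9xxxxxx`, `C9xxxxxx`) to avoid collision with real terms.

What the generator does **not** emulate: the long-tailed score distribution
of literature-mined associations, correlated mapping structure (real HPO
terms that map on one path tend to map on others), ontology depth and
branching statistics of the real HPO, and gene pleiotropy patterns. Passing
tests therefore demonstrate algorithmic correctness and reproducibility, not
clinical performance on real patients.

Patient cases plant 1 causal gene (a configurable fraction get 2, emulating
dual molecular diagnoses) by drawing association pairs without replacement
from those whose CUI is reachable from at least one HPO term, and including
such a term among the case's 1–15 phenotypes — so the planted gene is
guaranteed recoverable by the prioritizer. All randomness flows through
explicitly seeded `numpy` generators; identical (config, seed) produce
byte-identical files.

## Benchmark harness

* **Causal rank**: 1-based position of the diagnosed gene in a tool's full
  output, or MISSED; MISSED stays categorical here (no imputation) so
  output-size differences between tools remain visible.
* **Spike-in simulation**: per (case, causal gene), 25 panels of 19 decoys
  (drawn without replacement from the clinical-gene pool, excluding all of
  the case's causal genes) plus the causal gene. The tool's output
  restricted to a panel gives the causal rank; if absent after the *k*
  returned panel genes, the rank is uniform on {*k*+1, …, 20}, modeling an
  analyst who checks returned genes first. The stabilized rank is the median
  of the 25 (the 13th order statistic — an integer; if a user overrides the
  permutation count to an even number the lower median is taken). The 25
  panels are independently redrawn, not reshuffled — only redrawing
  compensates for an unlucky decoy set — and are seeded per (case, causal
  gene) so they are shared across tools, making tool comparisons paired; the
  imputation draw is seeded per (tool, case, gene, permutation).
* **Cumulative detection**: per tool, counts of median ranks ≤ r for
  r = 1…20; non-decreasing and saturating at the pair total.
* **Complementarity**: at a cutoff, a pair is hit if rank ≤ cutoff; unique
  if exactly one tool hits it. Reported percentages are 100·union/total and
  100·unique/union, rounded to 2 decimals. All tools must cover the same
  pair set.

## Problem sizes and open choices

The test suite and the acceptance script run on generated graphs of 50–120
HPO terms, 100–400 genes and 80–200 concepts with 200 random queries for
oracle comparison and 10⁴ draws for the imputation-uniformity check — sizes
chosen so each property is measured with comfortable statistical margin
while the whole suite stays fast. The 305-case cohort with three dual
diagnoses used by the acceptance script mirrors the published benchmark's
composition at synthetic scale; reproducing the published per-tool rankings
themselves would require running the seven external tools and is out of
scope.

Known limitations: no semantic-similarity scoring between HPO terms, no
variant-level evidence, no VCF integration; OWL parsing ignores anonymous
class expressions; scores are taken at face value from the store.
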