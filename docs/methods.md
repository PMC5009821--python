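# Methods

## Setting

Inputs are a GO ontology (OBO 1.2/1.4 flat file) and gene annotations (GAF
2.x or a two-column gene–term TSV). All computation is confined to one GO
namespace at a time (molecular_function, biological_process,
cellular_component); queries never cross namespaces. The ontology is a
rooted DAG; only `is_a` and `part_of` edges are traversed, matching the
convention of mainstream GO-similarity tools — `regulates`, `has_part` and
other relations are dropped at parse time with a logged count, as are
obsolete terms and cross-namespace edges. `alt_id`s resolve to their
canonical term.

## Annotation model

The true path rule: a gene annotated to a term is implicitly annotated to
every ancestor. The corpus keeps both the direct and the propagated
gene–term maps. Information content is

    IC(t) = -ln(|G_t| / |G|)

with `G_t` the propagated gene set of `t` and `G` the set of all genes with
at least one annotation in the loaded namespace. Natural log is the fixed
choice: the log base cancels in ratio-form measures but not in Resnik, and
fixing it makes every worked value reproducible. `IC(root) = 0` exactly;
IC is monotone non-decreasing from root to leaves. The most informative
common ancestor (MICA) is the max-IC common ancestor, with ties broken by
the lexicographically smallest term id so results are deterministic. GAF
rows with `NOT` qualifiers are dropped; evidence codes are included by
default with an exclusion flag (`--evidence-exclude IEA` and similar),
since backend corpora differ on IEA policy.

## Term measures

*Resnik* is `IC(MICA)`; it is 0 when two terms share only the root and is
bounded by `ln |G|`. *Schlicker* normalises by the terms' own IC and damps
generic ancestors: `2·IC(MICA)/(IC(t_a)+IC(t_b)) · (1 − |G_MICA|/|G|)`; the
root–root pair is defined as 0 (no information on either side). *Wang*
needs no annotations: the S-value of an ancestor `p` of term `t` is the
maximal product of edge contribution factors over paths `t → p`, computed
by dynamic programming in topological order (children before parents) and
verified in the test suite against exhaustive path enumeration. Factors
default to 0.8 (`is_a`) and 0.6 (`part_of`) — the original method's
convention — and must lie strictly inside (0, 1) so contributions decay;
when both relations connect the same pair the larger factor is used. The
ancestor sets in the Wang ratio include the terms themselves; otherwise
self-similarity would not be 1.

*HRSS* combines three quantities on the IC scale: `α = IC(MICA)` (shared
specificity), `β = ((IC(MIL_a) − IC(t_a)) + (IC(MIL_b) − IC(t_b)))/2` (how
far each term sits above its most informative leaf, MIL — the max-IC leaf
descendant, ties to the smallest id), and `γ = (IC(t_a) − IC(MICA)) +
(IC(t_b) − IC(MICA))` (distance of both terms to the MICA). The score is
`1/(1+γ) · α/(α+β)`, with 0 returned when `α+β = 0`. A widely circulated
statement of the HRSS weight places `IC(root)` in the numerator, which is
degenerate under the `IC(root) = 0` convention; this package follows the
orientation of the original HRSS formulation, under which an annotated
leaf's self-similarity is exactly 1. Distance is measured on the IC scale
by default (`dist(x, y) = IC(y) − IC(x)` for ancestor `x`); an edge-count
variant is available via `dist="edges"`. On sparse corpora a term may have
no *annotated* leaf below it; the MIL then falls back to the max-IC
annotated descendant (the term itself qualifies), contributing 0 to β.

## Gene measures

simUI, simGIC and TO compare *propagated* term sets (the true path rule is
the point of these measures). TO is returned as a raw count and flagged
unnormalised; thresholding a TO matrix therefore needs a threshold in
count units. Term measures are lifted to gene level over *direct*
annotation sets — propagating first would flood both sets with shared
ancestors and inflate every best match. Default aggregation is the
best-match average,

    ( Σ_{t∈T1} max_{t'∈T2} s(t,t') + Σ_{t'∈T2} max_{t∈T1} s(t,t') ) / (|T1|+|T2|),

with `max` available as an alternative. Batch scoring skips genes without
annotations and reports them in the matrix's skipped list (and the CLI's
JSON report) rather than failing the run.

## Integrative measure

Three steps, each with its free choices fixed as follows:

1. **Ranking.** Each seed measure's scores over the user's pair set are
   converted to descending ranks (ties get the mean of the tied
   positions — `scipy.stats.rankdata`), then normalised:
   `r' = 1 − (rank−1)/(N−1) ∈ [0,1]`. `r'` is invariant to any strictly
   monotone transform of the raw scores, which is what makes measures with
   different scales commensurable. Ranks are computed over the input pair
   set itself; no organism-wide pre-computed background is assumed.
2. **Seed selection.** For each pair, the median rank across measures is
   the consensus; measures within `δ·N` of it are selected (default
   `δ = 0.2`). If none qualifies, the single measure nearest the median is
   kept, so every pair retains at least one seed measure.
3. **Additive integration.** The integrated score is the weighted mean
   `Σ w_m r'(pair,m) / Σ w_m` over the selected measures. Normalising by
   the sum of *selected* weights keeps the score in [0,1] regardless of
   which subset was selected. Self-similarity is defined as 1. When a
   trained model assigns zero weight to a selected measure, selection is
   repeated among positively weighted measures so no pair becomes
   unscorable.

**Weight training.** Ground truth is a set of genes with Enzyme Commission
(EC) group labels (≥ 2 groups of ≥ 2 genes). The objective is mean
integrated similarity of within-group pairs minus mean of between-group
pairs. The search is simulated annealing over the weight simplex: uniform
start, Gaussian proposals (step 0.1) clipped to non-negative and
renormalised, Metropolis acceptance, geometric cooling (rate 0.995 from
temperature 0.05), 2 000 iterations by default. The best-seen state is
kept, so the trained objective is never below the uniform-weight
objective. The seed is a required, logged model field; scoring with a
trained model is fully deterministic. Weights are reported normalised to
sum 1 (the weighted mean is scale-invariant, so this is identifiability,
not a constraint on the search).

## Association networks

An edge connects two genes whose similarity is **strictly greater** than
the edge similarity threshold; ties at the threshold are excluded (the
documented reading of "greater than"). Isolated genes remain nodes.
Raising the threshold can only shrink the edge set — a property the tests
exercise directly. The score histogram over all `C(n,2)` pair scores
supports threshold choice. Subnetwork selection induces the subgraph on a
gene subset, optionally widened by the selected genes' direct neighbors.
Exports (edge TSV, GraphML, Cytoscape-compatible JSON in the
`elements{nodes,edges}` dialect with `score` as an edge data attribute)
write sorted nodes and edges with scores rounded to 6 decimals, so output
is byte-stable and round-trips through the matching readers.

## Synthetic data

The fixture generator stands in for a real GO release and a curated EC
training set:

- **TOY1** — a frozen 7-term, 8-gene fixture (hash-pinned as files) small
  enough that every similarity value is hand-checkable; all worked values
  in the tests are computed on it by independent set arithmetic.
- **Random ontologies** — term *i* may only parent to terms with smaller
  index, so acyclicity holds by construction; edges are `is_a` with
  probability 0.8, else `part_of`; sizes default to tens of terms.
- **EC-grouped corpora** — the ontology is built with one subtree
  ("functional module") per EC group under the root; each group's term
  pool is its own subtree, and a gene draws each of its 3 annotations from
  its group's pool with probability `coherence`, else uniformly from all
  non-root terms. Defaults (4 groups × 5 genes, coherence 0.9, 40 terms)
  give a clearly detectable but noisy group signal: at coherence 1 every
  within-group simUI exceeds every between-group simUI on test seeds, at
  coherence 0 the separation objective is indistinguishable from 0.

What the generator does *not* emulate: GO-scale ontologies (tens of
thousands of terms), realistic annotation-depth distributions, evidence
code mixtures, or shared terms between EC groups. Passing tests therefore
demonstrate correctness of the algorithms and the expected qualitative
behaviour of the integration, not performance on real annotation corpora.

## Numerical and degenerate-input choices

- `-ln(n/n)` is clamped to exactly 0.0 (no `-0.0` root IC).
- A gene annotated only to the root has simGIC self-similarity 0 (zero
  information), while simUI remains 1 (sets coincide).
- Rank normalisation with a single pair returns `r' = 1`.
- Training with one candidate measure returns weight 1 without searching.
- Empty-edge networks (threshold above the maximum score) are valid
  outputs with a warning, not errors.
- Problem sizes in the default test and acceptance runs (DAGs of 15–40
  terms, corpora of 8–20 genes, 50 oracle replicates, 20 training seeds)
  are chosen so every check runs in seconds while still exercising
  multi-parent paths, ties, and measure disagreement.

## Known limitations

- Gene identifiers are matched exactly against GAF column 2; no synonym or
  cross-database ID mapping (an optional user-supplied two-column map is
  accepted by the CLI).
- No pre-computed organism backgrounds: integrative ranks are relative to
  the submitted gene set, so integrated scores are comparable within one
  run, not across runs with different gene sets.
- The seed-selection window and the annealing schedule are pragmatic
  constructions; they satisfy the three-step integration design but are
  not calibrated against any external benchmark.
- Browser-based rendering/layout of networks is out of scope; exports
  target external viewers.
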