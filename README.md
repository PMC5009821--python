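# gosimnet

Gene Ontology (GO) based gene functional similarity, an integrative
rank-based measure, and thresholded gene functional-association networks.

Biologists comparing gene lists — from a screen, a co-expression module, a
proteomics hit list — often want to know which genes are *functionally*
similar, not just sequence-similar. GO annotations make that computable,
but no single semantic-similarity measure is best for every gene pair.
`gosimnet` provides seven established seed measures, an integrative measure
that selects and weights them per gene pair, and the network layer that
turns a similarity matrix into an association graph you can threshold,
slice and export to graph viewers.

## Measures

Term-level (lifted to genes by best-match averaging over direct
annotations):

- **Resnik** — `sim(t_a, t_b) = IC(MICA)`, the information content
  `IC(t) = -ln(|G_t|/|G|)` of the most informative common ancestor, where
  `G_t` is the set of genes annotated to `t` after true-path-rule
  propagation.
- **Schlicker** — `2·IC(MICA)/(IC(t_a)+IC(t_b)) · (1 − |G_MICA|/|G|)`.
- **Wang** — topology only: each term contributes an S-value to every
  ancestor (maximal product of edge factors, is_a 0.8 / part_of 0.6 by
  default), and similarity is the shared contribution over the total.
- **HRSS** — hybrid relative specificity: `1/(1+γ) · α/(α+β)` with
  `α = IC(MICA)`, `β` the mean IC gap from each term to its most
  informative leaf, and `γ` the IC distance of both terms to the MICA.

Gene-level, on propagated annotation sets `T_1`, `T_2`:

- **simUI** — Jaccard index `|T_1 ∩ T_2| / |T_1 ∪ T_2|`.
- **simGIC** — IC-weighted Jaccard `Σ_{T_1∩T_2} IC / Σ_{T_1∪T_2} IC`.
- **TO** — raw term overlap `|T_1 ∩ T_2|` (a count, deliberately
  unnormalised).

The integrative measure (`intego2` in the registry) ranks every gene pair
under each seed measure, keeps per pair the measures that agree with the
median rank (within a `δ·N` window), and averages their normalised rank
scores with weights trained on genes of known Enzyme Commission (EC)
groups — maximising mean within-group minus mean between-group similarity
with a seeded simulated-annealing search. See `docs/methods.md` for the
full model description.

## Worked example

Generate the built-in 7-term / 8-gene toy fixture, score five genes with
simUI, and build a network at threshold 0.4:

```bash
gosimnet fixtures --preset toy1 --outdir fx
gosimnet sim --obo fx/ontology.obo --gaf fx/annotations.gaf \
    --measure simui --out sim.tsv genes.txt   # genes.txt: g1..g5
gosimnet network --threshold 0.4 --out net.tsv sim.tsv
```

`sim.tsv` contains one row per unordered gene pair:

```
gene1	gene2	score	measure
g1	g2	1.0	simui
g1	g3	0.5	simui
g1	g4	0.2	simui
g1	g5	0.4	simui
...
```

`g1` and `g2` are annotated to the same term, so their propagated term
sets coincide (simUI 1.0); `g1` and `g3` sit in sibling leaves of the same
branch and share half of their union (0.5); `g1` and `g4` share only the
root's branch-level ancestors (0.2). The network step keeps edges with
score strictly greater than 0.4:

```
network: 5 nodes, 3 edges (threshold 0.4, measure simui) -> net.tsv
```

The same library calls are available in Python (`gosimnet.toy1`,
`gosimnet.pairwise_matrix`, `gosimnet.build_network`, ...), and
`gosimnet train` fits integration weights from an EC-group TSV.

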