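"""Term-to-term semantic similarity measures.

Four seed measures operate at the term level:

* **Resnik** — IC of the most informative common ancestor (MICA):
  ``sim = IC(MICA) = -ln(|G_MICA|/|G|)``.
* **Schlicker** — MICA IC normalised by the terms' own IC, damped by how
  generic the MICA is: ``sim = 2·IC(MICA)/(IC(ta)+IC(tb)) · (1-|G_MICA|/|G|)``.
* **Wang** — purely topological: each term spreads a semantic contribution
  (S-value) to its ancestors as the maximal product of edge weights along
  any path, and similarity is the shared contribution over the total.
* **HRSS** — hybrid relative specificity: combines the IC-scale distance of
  both terms to the MICA with how far each term sits above its most
  informative descendant leaf (MIL).

All four are symmetric. Resnik is unbounded above by ln|G|; the others map
into [0,1].
"""

from __future__ import annotations

from dataclasses import dataclass

from .annotations import AnnotationCorpus
from .errors import UndefinedICError
from .ontology import OntologyDAG


@dataclass(frozen=True)
class EdgeWeights:
    """Per-relation semantic contribution factors for the Wang measure.

    Defaults follow the original method's convention (is_a 0.8, part_of
    0.6); the factors must lie strictly inside (0, 1) so contributions
    decay toward the root.
    """

    w_is_a: float = 0.8
    w_part_of: float = 0.6

    def __post_init__(self) -> None:
        for name, w in (("w_is_a", self.w_is_a), ("w_part_of", self.w_part_of)):
            if not 0.0 < w < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {w}")

    def weight(self, relations: frozenset[str]) -> float:
        """Best factor when several relations link the same child/parent pair."""
        candidates = []
        if "is_a" in relations:
            candidates.append(self.w_is_a)
        if "part_of" in relations:
            candidates.append(self.w_part_of)
        if not candidates:
            raise ValueError(f"no weighted relation among {set(relations)}")
        return max(candidates)


DEFAULT_WEIGHTS = EdgeWeights()


@dataclass(frozen=True)
class WangSValueMap:
    """S-values of one term: ancestor id -> maximal path-product contribution."""

    term: str
    svalue: dict[str, float]

    @property
    def total(self) -> float:
        return sum(self.svalue[t] for t in sorted(self.svalue))


def wang_svalues(
    dag: OntologyDAG, term: str, weights: EdgeWeights = DEFAULT_WEIGHTS
) -> WangSValueMap:
    """S-value of every ancestor ``p`` of ``term`` (term itself included,
    with S-value 1): the max over child->...->p paths of the product of the
    edge factors along the path. Computed by dynamic programming in
    topological order, children before parents."""
    tid = dag.resolve(term)
    anc = dag.ancestors(tid, include_self=True)
    sval: dict[str, float] = {tid: 1.0}
    order = [t for t in dag.topological_order() if t in anc]
    order.reverse()  # leaf-ward first: children before parents
    for t in order:
        if t not in sval:
            continue
        for pid, _rel in dag.parents_of(t):
            if pid not in anc:
                continue
            w = weights.weight(dag.edge_relations(t, pid))
            cand = sval[t] * w
            if cand > sval.get(pid, 0.0):
                sval[pid] = cand
    return WangSValueMap(term=tid, svalue=sval)


def sim_wang(
    dag: OntologyDAG,
    ta: str,
    tb: str,
    weights: EdgeWeights = DEFAULT_WEIGHTS,
) -> float:
    """Wang semantic similarity; 1 for identical terms, > 0 always (the
    root is shared). Ancestor sets include the terms themselves."""
    sa = wang_svalues(dag, ta, weights)
    sb = wang_svalues(dag, tb, weights)
    shared = set(sa.svalue) & set(sb.svalue)
    # summation in sorted order keeps the result exactly symmetric in
    # (ta, tb) and reproducible across processes
    num = sum(sa.svalue[p] + sb.svalue[p] for p in sorted(shared))
    return num / (sa.total + sb.total)


def sim_resnik(corpus: AnnotationCorpus, dag: OntologyDAG, ta: str, tb: str) -> float:
    """IC of the most informative common ancestor; 0 when only the root is
    shared."""
    return corpus.information_content(corpus.mica(ta, tb))


def sim_schlicker(corpus: AnnotationCorpus, dag: OntologyDAG, ta: str, tb: str) -> float:
    """Relevance similarity: MICA IC normalised by the terms' combined IC,
    scaled by 1 - |G_MICA|/|G|. Defined as 0 when both terms are the root
    (zero information on both sides)."""
    m = corpus.mica(ta, tb)
    ic_a = corpus.information_content(ta)
    ic_b = corpus.information_content(tb)
    if ic_a + ic_b == 0.0:
        return 0.0
    ic_m = corpus.information_content(m)
    p_m = len(corpus.term_genes[m]) / corpus.total_genes
    return (2.0 * ic_m / (ic_a + ic_b)) * (1.0 - p_m)


def most_informative_leaf(corpus: AnnotationCorpus, dag: OntologyDAG, term: str) -> str:
    """Max-IC leaf below a term (ties to the smallest id). When no leaf
    below carries annotations, falls back to the max-IC annotated
    descendant, which always exists (the term itself qualifies)."""
    tid = dag.resolve(term)
    leaves = [t for t in dag.leaves_below(tid) if t in corpus.ic]
    if not leaves:
        leaves = [t for t in dag.descendants(tid, include_self=True) if t in corpus.ic]
    if not leaves:
        raise UndefinedICError(f"no annotated descendant of {term}; MIL undefined")
    return max(leaves, key=lambda t: (corpus.ic[t], tuple(-b for b in t.encode())))


def sim_hrss(
    corpus: AnnotationCorpus,
    dag: OntologyDAG,
    ta: str,
    tb: str,
    dist: str = "ic",
) -> float:
    """Hybrid relative specificity similarity.

    With alpha = IC(MICA), beta = mean of IC(MIL_x) - IC(x) over both terms,
    and gamma = dist(MICA, ta) + dist(MICA, tb):

        sim = 1 / (1 + gamma) * alpha / (alpha + beta)

    ``dist='ic'`` (default) measures distance on the IC scale,
    dist(MICA, t) = IC(t) - IC(MICA); ``dist='edges'`` counts the fewest
    parent edges instead. Returns 0 when alpha + beta = 0 (only root-level
    information on both sides). Self-similarity of an annotated leaf is 1.
    """
    if dist not in ("ic", "edges"):
        raise ValueError(f"dist must be 'ic' or 'edges', got {dist!r}")
    m = corpus.mica(ta, tb)
    ic_m = corpus.information_content(m)
    ic_a = corpus.information_content(ta)
    ic_b = corpus.information_content(tb)
    mil_a = most_informative_leaf(corpus, dag, ta)
    mil_b = most_informative_leaf(corpus, dag, tb)
    alpha = ic_m
    beta = (
        (corpus.information_content(mil_a) - ic_a)
        + (corpus.information_content(mil_b) - ic_b)
    ) / 2.0
    if alpha + beta == 0.0:
        return 0.0
    if dist == "ic":
        gamma = (ic_a - ic_m) + (ic_b - ic_m)
    else:
        gamma = float(
            dag.min_edges_up(ta, m) + dag.min_edges_up(tb, m)
        )
    return (1.0 / (1.0 + gamma)) * (alpha / (alpha + beta))


#: Registry of term-level measure names usable in gene-level aggregation.
TERM_MEASURES = ("resnik", "schlicker", "wang", "hrss")


def term_similarity(
    name: str,
    corpus: AnnotationCorpus,
    dag: OntologyDAG,
    ta: str,
    tb: str,
    weights: EdgeWeights = DEFAULT_WEIGHTS,
) -> float:
    """Dispatch a term measure by registry name."""
    if name == "resnik":
        return sim_resnik(corpus, dag, ta, tb)
    if name == "schlicker":
        return sim_schlicker(corpus, dag, ta, tb)
    if name == "wang":
        return sim_wang(dag, ta, tb, weights)
    if name == "hrss":
        return sim_hrss(corpus, dag, ta, tb)
    raise ValueError(f"unknown term measure {name!r}; expected one of {TERM_MEASURES}")
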