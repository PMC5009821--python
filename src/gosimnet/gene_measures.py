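"""Gene-to-gene functional similarity.

Three set-based measures compare the genes' propagated annotation sets
(true path rule applied):

* **simUI** — Jaccard index |T1 ∩ T2| / |T1 ∪ T2|.
* **simGIC** — IC-weighted Jaccard, Σ IC over the intersection divided by
  Σ IC over the union.
* **TO** — raw term overlap |T1 ∩ T2| (a count; deliberately unnormalised).

Term-level measures (Resnik, Schlicker, Wang, HRSS) are lifted to gene
level over the genes' *direct* annotation sets by best-match averaging
(default) or by the maximum pairwise term score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .annotations import AnnotationCorpus
from .errors import EmptyCorpusError, MissingAnnotationError, UsageError
from .ontology import OntologyDAG
from .term_measures import DEFAULT_WEIGHTS, EdgeWeights, term_similarity

logger = logging.getLogger(__name__)

#: All directly computable gene-level measures ("intego2" layers on top).
SEED_MEASURES = ("resnik", "schlicker", "wang", "hrss", "simui", "simgic", "to")

#: Measures whose scores are guaranteed to lie in [0, 1].
NORMALIZED_MEASURES = frozenset({"schlicker", "wang", "hrss", "simui", "simgic", "intego2"})


def _pair(g1: str, g2: str) -> tuple[str, str]:
    return (g1, g2) if g1 <= g2 else (g2, g1)


@dataclass
class GeneSimilarityMatrix:
    """Symmetric gene-pair score table for one measure.

    Scores are stored once per unordered pair; the diagonal (self scores)
    is included. ``normalized`` records whether scores live in [0, 1] —
    the raw TO counts, for instance, do not.
    """

    measure: str
    genes: tuple[str, ...]
    scores: dict[tuple[str, str], float]
    normalized: bool
    skipped: tuple[str, ...] = ()

    def score(self, g1: str, g2: str) -> float:
        return self.scores[_pair(g1, g2)]

    def pairs(self) -> list[tuple[str, str]]:
        """Unordered off-diagonal pairs in sorted order."""
        return [p for p in sorted(self.scores) if p[0] != p[1]]

    def to_long(self) -> pd.DataFrame:
        rows = [
            {"gene1": a, "gene2": b, "score": s, "measure": self.measure}
            for (a, b), s in sorted(self.scores.items())
            if a != b
        ]
        return pd.DataFrame(rows, columns=["gene1", "gene2", "score", "measure"])

    def to_square(self) -> pd.DataFrame:
        genes = sorted(self.genes)
        df = pd.DataFrame(index=genes, columns=genes, dtype=float)
        for (a, b), s in self.scores.items():
            df.loc[a, b] = s
            df.loc[b, a] = s
        return df

    def write_tsv(self, path: str | Path, square: bool = False) -> None:
        if square:
            self.to_square().to_csv(path, sep="\t", index_label="gene")
        else:
            self.to_long().to_csv(path, sep="\t", index=False)


def read_similarity_tsv(path: str | Path) -> GeneSimilarityMatrix:
    """Read the long-format `gene1 gene2 score measure` TSV back."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene1", "gene2", "score", "measure"}
    if not required.issubset(df.columns):
        raise UsageError(f"{path}: expected columns {sorted(required)}")
    measures = df["measure"].unique()
    if len(measures) != 1:
        raise UsageError(f"{path}: expected one measure, found {list(measures)}")
    measure = str(measures[0])
    scores = {
        _pair(str(r.gene1), str(r.gene2)): float(r.score) for r in df.itertuples()
    }
    genes = tuple(sorted(set(df["gene1"].astype(str)) | set(df["gene2"].astype(str))))
    return GeneSimilarityMatrix(
        measure=measure,
        genes=genes,
        scores=scores,
        normalized=measure in NORMALIZED_MEASURES,
    )


# -- set-based measures ----------------------------------------------------


def _propagated(corpus: AnnotationCorpus, gene: str) -> set[str]:
    if not corpus.annotated(gene):
        raise MissingAnnotationError(f"gene {gene} has no annotations")
    return corpus.propagated[gene]


def sim_simui(corpus: AnnotationCorpus, g1: str, g2: str) -> float:
    """Jaccard index of the propagated annotation sets."""
    t1, t2 = _propagated(corpus, g1), _propagated(corpus, g2)
    return len(t1 & t2) / len(t1 | t2)


def sim_simgic(corpus: AnnotationCorpus, g1: str, g2: str) -> float:
    """IC-weighted Jaccard; 0 when both genes carry only zero-IC terms."""
    t1, t2 = _propagated(corpus, g1), _propagated(corpus, g2)
    # sorted summation: exactly symmetric in (g1, g2), stable across runs
    denom = sum(corpus.ic[t] for t in sorted(t1 | t2))
    if denom == 0.0:
        return 0.0
    return sum(corpus.ic[t] for t in sorted(t1 & t2)) / denom


def sim_to(corpus: AnnotationCorpus, g1: str, g2: str) -> int:
    """Count of shared propagated terms (unnormalised)."""
    t1, t2 = _propagated(corpus, g1), _propagated(corpus, g2)
    return len(t1 & t2)


# -- term-measure aggregation ----------------------------------------------


def aggregate_term_measure(
    term_sim: str,
    corpus: AnnotationCorpus,
    dag: OntologyDAG,
    g1: str,
    g2: str,
    strategy: str = "bma",
    weights: EdgeWeights = DEFAULT_WEIGHTS,
) -> float:
    """Lift a term measure to gene level over the DIRECT annotation sets.

    ``bma`` (best-match average): every term in each gene's set is matched
    to its best counterpart in the other set and the matches are averaged,
    (Σ_t1 max + Σ_t2 max) / (|T1| + |T2|). ``max`` takes the single best
    pairwise term score. Direct (unpropagated) sets are used because
    propagation would flood both sets with shared ancestors and inflate
    every best match.
    """
    if strategy not in ("bma", "max"):
        raise UsageError(f"unknown aggregation strategy {strategy!r}")
    if not corpus.annotated(g1):
        raise MissingAnnotationError(f"gene {g1} has no annotations")
    if not corpus.annotated(g2):
        raise MissingAnnotationError(f"gene {g2} has no annotations")
    t1 = sorted(corpus.direct[g1])
    t2 = sorted(corpus.direct[g2])
    cache: dict[tuple[str, str], float] = {}

    def s(a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        if key not in cache:
            cache[key] = term_similarity(term_sim, corpus, dag, a, b, weights)
        return cache[key]

    if strategy == "max":
        return max(s(a, b) for a in t1 for b in t2)
    row = sum(max(s(a, b) for b in t2) for a in t1)
    col = sum(max(s(a, b) for a in t1) for b in t2)
    return (row + col) / (len(t1) + len(t2))


# -- batch matrix ----------------------------------------------------------


def pairwise_matrix(
    corpus: AnnotationCorpus,
    dag: OntologyDAG,
    genes: Sequence[str],
    measure: str,
    strategy: str = "bma",
    weights: EdgeWeights = DEFAULT_WEIGHTS,
    pairs: Iterable[tuple[str, str]] | None = None,
) -> GeneSimilarityMatrix:
    """Score all unordered pairs (or an explicit pair list) of a gene set.

    Genes without annotations are dropped and reported in the matrix's
    ``skipped`` list rather than aborting the batch.
    """
    if measure not in SEED_MEASURES:
        raise UsageError(
            f"unknown measure {measure!r}; expected one of {SEED_MEASURES}"
        )
    seen: list[str] = []
    for g in genes:
        if g not in seen:
            seen.append(g)
    usable = sorted(g for g in seen if corpus.annotated(g))
    skipped = tuple(sorted(g for g in seen if not corpus.annotated(g)))
    if skipped:
        logger.warning(
            "pairwise_matrix(%s): %d gene(s) without GO annotations skipped: %s",
            measure, len(skipped), ", ".join(skipped),
        )
    if not usable:
        raise EmptyCorpusError("none of the input genes has GO annotations")

    def one(g1: str, g2: str) -> float:
        if measure == "simui":
            return sim_simui(corpus, g1, g2)
        if measure == "simgic":
            return sim_simgic(corpus, g1, g2)
        if measure == "to":
            return float(sim_to(corpus, g1, g2))
        return aggregate_term_measure(
            measure, corpus, dag, g1, g2, strategy=strategy, weights=weights
        )

    if pairs is None:
        wanted = [
            (usable[i], usable[j])
            for i in range(len(usable))
            for j in range(i, len(usable))
        ]
    else:
        wanted = [_pair(a, b) for a, b in pairs if a in usable and b in usable]
    scores = {_pair(a, b): one(a, b) for a, b in wanted}
    return GeneSimilarityMatrix(
        measure=measure,
        genes=tuple(usable),
        scores=scores,
        normalized=measure in NORMALIZED_MEASURES,
        skipped=skipped,
    )
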