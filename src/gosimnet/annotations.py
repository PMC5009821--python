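"""Annotation corpus: GAF parsing, true-path-rule propagation, IC, MICA.

A gene annotated to a term is implicitly annotated to every ancestor of
that term (true path rule). Information content of a term is

    IC(t) = -ln(|G_t| / |G|)

where ``G_t`` is the set of genes annotated (after propagation) to ``t``
and ``G`` the set of all annotated genes; the root therefore has IC 0.
Natural log is used throughout so worked values are reproducible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio.UniProt import GOA

from .errors import EmptyCorpusError, GafParseError, UndefinedICError
from .ontology import NAMESPACE_ASPECT, OntologyDAG

logger = logging.getLogger(__name__)


@dataclass
class AnnotationCorpus:
    """Direct and propagated gene-term annotations with the IC table.

    ``propagated`` maps each gene to its direct terms plus all of their
    ancestors; ``term_genes`` is the inverse map over propagated sets.
    ``ic`` covers every term with at least one propagated annotation.
    """

    dag: OntologyDAG
    direct: dict[str, set[str]]
    propagated: dict[str, set[str]] = field(init=False)
    term_genes: dict[str, set[str]] = field(init=False)
    ic: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        if not self.direct:
            raise EmptyCorpusError("no annotated genes in corpus")
        self.propagated = {}
        self.term_genes = {}
        for gene, terms in self.direct.items():
            prop: set[str] = set()
            for t in terms:
                prop |= self.dag.ancestors(t, include_self=True)
            self.propagated[gene] = prop
            for t in prop:
                self.term_genes.setdefault(t, set()).add(gene)
        n = self.total_genes
        self.ic = {
            t: -math.log(len(genes) / n) for t, genes in self.term_genes.items()
        }
        # -log(n/n) can land on -0.0; keep root IC exactly 0
        for t, v in self.ic.items():
            if v == 0.0:
                self.ic[t] = 0.0

    @property
    def total_genes(self) -> int:
        """|G|: genes with at least one annotation in the loaded namespace."""
        return len(self.direct)

    @property
    def genes(self) -> list[str]:
        return sorted(self.direct)

    def annotated(self, gene: str) -> bool:
        return gene in self.direct

    def information_content(self, term: str) -> float:
        term = self.dag.resolve(term)
        if term not in self.ic:
            raise UndefinedICError(
                f"term {term} has no propagated annotations; IC undefined"
            )
        return self.ic[term]

    def mica(self, ta: str, tb: str) -> str:
        """Most informative (max-IC) common ancestor; ties break to the
        lexicographically smallest id so results are deterministic."""
        common = self.dag.common_ancestors(ta, tb)
        scored = [t for t in common if t in self.ic]
        if not scored:
            raise UndefinedICError(
                f"no common ancestor of {ta}, {tb} has defined IC"
            )
        return max(scored, key=lambda t: (self.ic[t], _reverse_key(t)))


def _reverse_key(term_id: str) -> tuple[int, ...]:
    """Orders ids descending lexicographically, so max() picks the smallest."""
    return tuple(-b for b in term_id.encode())


# -- module-level operation surface ---------------------------------------


def information_content(corpus: AnnotationCorpus, term: str) -> float:
    return corpus.information_content(term)


def mica(corpus: AnnotationCorpus, dag: OntologyDAG, ta: str, tb: str) -> str:
    return corpus.mica(ta, tb)


def build_corpus(dag: OntologyDAG, direct: Mapping[str, Iterable[str]]) -> AnnotationCorpus:
    """Build a corpus from in-memory direct annotations, resolving alt_ids
    and dropping terms missing from the DAG (logged)."""
    cleaned: dict[str, set[str]] = {}
    dropped = 0
    for gene, terms in direct.items():
        kept = set()
        for t in terms:
            if t in dag:
                kept.add(dag.resolve(t))
            else:
                dropped += 1
        if kept:
            cleaned[gene] = kept
    if dropped:
        logger.info("build_corpus: dropped %d annotations to unknown terms", dropped)
    if not cleaned:
        raise EmptyCorpusError("no annotations matched the loaded ontology")
    return AnnotationCorpus(dag=dag, direct=cleaned)


def parse_gaf(
    path: str | Path,
    dag: OntologyDAG,
    evidence_exclude: Iterable[str] = (),
) -> AnnotationCorpus:
    """Parse a GAF 2.x file against a loaded single-namespace DAG.

    Rows with NOT qualifiers, rows with excluded evidence codes, and rows
    whose term is absent from the DAG are dropped (counts logged). Genes
    are keyed by GAF column 2 (DB object id); no synonym resolution.
    """
    path = Path(path)
    excluded = set(evidence_exclude)
    direct: dict[str, set[str]] = {}
    n_not = n_evidence = n_unknown = 0
    try:
        with open(path, encoding="utf-8") as fh:
            for rec in GOA.gafiterator(fh):
                qualifiers = rec.get("Qualifier", [])
                if any(q.startswith("NOT") for q in qualifiers if q):
                    n_not += 1
                    continue
                if rec["Evidence"] in excluded:
                    n_evidence += 1
                    continue
                term = rec["GO_ID"]
                if term not in dag:
                    n_unknown += 1
                    continue
                direct.setdefault(rec["DB_Object_ID"], set()).add(dag.resolve(term))
    except EmptyCorpusError:
        raise
    except Exception as exc:  # biopython raises bare Exceptions on bad columns
        raise GafParseError(f"cannot parse GAF file {path}: {exc}") from exc
    logger.info(
        "parse_gaf(%s): %d genes kept; dropped %d NOT rows, %d by evidence, "
        "%d with terms outside the %s DAG",
        path.name, len(direct), n_not, n_evidence, n_unknown, dag.namespace,
    )
    if not direct:
        raise EmptyCorpusError(
            f"{path}: no usable annotation rows after filtering "
            f"(NOT={n_not}, evidence={n_evidence}, unknown-term={n_unknown})"
        )
    return AnnotationCorpus(dag=dag, direct=direct)


def parse_annotation_tsv(path: str | Path, dag: OntologyDAG) -> AnnotationCorpus:
    """Parse the plain two-column gene<TAB>term format."""
    path = Path(path)
    direct: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise GafParseError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}"
                )
            direct.setdefault(parts[0], set()).add(parts[1])
    return build_corpus(dag, direct)


def write_gaf(corpus: AnnotationCorpus, path: str | Path, db: str = "gosimnet") -> None:
    """Write direct annotations as GAF 2.2 (round-trip support for tests)."""
    path = Path(path)
    aspect = NAMESPACE_ASPECT[corpus.dag.namespace]
    rows = []
    for gene in sorted(corpus.direct):
        for term in sorted(corpus.direct[gene]):
            rows.append(
                "\t".join(
                    [db, gene, gene, "", term, "GO_REF:0000000", "IEA", "",
                     aspect, "", "", "protein", "taxon:0", "20200101", db, "", ""]
                )
            )
    path.write_text("!gaf-version: 2.2\n" + "\n".join(rows) + "\n", encoding="utf-8")
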