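"""Deterministic synthetic ontologies, annotation corpora and EC groups.

Everything every other module needs for testing can be generated here
without downloading GO: a hand-checkable 7-term toy ontology (TOY1), seeded
random DAGs, and enzyme-classification-style gene groups whose functional
coherence is a dial. Fixtures are writable as OBO/GAF/TSV files so the
parsers are exercised, not bypassed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .annotations import AnnotationCorpus, build_corpus, write_gaf
from .errors import ConfigurationError
from .integrative import ECGroupedGenes
from .ontology import OntologyDAG, Term, write_obo


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic corpus.

    ``coherence`` is the probability that a group member draws each of its
    annotations from its own group's term pool rather than uniformly from
    all terms; 1 gives perfectly coherent EC groups, 0 removes all group
    signal. Identical spec + seed always yields byte-identical fixtures.
    """

    n_terms: int = 30
    max_parents: int = 2
    n_genes: int = 20
    annotations_per_gene: int = 3
    n_ec_groups: int = 4
    coherence: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_terms", "max_parents", "n_genes", "annotations_per_gene", "n_ec_groups"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {getattr(self, name)}")
        if not 0.0 <= self.coherence <= 1.0:
            raise ConfigurationError(f"coherence must be in [0, 1], got {self.coherence}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "FixtureSpec":
        return cls(**json.loads(Path(path).read_text()))


# -- TOY1: the frozen hand-checkable fixture -------------------------------

_TOY1_PARENTS = {
    "R": (),
    "A": (("R", "is_a"),),
    "B": (("R", "is_a"),),
    "A1": (("A", "is_a"),),
    "A2": (("A", "is_a"),),
    "B1": (("B", "is_a"),),
    "C": (("A", "is_a"), ("B", "is_a")),
}

_TOY1_ANNOTATIONS = {
    "g1": {"A1"}, "g2": {"A1"}, "g3": {"A2"}, "g4": {"B1"},
    "g5": {"C"}, "g6": {"B"}, "g7": {"A"}, "g8": {"R"},
}


def toy1() -> tuple[OntologyDAG, AnnotationCorpus]:
    """Seven-term ontology (root R; A, B; leaves A1, A2, B1 and the
    two-parent term C) with eight genes annotated one term each. All
    worked examples in the test suite are hand-computed on this fixture,
    so its structure is frozen."""
    terms = {
        tid: Term(id=tid, name=tid.lower(), namespace="biological_process", parents=parents)
        for tid, parents in _TOY1_PARENTS.items()
    }
    dag = OntologyDAG(terms=terms, namespace="biological_process")
    corpus = build_corpus(dag, _TOY1_ANNOTATIONS)
    return dag, corpus


# -- random generators -----------------------------------------------------


def random_ontology(spec: FixtureSpec) -> OntologyDAG:
    """Seeded random single-rooted DAG, acyclic by construction: term i
    may only choose parents among terms with smaller index."""
    rng = np.random.default_rng(spec.seed)
    ids = [f"GO:{i:07d}" for i in range(spec.n_terms)]
    terms: dict[str, Term] = {
        ids[0]: Term(id=ids[0], name="root", namespace="biological_process")
    }
    for i in range(1, spec.n_terms):
        k = int(rng.integers(1, min(i, spec.max_parents) + 1))
        parent_idx = rng.choice(i, size=k, replace=False)
        parents = tuple(
            sorted(
                (ids[int(j)], "part_of" if rng.random() < 0.2 else "is_a")
                for j in parent_idx
            )
        )
        terms[ids[i]] = Term(
            id=ids[i], name=f"term {i}", namespace="biological_process", parents=parents
        )
    return OntologyDAG(terms=terms, namespace="biological_process")


def _branched_ontology(spec: FixtureSpec) -> tuple[OntologyDAG, list[list[str]]]:
    """Ontology with one subtree ("functional module") per EC group.

    Term 0 is the root; the next ``n_ec_groups`` terms are branch anchors
    (children of the root); every later term joins a branch round-robin and
    picks its parents among earlier terms of the same branch. Returns the
    DAG and the per-branch term pools (anchors included).
    """
    rng = np.random.default_rng(spec.seed)
    k = spec.n_ec_groups
    if spec.n_terms - 1 < k:
        raise ConfigurationError(
            f"{spec.n_terms} terms cannot supply {k} branch pools"
        )
    ids = [f"GO:{i:07d}" for i in range(spec.n_terms)]
    terms: dict[str, Term] = {
        ids[0]: Term(id=ids[0], name="root", namespace="biological_process")
    }
    branches: list[list[str]] = [[] for _ in range(k)]
    for b in range(k):
        anchor = ids[1 + b]
        terms[anchor] = Term(
            id=anchor, name=f"module {b + 1}", namespace="biological_process",
            parents=((ids[0], "is_a"),),
        )
        branches[b].append(anchor)
    for i in range(1 + k, spec.n_terms):
        b = (i - 1 - k) % k
        pool = branches[b]
        n_par = int(rng.integers(1, min(len(pool), spec.max_parents) + 1))
        chosen = rng.choice(len(pool), size=n_par, replace=False)
        parents = tuple(
            sorted(
                (pool[int(j)], "part_of" if rng.random() < 0.2 else "is_a")
                for j in chosen
            )
        )
        terms[ids[i]] = Term(
            id=ids[i], name=f"term {i}", namespace="biological_process",
            parents=parents,
        )
        branches[b].append(ids[i])
    return OntologyDAG(terms=terms, namespace="biological_process"), branches


def ec_grouped_corpus(spec: FixtureSpec) -> tuple[AnnotationCorpus, ECGroupedGenes]:
    """EC-style grouped corpus on a branch-structured ontology.

    Each group owns a disjoint pool of specific terms — the terms of its
    own subtree under the root, emulating a functional module. Each gene
    draws ``annotations_per_gene`` terms; each draw comes from the gene's
    group pool with probability ``coherence`` and uniformly from all
    non-root terms otherwise.
    """
    if spec.n_ec_groups < 2:
        raise ConfigurationError("ec_grouped_corpus needs n_ec_groups >= 2")
    genes_per_group = spec.n_genes // spec.n_ec_groups
    if genes_per_group < 2:
        raise ConfigurationError(
            f"{spec.n_genes} genes across {spec.n_ec_groups} groups leaves "
            f"{genes_per_group} per group; need >= 2"
        )
    dag, pools = _branched_ontology(spec)
    rng = np.random.default_rng(spec.seed + 1)  # independent of the DAG draw
    non_root = sorted(set(dag.terms) - {dag.root})
    direct: dict[str, set[str]] = {}
    labels: dict[str, str] = {}
    gi = 0
    for g in range(spec.n_ec_groups):
        label = f"EC{g + 1}"
        for _ in range(genes_per_group):
            gene = f"g{gi:03d}"
            gi += 1
            labels[gene] = label
            terms: set[str] = set()
            while len(terms) < min(spec.annotations_per_gene, len(non_root)):
                if rng.random() < spec.coherence:
                    terms.add(pools[g][int(rng.integers(len(pools[g])))])
                else:
                    terms.add(non_root[int(rng.integers(len(non_root)))])
            direct[gene] = terms
    return build_corpus(dag, direct), ECGroupedGenes(labels)


# -- file output -----------------------------------------------------------


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fixture_files(
    spec: FixtureSpec, outdir: str | Path, preset: str | None = None
) -> dict[str, str]:
    """Write OBO + GAF (+ EC TSV) files and a manifest of SHA-256 hashes.

    ``preset='toy1'`` writes the frozen toy fixture instead of a random
    one (no EC groups in that case). Returns the manifest mapping.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if preset == "toy1":
        dag, corpus = toy1()
        ec = None
    elif preset is None:
        corpus, ec = ec_grouped_corpus(spec)
        dag = corpus.dag
    else:
        raise ConfigurationError(f"unknown preset {preset!r}")
    write_obo(dag, outdir / "ontology.obo")
    write_gaf(corpus, outdir / "annotations.gaf")
    files = [outdir / "ontology.obo", outdir / "annotations.gaf"]
    if ec is not None:
        ec.write_tsv(outdir / "ec_groups.tsv")
        files.append(outdir / "ec_groups.tsv")
    spec.to_json(outdir / "fixture_spec.json")
    files.append(outdir / "fixture_spec.json")
    manifest = {f.name: _sha256(f) for f in files}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
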