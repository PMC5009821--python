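"""Rank-based integrative gene similarity ("intego2" in the measure registry).

No single GO similarity measure wins on every gene pair, so the integrative
measure combines them in three steps:

1. Score every gene pair with each available seed measure and convert each
   measure's column to ranks (rank 1 = most similar; ties get the mean of
   the tied positions). The normalised rank score is
   ``r' = 1 - (rank - 1)/(N - 1)``, which is invariant to any strictly
   monotone rescaling of the raw measure.
2. For each pair, keep the seed measures whose rank agrees with the
   cross-measure consensus: those within a window of ``delta * N`` of the
   median rank. A pair whose measures all disagree falls back to the single
   measure closest to the median, so every pair keeps at least one measure.
3. Integrate the selected measures additively: the integrated score is the
   weighted mean of their normalised rank scores.

The per-measure weights are learned on a training set of genes with known
Enzyme Commission (EC) groups, by maximising the separation between mean
within-group and mean between-group integrated similarity with a seeded
simulated-annealing search over the weight simplex.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .annotations import AnnotationCorpus
from .errors import (
    AlignmentError,
    ConfigurationError,
    DegenerateModelError,
    EmptyCorpusError,
    GosimnetError,
    UsageError,
)
from .gene_measures import (
    NORMALIZED_MEASURES,
    SEED_MEASURES,
    GeneSimilarityMatrix,
    pairwise_matrix,
)
from .ontology import OntologyDAG

logger = logging.getLogger(__name__)

#: Minimum weight kept during search so no selected pair becomes unscorable.
_WEIGHT_FLOOR = 1e-9


@dataclass(frozen=True)
class ECGroupedGenes:
    """Gene -> EC-group label map used as functional ground truth."""

    labels: Mapping[str, str]

    def __post_init__(self) -> None:
        groups: dict[str, int] = {}
        for label in self.labels.values():
            groups[label] = groups.get(label, 0) + 1
        small = sorted(g for g, n in groups.items() if n < 2)
        if len(groups) < 2 or small:
            raise ConfigurationError(
                f"EC grouping needs >= 2 groups of >= 2 genes; got "
                f"{len(groups)} group(s), undersized: {small}"
            )

    @property
    def genes(self) -> list[str]:
        return sorted(self.labels)

    @property
    def groups(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for gene, label in self.labels.items():
            out.setdefault(label, set()).add(gene)
        return out

    def write_tsv(self, path: str | Path) -> None:
        lines = [f"{g}\t{self.labels[g]}" for g in self.genes]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ECGroupedGenes":
        labels: dict[str, str] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            if not raw or raw.startswith("#"):
                continue
            parts = raw.split("\t")
            if len(parts) != 2:
                raise UsageError(f"{path}:{lineno}: expected gene<TAB>group")
            labels[parts[0]] = parts[1]
        return cls(labels)


@dataclass
class RankMatrix:
    """Per-measure rankings of one shared gene-pair list.

    ``ranks[i, j]`` is pair i's rank under measure j (1 = highest raw
    score; ties averaged); ``rprime`` holds the normalised rank scores."""

    pairs: tuple[tuple[str, str], ...]
    measures: tuple[str, ...]
    ranks: np.ndarray
    rprime: np.ndarray

    def pair_index(self, pair: tuple[str, str]) -> int:
        key = tuple(sorted(pair))
        try:
            return self.pairs.index(key)  # type: ignore[arg-type]
        except ValueError:
            raise AlignmentError(f"pair {pair} not in rank matrix")


@dataclass
class SeedSelection:
    """Boolean mask: which measures were selected for which pair."""

    pairs: tuple[tuple[str, str], ...]
    measures: tuple[str, ...]
    mask: np.ndarray

    def selected(self, pair: tuple[str, str]) -> tuple[str, ...]:
        key = tuple(sorted(pair))
        i = self.pairs.index(key)  # type: ignore[arg-type]
        return tuple(m for m, on in zip(self.measures, self.mask[i]) if on)


@dataclass
class IntegrationModel:
    """Trained integration parameters: per-measure weights and the grouping
    window delta, plus reproducibility metadata."""

    weights: dict[str, float]
    delta: float = 0.2
    seed: int | None = None
    iterations: int | None = None
    objective: float | None = None

    def __post_init__(self) -> None:
        if not self.weights or all(w <= 0 for w in self.weights.values()):
            raise DegenerateModelError("model needs at least one positive weight")
        if any(w < 0 for w in self.weights.values()):
            raise DegenerateModelError("weights must be non-negative")
        if not 0.0 < self.delta <= 1.0:
            raise ConfigurationError(f"delta must be in (0, 1], got {self.delta}")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "weights": {m: self.weights[m] for m in sorted(self.weights)},
            "delta": self.delta,
            "seed": self.seed,
            "iterations": self.iterations,
            "objective": self.objective,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "IntegrationModel":
        return cls(**json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class SearchParams:
    """Simulated-annealing knobs: iteration budget, geometric cooling rate,
    starting temperature, and the Gaussian proposal step size."""

    iterations: int = 2000
    cooling: float = 0.995
    initial_temp: float = 0.05
    step: float = 0.1

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ConfigurationError("search budget must be >= 1 iteration")
        if not 0.0 < self.cooling <= 1.0:
            raise ConfigurationError("cooling rate must be in (0, 1]")


# -- step 1: rank matrix ---------------------------------------------------


def build_rank_matrix(
    matrices: Mapping[str, GeneSimilarityMatrix],
) -> RankMatrix:
    """Rank every measure's scores over the shared off-diagonal pair set."""
    if not matrices:
        raise EmptyCorpusError("no similarity matrices to rank")
    measures = tuple(sorted(matrices))
    pair_sets = {m: tuple(matrices[m].pairs()) for m in measures}
    pairs = pair_sets[measures[0]]
    for m in measures[1:]:
        if pair_sets[m] != pairs:
            raise AlignmentError(
                f"measure {m} covers different gene pairs than {measures[0]}"
            )
    n = len(pairs)
    ranks = np.empty((n, len(measures)))
    for j, m in enumerate(measures):
        scores = np.array([matrices[m].scores[p] for p in pairs], dtype=float)
        ranks[:, j] = rankdata(-scores, method="average")
    rprime = np.ones_like(ranks) if n == 1 else 1.0 - (ranks - 1.0) / (n - 1.0)
    return RankMatrix(pairs=pairs, measures=measures, ranks=ranks, rprime=rprime)


# -- step 2: per-pair seed selection ---------------------------------------


def select_seed_measures(rank_matrix: RankMatrix, delta: float = 0.2) -> SeedSelection:
    """Keep, per pair, the measures ranking it within ``delta * N`` of the
    cross-measure median rank; fall back to the single nearest measure."""
    if not 0.0 < delta <= 1.0:
        raise ConfigurationError(f"delta must be in (0, 1], got {delta}")
    ranks = rank_matrix.ranks
    n_pairs = ranks.shape[0]
    med = np.median(ranks, axis=1, keepdims=True)
    dev = np.abs(ranks - med)
    mask = dev <= delta * n_pairs
    empty = ~mask.any(axis=1)
    if empty.any():
        nearest = dev[empty].argmin(axis=1)
        mask[np.flatnonzero(empty), nearest] = True
    return SeedSelection(
        pairs=rank_matrix.pairs, measures=rank_matrix.measures, mask=mask
    )


# -- step 3: additive integration ------------------------------------------


def _weight_vector(
    weights: Mapping[str, float], measures: Sequence[str]
) -> np.ndarray:
    w = np.array([weights.get(m, 0.0) for m in measures], dtype=float)
    if (w < 0).any():
        raise DegenerateModelError("weights must be non-negative")
    return w


def _integrate_all(
    rprime: np.ndarray, mask: np.ndarray, w: np.ndarray
) -> np.ndarray:
    """Weighted mean of r' over each pair's selected measures."""
    sel_w = mask * w
    denom = sel_w.sum(axis=1)
    if (denom == 0).any():
        bad = int(np.flatnonzero(denom == 0)[0])
        raise DegenerateModelError(
            f"all selected measures have zero weight for pair index {bad}"
        )
    return (rprime * sel_w).sum(axis=1) / denom


def integrate_pair(
    model: IntegrationModel,
    rank_matrix: RankMatrix,
    selection: SeedSelection,
    pair: tuple[str, str],
) -> float:
    """Integrated score of one pair: Σ w_m r'(pair, m) / Σ w_m over the
    pair's selected measures."""
    i = rank_matrix.pair_index(pair)
    w = _weight_vector(model.weights, rank_matrix.measures)
    return float(
        _integrate_all(
            rank_matrix.rprime[i : i + 1], selection.mask[i : i + 1], w
        )[0]
    )


# -- training --------------------------------------------------------------


def _group_masks(
    pairs: Sequence[tuple[str, str]], ec_groups: ECGroupedGenes
) -> tuple[np.ndarray, np.ndarray]:
    labels = ec_groups.labels
    within = np.array(
        [a in labels and b in labels and labels[a] == labels[b] for a, b in pairs]
    )
    between = np.array(
        [a in labels and b in labels and labels[a] != labels[b] for a, b in pairs]
    )
    if not within.any() or not between.any():
        raise ConfigurationError(
            "EC groups yield no within-group or no between-group pairs"
        )
    return within, between


def separation_objective(
    weights: Mapping[str, float],
    delta: float,
    matrices: Mapping[str, GeneSimilarityMatrix],
    ec_groups: ECGroupedGenes,
) -> float:
    """Mean integrated similarity of within-group pairs minus that of
    between-group pairs. Positive values mean the weighted integration
    ranks functionally related (same-EC) genes above unrelated ones."""
    for gene in ec_groups.genes:
        for m, mat in matrices.items():
            if gene not in mat.genes:
                raise ConfigurationError(
                    f"EC-labelled gene {gene} missing from matrix {m!r}"
                )
    rm = build_rank_matrix(matrices)
    sel = select_seed_measures(rm, delta)
    w = _weight_vector(weights, rm.measures)
    integrated = _integrate_all(rm.rprime, sel.mask, w)
    within, between = _group_masks(rm.pairs, ec_groups)
    return float(integrated[within].mean() - integrated[between].mean())


def train_weights(
    matrices: Mapping[str, GeneSimilarityMatrix],
    ec_groups: ECGroupedGenes,
    delta: float = 0.2,
    search_params: SearchParams | None = None,
    seed: int = 0,
) -> IntegrationModel:
    """Learn seed-measure weights by seeded simulated annealing.

    The search walks the weight simplex with Gaussian proposals, Metropolis
    acceptance on the separation objective, and geometric cooling. It
    starts from uniform weights and keeps the best state seen, so the
    trained objective can never fall below the uniform-weight objective.
    Weights are renormalised to sum to 1 (the weighted mean is invariant to
    scale, so this is pure identifiability).
    """
    params = search_params or SearchParams()
    measures = tuple(sorted(matrices))
    k = len(measures)
    rm = build_rank_matrix(matrices)
    sel = select_seed_measures(rm, delta)
    within, between = _group_masks(rm.pairs, ec_groups)

    def objective(w: np.ndarray) -> float:
        integrated = _integrate_all(rm.rprime, sel.mask, w)
        return float(integrated[within].mean() - integrated[between].mean())

    uniform = np.full(k, 1.0 / k)
    if k == 1:
        obj = objective(uniform)
        return IntegrationModel(
            weights={measures[0]: 1.0}, delta=delta, seed=seed,
            iterations=0, objective=obj,
        )

    rng = np.random.default_rng(seed)
    current = uniform.copy()
    current_obj = objective(current)
    best, best_obj = current.copy(), current_obj
    temp = params.initial_temp
    for _ in range(params.iterations):
        proposal = np.clip(
            current + rng.normal(0.0, params.step, size=k), _WEIGHT_FLOOR, None
        )
        proposal /= proposal.sum()
        obj = objective(proposal)
        delta_obj = obj - current_obj
        if delta_obj > 0 or rng.random() < math.exp(delta_obj / max(temp, 1e-12)):
            current, current_obj = proposal, obj
            if obj > best_obj:
                best, best_obj = proposal.copy(), obj
        temp *= params.cooling
    best /= best.sum()
    logger.info(
        "train_weights: objective %.4f (uniform %.4f) after %d iterations, seed %d",
        best_obj, objective(uniform), params.iterations, seed,
    )
    return IntegrationModel(
        weights=dict(zip(measures, best.tolist())),
        delta=delta,
        seed=seed,
        iterations=params.iterations,
        objective=best_obj,
    )


# -- end-to-end matrix -----------------------------------------------------


def compute_seed_matrices(
    corpus: AnnotationCorpus,
    dag: OntologyDAG,
    genes: Sequence[str],
    measures: Sequence[str] = SEED_MEASURES,
    strategy: str = "bma",
) -> dict[str, GeneSimilarityMatrix]:
    """All requested seed matrices; a measure that fails on this corpus is
    dropped with a warning rather than aborting the integration."""
    out: dict[str, GeneSimilarityMatrix] = {}
    for m in measures:
        try:
            out[m] = pairwise_matrix(corpus, dag, genes, m, strategy=strategy)
        except GosimnetError as exc:
            logger.warning("seed measure %s unavailable, dropped: %s", m, exc)
    if not out:
        raise EmptyCorpusError("no seed measure could be computed")
    return out


def intego2_matrix(
    corpus: AnnotationCorpus,
    dag: OntologyDAG,
    genes: Sequence[str],
    model: IntegrationModel | None = None,
    measures: Sequence[str] = SEED_MEASURES,
    delta: float = 0.2,
    strategy: str = "bma",
) -> GeneSimilarityMatrix:
    """Integrated similarity matrix over a gene set.

    Without a trained model, all available seed measures get equal weight.
    Self-similarity is defined as 1 (rank integration is only meaningful
    across distinct pairs). Scores lie in [0, 1] by construction.
    """
    seed_mats = compute_seed_matrices(corpus, dag, genes, measures, strategy)
    if model is not None:
        delta = model.delta
        weights = {m: model.weights.get(m, 0.0) for m in seed_mats}
        if all(w == 0.0 for w in weights.values()):
            raise DegenerateModelError(
                "model assigns zero weight to every available seed measure"
            )
    else:
        weights = {m: 1.0 for m in seed_mats}
    rm = build_rank_matrix(seed_mats)
    sel = select_seed_measures(rm, delta)
    w = _weight_vector(weights, rm.measures)
    # a selected-but-zero-weight measure must not zero out a pair: re-select
    # among positively weighted measures only
    positive = w > 0
    mask = sel.mask & positive
    empty = ~mask.any(axis=1)
    if empty.any():
        dev = np.abs(rm.ranks - np.median(rm.ranks, axis=1, keepdims=True))
        dev = np.where(positive, dev, np.inf)
        nearest = dev[empty].argmin(axis=1)
        mask[np.flatnonzero(empty), nearest] = True
    integrated = _integrate_all(rm.rprime, mask, w)
    usable = sorted(next(iter(seed_mats.values())).genes)
    scores = {pair: float(s) for pair, s in zip(rm.pairs, integrated)}
    for g in usable:
        scores[(g, g)] = 1.0
    skipped = next(iter(seed_mats.values())).skipped
    return GeneSimilarityMatrix(
        measure="intego2",
        genes=tuple(usable),
        scores=scores,
        normalized=True,
        skipped=skipped,
    )
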