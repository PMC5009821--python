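"""Rank integration: ranking, seed selection, weighting, training."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gosimnet import (
    ECGroupedGenes,
    FixtureSpec,
    IntegrationModel,
    SearchParams,
    build_rank_matrix,
    ec_grouped_corpus,
    intego2_matrix,
    integrate_pair,
    pairwise_matrix,
    select_seed_measures,
    separation_objective,
    train_weights,
)
from gosimnet.errors import (
    AlignmentError,
    ConfigurationError,
    DegenerateModelError,
)
from gosimnet.gene_measures import GeneSimilarityMatrix


def _matrix(measure, scores, genes=None):
    """Build a similarity matrix from {(g1,g2): score} directly."""
    if genes is None:
        genes = tuple(sorted({g for p in scores for g in p}))
    full = dict(scores)
    for g in genes:
        full.setdefault((g, g), 1.0)
    return GeneSimilarityMatrix(
        measure=measure, genes=tuple(genes), scores=full, normalized=True
    )


PAIRS3 = [("a", "b"), ("a", "c"), ("b", "c")]


def test_rank_matrix_basic_and_ties():
    m = _matrix("m1", dict(zip(PAIRS3, [0.9, 0.5, 0.1])))
    rm = build_rank_matrix({"m1": m})
    assert rm.ranks[:, 0].tolist() == [1.0, 2.0, 3.0]
    assert rm.rprime[:, 0].tolist() == [1.0, 0.5, 0.0]
    tied = _matrix("m1", dict(zip(PAIRS3, [0.7, 0.7, 0.2])))
    rm2 = build_rank_matrix({"m1": tied})
    assert rm2.ranks[:, 0].tolist() == [1.5, 1.5, 3.0]


def test_identical_matrices_rank_identically():
    scores = dict(zip(PAIRS3, [0.9, 0.5, 0.1]))
    rm = build_rank_matrix({"m1": _matrix("m1", scores), "m2": _matrix("m2", scores)})
    assert np.array_equal(rm.ranks[:, 0], rm.ranks[:, 1])


def test_mismatched_pair_sets_raise():
    m1 = _matrix("m1", dict(zip(PAIRS3, [0.9, 0.5, 0.1])))
    m2 = _matrix("m2", {("a", "b"): 0.5, ("a", "d"): 0.1, ("b", "d"): 0.2})
    with pytest.raises(AlignmentError):
        build_rank_matrix({"m1": m1, "m2": m2})


def test_rank_normalization_invariant_to_monotone_transform():
    rng = np.random.default_rng(7)
    pairs = [(f"g{i}", f"g{j}") for i in range(6) for j in range(i + 1, 6)]
    raw = dict(zip(pairs, rng.random(len(pairs))))
    warped = {p: math.exp(3 * s) for p, s in raw.items()}
    rm1 = build_rank_matrix({"m": _matrix("m", raw)})
    rm2 = build_rank_matrix({"m": _matrix("m", warped)})
    assert np.allclose(rm1.rprime, rm2.rprime)


@settings(derandomize=True, max_examples=50)
@given(
    # grid-valued scores: distinct values stay distinct after the affine
    # map (a tiny float score would be absorbed by the shift, creating ties)
    scores=st.lists(
        st.integers(min_value=0, max_value=64).map(lambda i: i / 64),
        min_size=2, max_size=20,
    ),
    scale=st.floats(min_value=0.1, max_value=5.0, allow_nan=False),
    shift=st.floats(min_value=-2.0, max_value=2.0, allow_nan=False),
)
def test_rprime_invariant_under_affine_rescaling(scores, scale, shift):
    pairs = [(f"a{i}", f"b{i}") for i in range(len(scores))]
    raw = _matrix("m", dict(zip(pairs, scores)))
    warped = _matrix("m", {p: scale * s + shift for p, s in zip(pairs, scores)})
    rm1 = build_rank_matrix({"m": raw})
    rm2 = build_rank_matrix({"m": warped})
    assert np.allclose(rm1.rprime, rm2.rprime)
    assert ((rm1.rprime >= 0) & (rm1.rprime <= 1)).all()


def test_seed_selection_agreement_outlier_and_fallback():
    n = 10
    pairs = [(f"g{i}", f"h{i}") for i in range(n)]
    rng = np.random.default_rng(0)
    base = dict(zip(pairs, np.linspace(1.0, 0.1, n)))
    agree = {
        m: _matrix(m, base) for m in ("m1", "m2", "m3")
    }
    sel = select_seed_measures(build_rank_matrix(agree), delta=0.2)
    assert sel.mask.all()
    # m3 ranks the top pair last while m1/m2 rank it first -> m3 excluded there
    flipped = dict(base)
    top = pairs[0]
    flipped[top] = 0.0
    disagree = {"m1": _matrix("m1", base), "m2": _matrix("m2", base),
                "m3": _matrix("m3", flipped)}
    rm = build_rank_matrix(disagree)
    sel2 = select_seed_measures(rm, delta=0.2)
    assert sel2.selected(top) == ("m1", "m2")
    # single measure: always selected (fallback keeps every pair non-empty)
    sel3 = select_seed_measures(build_rank_matrix({"m1": _matrix("m1", base)}), 0.2)
    assert sel3.mask.all()


def test_integrate_pair_weighted_means():
    pairs = PAIRS3
    m1 = _matrix("m1", dict(zip(pairs, [0.9, 0.5, 0.1])))  # r' = 1, .5, 0
    m2 = _matrix("m2", dict(zip(pairs, [0.1, 0.5, 0.9])))  # r' = 0, .5, 1
    rm = build_rank_matrix({"m1": m1, "m2": m2})
    sel = select_seed_measures(rm, delta=1.0)  # keep everything
    equal = IntegrationModel(weights={"m1": 1.0, "m2": 1.0})
    assert integrate_pair(equal, rm, sel, ("a", "b")) == pytest.approx(0.5)
    assert integrate_pair(equal, rm, sel, ("a", "c")) == pytest.approx(0.5)
    skewed = IntegrationModel(weights={"m1": 3.0, "m2": 1.0})
    assert integrate_pair(skewed, rm, sel, ("a", "b")) == pytest.approx(0.75)
    single = IntegrationModel(weights={"m1": 1.0, "m2": 0.0})
    assert integrate_pair(single, rm, sel, ("b", "c")) == pytest.approx(0.0)


def test_separation_objective_hand_value():
    # 2 EC groups x 2 genes; single measure, so integrated scores are the
    # normalised ranks: within pairs rank 1-2 (r' = 1.0, 0.8), between pairs
    # rank 3-6 (r' = 0.6, 0.4, 0.2, 0.0) -> 0.9 - 0.3 = 0.6
    scores = {
        ("a1", "a2"): 0.9, ("b1", "b2"): 0.8,              # within
        ("a1", "b1"): 0.4, ("a1", "b2"): 0.3,              # between
        ("a2", "b1"): 0.2, ("a2", "b2"): 0.1,
    }
    ec = ECGroupedGenes({"a1": "E1", "a2": "E1", "b1": "E2", "b2": "E2"})
    obj = separation_objective({"m": 1.0}, 1.0, {"m": _matrix("m", scores)}, ec)
    assert obj == pytest.approx(0.6)


def test_separation_objective_zero_when_scores_identical():
    scores = {p: 0.5 for p in
              [("a1", "a2"), ("b1", "b2"), ("a1", "b1"),
               ("a1", "b2"), ("a2", "b1"), ("a2", "b2")]}
    ec = ECGroupedGenes({"a1": "E1", "a2": "E1", "b1": "E2", "b2": "E2"})
    assert separation_objective({"m": 1.0}, 1.0, {"m": _matrix("m", scores)}, ec) == 0.0


def test_ec_grouping_validation():
    with pytest.raises(ConfigurationError):
        ECGroupedGenes({"a": "E1", "b": "E1"})  # one group
    with pytest.raises(ConfigurationError):
        ECGroupedGenes({"a": "E1", "b": "E1", "c": "E2"})  # undersized group


def test_ec_tsv_round_trip(tmp_path):
    ec = ECGroupedGenes({"a1": "E1", "a2": "E1", "b1": "E2", "b2": "E2"})
    p = tmp_path / "ec.tsv"
    ec.write_tsv(p)
    assert dict(ECGroupedGenes.read_tsv(p).labels) == dict(ec.labels)


def _training_setup(seed, coherence=0.9):
    spec = FixtureSpec(n_terms=30, n_genes=8, n_ec_groups=2, coherence=coherence,
                       seed=seed)
    corpus, ec = ec_grouped_corpus(spec)
    informative = pairwise_matrix(corpus, corpus.dag, ec.genes, "simui")
    rng = np.random.default_rng(seed + 500)
    noise = GeneSimilarityMatrix(
        measure="noise",
        genes=informative.genes,
        scores={p: (1.0 if p[0] == p[1] else float(rng.random()))
                for p in informative.scores},
        normalized=True,
    )
    return {"simui": informative, "noise": noise}, ec


def test_training_is_deterministic_given_seed(tmp_path):
    matrices, ec = _training_setup(seed=1)
    m1 = train_weights(matrices, ec, seed=42,
                       search_params=SearchParams(iterations=200))
    m2 = train_weights(matrices, ec, seed=42,
                       search_params=SearchParams(iterations=200))
    assert m1.weights == m2.weights and m1.objective == m2.objective
    p = tmp_path / "model.json"
    m1.to_json(p)
    assert IntegrationModel.from_json(p).weights == pytest.approx(m1.weights)


def test_trained_objective_never_below_uniform():
    matrices, ec = _training_setup(seed=3)
    model = train_weights(matrices, ec, seed=0,
                          search_params=SearchParams(iterations=300))
    uniform = separation_objective(
        {m: 0.5 for m in matrices}, model.delta, matrices, ec
    )
    assert model.objective >= uniform - 1e-12


def test_training_upweights_the_informative_measure():
    wins = 0
    for seed in range(5):
        matrices, ec = _training_setup(seed=seed)
        model = train_weights(matrices, ec, seed=seed,
                              search_params=SearchParams(iterations=400))
        if model.weights["simui"] > model.weights["noise"]:
            wins += 1
    assert wins >= 4


def test_single_measure_training_is_trivial():
    matrices, ec = _training_setup(seed=2)
    model = train_weights({"simui": matrices["simui"]}, ec, seed=0)
    assert model.weights == {"simui": 1.0}
    assert model.iterations == 0


def test_duplicated_measure_objective_invariant_to_weights():
    matrices, ec = _training_setup(seed=4)
    twin = {"m1": matrices["simui"], "m2": matrices["simui"]}
    single = separation_objective({"simui": 1.0}, 0.2,
                                  {"simui": matrices["simui"]}, ec)
    for w in ({"m1": 1.0, "m2": 1.0}, {"m1": 0.9, "m2": 0.1}):
        assert separation_objective(w, 0.2, twin, ec) == pytest.approx(single)


def test_search_budget_must_be_positive():
    with pytest.raises(ConfigurationError):
        SearchParams(iterations=0)


def test_intego2_single_measure_degeneracy(toy_corpus, toy_dag):
    genes = ["g1", "g3", "g4", "g5"]
    integrated = intego2_matrix(toy_corpus, toy_dag, genes, measures=["simui"])
    base = pairwise_matrix(toy_corpus, toy_dag, genes, "simui")
    rm = build_rank_matrix({"simui": base})
    for i, pair in enumerate(rm.pairs):
        assert integrated.scores[pair] == rm.rprime[i, 0]
    assert integrated.measure == "intego2"


def test_intego2_invariants_and_measure_dropout(toy_corpus, toy_dag):
    genes = ["g1", "g2", "g3", "g4", "g5", "g6"]
    full = intego2_matrix(toy_corpus, toy_dag, genes)
    reduced = intego2_matrix(
        toy_corpus, toy_dag, genes,
        measures=["resnik", "schlicker", "wang", "simui", "simgic", "to"],
    )
    for m in (full, reduced):
        for (a, b), s in m.scores.items():
            assert 0.0 <= s <= 1.0
            assert m.score(a, b) == m.score(b, a)
        for g in m.genes:
            assert m.score(g, g) == 1.0


def test_intego2_order_independent(toy_corpus, toy_dag):
    genes = ["g1", "g3", "g4", "g5"]
    a = intego2_matrix(toy_corpus, toy_dag, genes)
    b = intego2_matrix(toy_corpus, toy_dag, list(reversed(genes)))
    assert a.scores == b.scores


def test_intego2_rejects_all_zero_weight_model(toy_corpus, toy_dag):
    model = IntegrationModel(weights={"unrelated": 1.0})
    with pytest.raises(DegenerateModelError):
        intego2_matrix(toy_corpus, toy_dag, ["g1", "g3", "g4"],
                       model=model, measures=["simui"])
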