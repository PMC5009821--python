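"""Gene-level measures: worked values, set identities, matrix behaviour."""

import itertools

import pytest

from gosimnet import (
    aggregate_term_measure,
    pairwise_matrix,
    read_similarity_tsv,
    sim_simgic,
    sim_simui,
    sim_to,
)
from gosimnet.annotations import build_corpus
from gosimnet.errors import EmptyCorpusError, MissingAnnotationError, UsageError

from conftest import make_random_corpus
from _oracles import jaccard, toy1_expected, TOY1_PROPAGATED

EXPECTED = toy1_expected()


@pytest.mark.parametrize(
    "fn,g1,g2,key",
    [
        (sim_simui, "g1", "g3", "simui_g1_g3"),
        (sim_simui, "g1", "g4", "simui_g1_g4"),
        (sim_simgic, "g1", "g3", "simgic_g1_g3"),
        (sim_to, "g1", "g3", "to_g1_g3"),
        (sim_to, "g1", "g4", "to_g1_g4"),
    ],
)
def test_set_measure_worked_values(toy_corpus, fn, g1, g2, key):
    assert fn(toy_corpus, g1, g2) == pytest.approx(EXPECTED[key], abs=1e-4)


def test_self_similarity(toy_corpus):
    assert sim_simui(toy_corpus, "g1", "g1") == 1.0
    assert sim_simgic(toy_corpus, "g1", "g1") == 1.0
    assert sim_to(toy_corpus, "g1", "g1") == len(TOY1_PROPAGATED["g1"])
    # g8 carries only the zero-IC root: zero-information convention
    assert sim_simgic(toy_corpus, "g8", "g8") == 0.0


def test_unannotated_gene_raises(toy_corpus):
    with pytest.raises(MissingAnnotationError, match="gX"):
        sim_simui(toy_corpus, "g1", "gX")


@pytest.mark.parametrize(
    "measure,g1,g2,key",
    [("resnik", "g1", "g5", "agg_resnik_g1_g5"), ("wang", "g1", "g3", "wang_A1_A2")],
)
def test_aggregation_reduces_to_term_score_for_singletons(
    toy_corpus, toy_dag, measure, g1, g2, key
):
    s = aggregate_term_measure(measure, toy_corpus, toy_dag, g1, g2)
    assert s == pytest.approx(EXPECTED[key], abs=1e-4)


def test_bma_self_match_is_one(toy_corpus, toy_dag):
    for g in ["g1", "g5"]:
        assert aggregate_term_measure("wang", toy_corpus, toy_dag, g, g) == pytest.approx(1.0)


def test_unknown_aggregation_strategy(toy_corpus, toy_dag):
    with pytest.raises(UsageError):
        aggregate_term_measure("wang", toy_corpus, toy_dag, "g1", "g2", strategy="mean")


def test_matrix_structure_and_skipped_genes(toy_corpus, toy_dag):
    m = pairwise_matrix(toy_corpus, toy_dag, ["g1", "g2", "g3"], "simui")
    assert len(m.pairs()) == 3
    for g in m.genes:
        assert m.score(g, g) == 1.0
    m2 = pairwise_matrix(toy_corpus, toy_dag, ["g1", "g2", "unknown"], "simui")
    assert m2.skipped == ("unknown",)
    with pytest.raises(EmptyCorpusError):
        pairwise_matrix(toy_corpus, toy_dag, ["x", "y"], "simui")


def test_full_simui_matrix_matches_set_arithmetic_oracle(toy_corpus, toy_dag):
    genes = sorted(TOY1_PROPAGATED)
    m = pairwise_matrix(toy_corpus, toy_dag, genes, "simui")
    for g1, g2 in itertools.combinations(genes, 2):
        assert m.score(g1, g2) == pytest.approx(
            jaccard(TOY1_PROPAGATED[g1], TOY1_PROPAGATED[g2])
        )


def test_matrix_is_order_independent(toy_corpus, toy_dag):
    genes = ["g1", "g3", "g4", "g5"]
    a = pairwise_matrix(toy_corpus, toy_dag, genes, "simgic")
    b = pairwise_matrix(toy_corpus, toy_dag, list(reversed(genes)), "simgic")
    assert a.scores == b.scores


def test_pair_list_mode_scores_only_listed_pairs(toy_corpus, toy_dag):
    m = pairwise_matrix(
        toy_corpus, toy_dag, ["g1", "g3", "g4"], "simui",
        pairs=[("g1", "g3"), ("g4", "g1")],
    )
    assert sorted(m.scores) == [("g1", "g3"), ("g1", "g4")]


@pytest.mark.parametrize("seed", range(6))
def test_set_identities_and_shared_term_monotonicity(seed):
    dag, corpus = make_random_corpus(seed)
    genes = corpus.genes
    # identities: simUI = TO / |union|; TO <= min set size
    for g1, g2 in itertools.combinations(genes, 2):
        t1, t2 = corpus.propagated[g1], corpus.propagated[g2]
        to = sim_to(corpus, g1, g2)
        assert to <= min(len(t1), len(t2))
        assert sim_simui(corpus, g1, g2) == pytest.approx(to / len(t1 | t2))
    # adding one shared (previously unshared) term never decreases any measure
    g1, g2 = genes[0], genes[1]
    extra = next(
        (t for t in sorted(dag.terms)
         if t not in corpus.propagated[g1] and t not in corpus.propagated[g2]),
        None,
    )
    if extra is None:
        pytest.skip("no unshared term available in this draw")
    boosted = {g: set(ts) for g, ts in corpus.direct.items()}
    boosted[g1].add(extra)
    boosted[g2].add(extra)
    corpus2 = build_corpus(dag, boosted)
    assert sim_simui(corpus2, g1, g2) >= sim_simui(corpus, g1, g2) - 1e-12
    assert sim_simgic(corpus2, g1, g2) >= sim_simgic(corpus, g1, g2) - 1e-12
    assert sim_to(corpus2, g1, g2) >= sim_to(corpus, g1, g2)


def test_similarity_tsv_round_trip(toy_corpus, toy_dag, tmp_path):
    m = pairwise_matrix(toy_corpus, toy_dag, ["g1", "g3", "g4"], "simui")
    p = tmp_path / "sim.tsv"
    m.write_tsv(p)
    r = read_similarity_tsv(p)
    assert r.measure == "simui"
    for pair in m.pairs():
        assert r.scores[pair] == pytest.approx(m.scores[pair])
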