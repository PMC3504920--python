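"""PFP scoring: the co-occurrence sum, parental propagation, rank cutoffs."""

from __future__ import annotations

import pytest

from moonpred.pfp_scorer import (
    PfpConfig,
    pfp_direct_score,
    pfp_propagate_parents,
    pfp_rank_cutoffs,
    pfp_score,
)
from moonpred.predictions import PredictionSet
from moonpred.search_io import SearchHit, SearchResult
from tests.conftest import gid, make_dag, make_db
from tests.oracles import pfp_direct_oracle, pfp_raw_oracle, random_pfp_instance


def _result(*hits: SearchHit) -> SearchResult:
    return SearchResult.from_hits("q", list(hits))


def test_config_requires_b_matching_e_max():
    with pytest.raises(ValueError):
        PfpConfig(b=3.0, e_max=100.0)
    PfpConfig(b=3.0, e_max=1000.0)  # consistent pair is fine


def test_single_hit_self_cooccurrence_scores_four(flat_dag):
    # corpus where f1 co-occurs only with itself -> P(f1|f1) = 1
    f1 = gid(11)
    db = make_db(flat_dag, {"p1": {f1}, "p2": {f1}})
    pred = pfp_direct_score(_result(SearchHit("s", 0.01, frozenset({f1}))), db)
    assert pred.scores == pytest.approx({f1: 4.0})


def test_hit_at_e_ceiling_contributes_nothing(flat_dag):
    f1 = gid(11)
    db = make_db(flat_dag, {"p1": {f1}})
    pred = pfp_direct_score(_result(SearchHit("s", 100.0, frozenset({f1}))), db)
    assert pred.scores == {}


def test_scores_add_over_hits(flat_dag):
    f1 = gid(11)
    db = make_db(flat_dag, {"p1": {f1}})
    hits = [SearchHit("s1", 1.0, frozenset({f1})), SearchHit("s2", 1.0, frozenset({f1}))]
    pred = pfp_direct_score(_result(*hits), db)
    assert pred.scores == pytest.approx({f1: 4.0})  # 2 x (0 + 2) x 1


def test_empty_hit_list_gives_empty_set(flat_dag):
    db = make_db(flat_dag, {"p1": {gid(11)}})
    assert pfp_direct_score(_result(), db).scores == {}


def test_unseen_annotation_contributes_fallback(flat_dag):
    f1, f2 = gid(11), gid(12)
    db = make_db(flat_dag, {"p1": {f1}})
    hit = SearchHit("s", 0.01, frozenset({f2}))  # f2 never annotated in corpus
    assert pfp_direct_score(_result(hit), db).scores == {}
    cfg = PfpConfig(cond_prob_fallback=0.5)
    assert pfp_direct_score(_result(hit), db, cfg).scores == pytest.approx({f2: 2.0})


def test_parental_propagation_chain_proportion():
    a, b = gid(1), gid(2)
    dag = make_dag({a: set(), b: {a}})
    # propagated counts: 5 proteins have B (hence A too), 5 more have only A
    corpus = {f"pb{k}": {b} for k in range(5)} | {f"pa{k}": {a} for k in range(5)}
    db = make_db(dag, corpus)
    direct = PredictionSet("q", {b: 4.0}, "pfp")
    raw = pfp_propagate_parents(direct, dag, db)
    assert raw.scores == pytest.approx({b: 4.0, a: 4.0 * 5 / 10})


def test_propagation_of_root_only_scores_is_identity(flat_dag):
    root = gid(10)
    db = make_db(flat_dag, {"p1": {root}})
    direct = PredictionSet("q", {root: 3.0}, "pfp")
    raw = pfp_propagate_parents(direct, flat_dag, db)
    assert raw.scores == pytest.approx({root: 3.0})


def test_diamond_descendant_counted_once(diamond_dag):
    a, b, c, d = gid(1), gid(2), gid(3), gid(4)
    db = make_db(diamond_dag, {"p1": {d}, "p2": {b}, "p3": {c}, "p4": {a}})
    direct = PredictionSet("q", {d: 6.0}, "pfp")
    raw = pfp_propagate_parents(direct, diamond_dag, db)
    # n(D)=1, n(B)=2, n(C)=2, n(A)=4; A receives D's share once, not once per path
    assert raw.scores == pytest.approx({d: 6.0, b: 3.0, c: 3.0, a: 1.5})


def test_raw_score_never_below_direct(paper_data):
    dag, db, results, _ = paper_data
    for q in sorted(results)[:5]:
        direct = pfp_direct_score(results[q], db)
        raw = pfp_propagate_parents(direct, dag, db)
        for term, score in direct.scores.items():
            assert raw.scores[term] >= score - 1e-12


@pytest.mark.parametrize("seed", range(25))
def test_direct_score_matches_quadruple_loop_oracle(seed):
    dag, db, result, plain_hits, corpus = random_pfp_instance(seed)
    expected = pfp_direct_oracle(plain_hits, corpus, sorted(dag.terms))
    got = pfp_direct_score(result, db).scores
    assert set(got) == set(expected)
    for term, value in expected.items():
        assert got[term] == pytest.approx(value, rel=1e-9)


@pytest.mark.parametrize("seed", range(10))
def test_raw_score_matches_descendant_sum_oracle(seed):
    dag, db, result, _, corpus = random_pfp_instance(seed)
    direct = pfp_direct_score(result, db)
    parents = {t: set(term.parents) for t, term in dag.terms.items()}
    prop_counts = {t: db.term_count(t, propagated=True) for t in dag.terms}
    expected = pfp_raw_oracle(direct.scores, parents, prop_counts)
    got = pfp_propagate_parents(direct, dag, db).scores
    assert set(got) == set(expected)
    for term, value in expected.items():
        assert got[term] == pytest.approx(value, rel=1e-9)


def test_pfp_score_composes_direct_and_propagation(paper_data):
    dag, db, results, _ = paper_data
    q = sorted(results)[0]
    assert pfp_score(results[q], db, dag).scores == pytest.approx(
        pfp_propagate_parents(pfp_direct_score(results[q], db), dag, db).scores)


# -- ranked-list cutoffs -----------------------------------------------------


def _pred_with_n_terms(n: int) -> PredictionSet:
    return PredictionSet("q", {gid(k + 1): float(n - k) for k in range(n)}, "pfp")


def test_rank_cutoffs_full_grid():
    pred = _pred_with_n_terms(1000)
    grid = pfp_rank_cutoffs(pred, n_top=1000, interval=10)
    assert len(grid) == 100
    assert [rank for rank, _ in grid] == list(range(10, 1001, 10))
    assert all(len(s) == min(rank, 1000) for rank, s in grid)


def test_rank_cutoffs_short_list_capped():
    grid = pfp_rank_cutoffs(_pred_with_n_terms(7), n_top=1000, interval=10)
    assert all(len(s) == 7 for _, s in grid)


def test_rank_cutoffs_nested_and_deterministic_ties():
    scores = {gid(k): 1.0 for k in range(1, 31)}  # fully tied block
    pred = PredictionSet("q", scores, "pfp")
    grid = pfp_rank_cutoffs(pred, n_top=30, interval=5)
    ranked = sorted(scores)  # ties break by ascending accession
    for rank, subset in grid:
        assert subset == frozenset(ranked[:rank])
    for (_, small), (_, big) in zip(grid, grid[1:]):
        assert small <= big


def test_rank_cutoffs_empty_and_bad_params():
    assert pfp_rank_cutoffs(PredictionSet("q", {}, "pfp")) == []
    with pytest.raises(ValueError):
        pfp_rank_cutoffs(_pred_with_n_terms(5), n_top=5, interval=10)


def test_fraction_cutoff_keeps_top_half():
    pred = _pred_with_n_terms(1000)
    kept = pred.terms_at_fraction(0.5, n_top=1000)
    assert len(kept) == 500
    assert kept == {t for t, _ in pred.ranked_terms()[:500]}
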