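"""Precision/recall evaluation: propagation, averaging, and truth filters."""

from __future__ import annotations

import pytest

from moonpred.evaluation import (
    ALL_LABELS,
    MOONLIGHTING_LABELS,
    EvaluationError,
    MoonlightingTruth,
    confusion_at_cutoff,
    load_truth,
    per_protein_recall,
    pr_curve,
)
from moonpred.blast_baseline import blast_transfer
from moonpred.esg_scorer import esg_score
from moonpred.pfp_scorer import pfp_score
from moonpred.predictions import PredictionSet
from moonpred.search_io import TableSearchProvider
from tests.conftest import gid, make_dag


def _pred(scores: dict[str, float], tag: str = "esg") -> PredictionSet:
    return PredictionSet("q", scores, tag)


def test_perfect_prediction_scores_one_one(chain_dag):
    truth = frozenset({gid(3)})
    pred = _pred({gid(3): 0.9})
    point = confusion_at_cutoff(pred, truth, chain_dag, cutoff=0.5)
    assert (point.precision, point.recall) == (1.0, 1.0)
    assert point.fp == point.fn == 0


def test_flat_dag_set_arithmetic(flat_dag):
    a, b, c, d = gid(11), gid(12), gid(13), gid(14)
    point = confusion_at_cutoff(_pred({a: 1.0, b: 1.0, c: 1.0}), frozenset({b, c, d}),
                                flat_dag, cutoff=0.5)
    # propagated sets share the root: tp = |{b,c,root}| = 3, fp = {a}, fn = {d}
    assert (point.tp, point.fp, point.fn) == (3, 1, 1)
    assert point.precision == pytest.approx(3 / 4)
    assert point.recall == pytest.approx(3 / 4)


def test_root_exclusion_flag(flat_dag):
    a, b = gid(11), gid(12)
    point = confusion_at_cutoff(_pred({a: 1.0}), frozenset({b}), flat_dag,
                                cutoff=0.5, include_roots=False)
    assert (point.tp, point.fp, point.fn) == (0, 1, 1)
    assert point.recall == 0.0


def test_cutoff_above_all_scores(flat_dag):
    point = confusion_at_cutoff(_pred({gid(11): 0.2}), frozenset({gid(12)}), flat_dag,
                                cutoff=0.9)
    assert point.precision is None
    assert point.recall == 0.0


def test_empty_truth_is_an_error(flat_dag):
    with pytest.raises(EvaluationError):
        confusion_at_cutoff(_pred({gid(11): 1.0}), frozenset(), flat_dag, cutoff=0.5)


def test_truth_labels_validated():
    with pytest.raises(ValueError):
        MoonlightingTruth("p", {gid(1): "primary"})


def test_load_truth_and_moonlighting_flag(tmp_path, chain_dag):
    path = tmp_path / "truth.tsv"
    path.write_text(f"p1\t{gid(2)}\tfunction1\np1\t{gid(3)}\tfunction2\n")
    truths = load_truth(path, chain_dag)
    assert truths["p1"].is_moonlighting()
    assert truths["p1"].terms(frozenset({"function2"})) == {gid(3)}


def _cohort(paper_data):
    """All three methods scored over the synthetic moonlighting cohort."""
    dag, db, results, truths = paper_data
    provider = TableSearchProvider(results)
    queries = sorted(truths)
    preds = {
        "pfp": {q: pfp_score(results[q], db, dag) for q in queries},
        "esg": {q: esg_score(q, provider, db) for q in queries},
        "blast": {q: blast_transfer(results[q]) for q in queries},
    }
    return dag, truths, preds


@pytest.fixture(scope="module")
def cohort(paper_data):
    return _cohort(paper_data)


def test_conservation_tp_plus_fn_is_truth_size(cohort):
    dag, truths, preds = cohort
    for q, pred in preds["esg"].items():
        truth = truths[q].terms(ALL_LABELS)
        n_truth = len(dag.propagate(truth))
        for cutoff in (0.0, 0.3, 0.8, 2.0):
            point = confusion_at_cutoff(pred, truth, dag, cutoff)
            assert point.tp + point.fn == n_truth


def test_recall_monotone_non_increasing_in_cutoff(cohort):
    dag, truths, preds = cohort
    for q, pred in preds["blast"].items():
        truth = truths[q].terms(ALL_LABELS)
        recalls = [confusion_at_cutoff(pred, truth, dag, c).recall
                   for c in [4 + 41 * k / 19 for k in range(20)]]
        assert all(r1 >= r2 - 1e-12 for r1, r2 in zip(recalls, recalls[1:]))


def test_pr_curve_perfect_predictor_is_flat(chain_dag):
    truth = {"q": MoonlightingTruth("q", {gid(3): "function1"})}
    pred = {"q": _pred({gid(1): 1.0, gid(2): 1.0, gid(3): 1.0})}
    curve = pr_curve(pred, truth, chain_dag, cutoffs=[0.1, 0.5, 0.9])
    assert all(p.precision == 1.0 and p.recall == 1.0 for p in curve.points)


def test_pr_curve_matches_per_protein_loop_oracle(cohort):
    dag, truths, preds = cohort
    cutoffs = [0.0, 0.2, 0.4, 0.6]
    curve = pr_curve(preds["esg"], truths, dag, cutoffs)
    for i, cutoff in enumerate(cutoffs):
        precisions, recalls = [], []
        for q, pred in preds["esg"].items():
            pt = confusion_at_cutoff(pred, truths[q].terms(ALL_LABELS), dag, cutoff)
            recalls.append(pt.recall)
            if pt.precision is not None:
                precisions.append(pt.precision)
        assert curve.points[i].recall == pytest.approx(sum(recalls) / len(recalls))
        if precisions:
            assert curve.points[i].precision == pytest.approx(sum(precisions) / len(precisions))


def test_all_labels_filter_identical_to_unfiltered(cohort):
    dag, truths, preds = cohort
    base = pr_curve(preds["blast"], truths, dag, [4.0, 10.0], truth_filter=ALL_LABELS)
    same = pr_curve(preds["blast"], truths, dag, [4.0, 10.0],
                    truth_filter=frozenset({"function1", "function2", "both", "neither"}))
    assert [(p.precision, p.recall) for p in base.points] == [
        (p.precision, p.recall) for p in same.points]


def test_micro_average_pools_counts(cohort):
    dag, truths, preds = cohort
    curve = pr_curve(preds["blast"], truths, dag, [5.0], average="micro")
    pt = curve.points[0]
    assert pt.precision == pytest.approx(pt.tp / (pt.tp + pt.fp))
    assert pt.recall == pytest.approx(pt.tp / (pt.tp + pt.fn))


def test_moonlighting_recall_decomposes_over_disjoint_functions():
    # two disjoint chains under one root; f1 truth on one, f2 on the other
    r, b1, c1, b2, c2 = gid(1), gid(2), gid(3), gid(4), gid(5)
    dag = make_dag({r: set(), b1: {r}, c1: {b1}, b2: {r}, c2: {b2}})
    truth = MoonlightingTruth("q", {c1: "function1", c2: "function2"})
    pred = _pred({c1: 1.0, b2: 1.0})
    kwargs = dict(dag=dag, cutoff=0.5, include_roots=False)
    both = confusion_at_cutoff(pred, truth.terms(MOONLIGHTING_LABELS), **kwargs)
    f1 = confusion_at_cutoff(pred, truth.terms(frozenset({"function1"})), **kwargs)
    f2 = confusion_at_cutoff(pred, truth.terms(frozenset({"function2"})), **kwargs)
    assert both.tp == f1.tp + f2.tp
    assert both.tp + both.fn == (f1.tp + f1.fn) + (f2.tp + f2.fn)


def test_per_protein_recall_matches_confusion_recomputation(cohort):
    dag, truths, preds = cohort
    recall, flagged = per_protein_recall(preds, truths, dag)
    assert not flagged.to_numpy().any()
    kinds = {"pfp": ("fraction", 0.5), "esg": ("score", 0.35), "blast": ("evalue", 0.01)}
    for method, (kind, cutoff) in kinds.items():
        for q in recall.index:
            pt = confusion_at_cutoff(preds[method][q], truths[q].terms(ALL_LABELS), dag,
                                     cutoff, cutoff_kind=kind)
            assert recall.loc[q, method] == pytest.approx(pt.recall)


def test_per_protein_recall_flags_empty_predictions(chain_dag):
    truths = {"q": MoonlightingTruth("q", {gid(3): "function1"})}
    preds = {"esg": {"q": PredictionSet("q", {}, "esg")}}
    recall, flagged = per_protein_recall(preds, truths, chain_dag)
    assert recall.loc["q", "esg"] == 0.0
    assert bool(flagged.loc["q", "esg"])


def test_full_truth_prediction_gives_recall_one(chain_dag):
    truths = {"q": MoonlightingTruth("q", {gid(3): "function1"})}
    preds = {"esg": {"q": _pred({gid(1): 0.9, gid(2): 0.9, gid(3): 0.9})}}
    recall, _ = per_protein_recall(preds, truths, chain_dag)
    assert recall.loc["q", "esg"] == 1.0


def test_pr_curve_requires_truth_for_every_protein(chain_dag):
    preds = {"q_unknown": _pred({gid(3): 1.0})}
    with pytest.raises(EvaluationError):
        pr_curve(preds, {}, chain_dag, [0.5])
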