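"""The PFP scorer: E-value-weighted GO co-occurrence plus parental propagation.

The direct score of a candidate term fa is

    s(fa) = sum_i sum_{fj in ann(i)} (-log10(E_i) + b) * P(fa | fj)

over search hits i with E-value at most e_max (default 100); b = log10(e_max)
so the weight of a hit at the E-value ceiling is exactly zero.  P(fa|fj) is
the corpus co-occurrence probability from :mod:`moonpred.annotation_db`.

The direct scores are then transferred upward: every ancestor p of a scored
term receives direct(fa) * n(fa)/n(p), where n(·) counts proteins annotated
(after propagation) with the term.  The sum of a term's direct score and the
contributions propagated up from its scored descendants is the *raw score*,
which is what predictions are ranked by.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from moonpred.annotation_db import AnnotationDatabase
from moonpred.go_dag import GoDag
from moonpred.predictions import PredictionSet
from moonpred.search_io import DEFAULT_E_FLOOR, SearchResult, neglog_weight

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PfpConfig:
    """PFP parameters.

    ``b`` must equal log10(e_max) so a hit at the E-value ceiling contributes
    zero weight; with the defaults (e_max = 100, b = 2) all scores are
    non-negative.  ``cond_prob_fallback`` is the probability credited to a
    hit annotation never seen in the corpus — by default 0 (no corpus
    evidence, no score).
    """

    b: float = 2.0
    e_max: float = 100.0
    e_floor: float = DEFAULT_E_FLOOR
    cond_prob_fallback: float = 0.0
    propagate_parents: bool = True

    def __post_init__(self) -> None:
        if not math.isclose(self.b, math.log10(self.e_max)):
            raise ValueError("b must equal log10(e_max) so the weight vanishes at e_max")
        if not 0 <= self.cond_prob_fallback <= 1:
            raise ValueError("cond_prob_fallback must be in [0, 1]")


def pfp_direct_score(result: SearchResult, db: AnnotationDatabase,
                     cfg: PfpConfig = PfpConfig()) -> PredictionSet:
    """Score candidate GO terms by E-value-weighted co-occurrence.

    Candidates are exactly the terms with nonzero co-occurrence against some
    annotation observed in the hits (scoring the rest of the ontology would
    only add zeros).  Terms ending at score 0 are omitted.  An empty hit
    list yields an empty prediction set.
    """
    scores: dict[str, float] = {}
    for hit in result.hits:
        if hit.e_value > cfg.e_max:
            continue
        weight = neglog_weight(hit.e_value, cfg.b, cfg.e_floor)
        if weight == 0:
            continue
        for fj in hit.annotations:
            cooc = db.cooccurring_terms(fj)
            if not cooc:
                if cfg.cond_prob_fallback > 0 and fj in db.dag:
                    fj_primary = db.dag.resolve(fj)
                    scores[fj_primary] = scores.get(fj_primary, 0.0) + weight * cfg.cond_prob_fallback
                continue
            for fa, prob in cooc.items():
                scores[fa] = scores.get(fa, 0.0) + weight * prob
    scores = {t: s for t, s in scores.items() if s > 0}
    return PredictionSet(query_id=result.query_id, scores=scores, method_tag="pfp")


def pfp_propagate_parents(direct: PredictionSet, dag: GoDag,
                          db: AnnotationDatabase) -> PredictionSet:
    """Turn direct scores into raw scores by upward parental transfer.

    Each ancestor p of a scored term accumulates, once per scored descendant
    fa (regardless of how many is_a paths connect them),

        direct(fa) * term_count(fa, propagated) / term_count(p, propagated).

    Only directly scored terms act as sources — contributions never cascade
    through already-propagated intermediate scores, which would count a
    descendant once per level.  Ancestors with zero propagated count are
    skipped with a warning.
    """
    raw: dict[str, float] = dict(direct.scores)
    for fa, score in direct.scores.items():
        n_fa = db.term_count(fa, propagated=True)
        if n_fa == 0:
            continue
        for p in dag.ancestors(fa):
            n_p = db.term_count(p, propagated=True)
            if n_p == 0:
                logger.warning("ancestor %s of scored term %s has zero propagated count; skipped", p, fa)
                continue
            raw[p] = raw.get(p, 0.0) + score * (n_fa / n_p)
    return PredictionSet(query_id=direct.query_id, scores=raw, method_tag="pfp",
                         metadata=dict(direct.metadata))


def pfp_score(result: SearchResult, db: AnnotationDatabase, dag: GoDag,
              cfg: PfpConfig = PfpConfig()) -> PredictionSet:
    """Direct scoring followed by parental propagation (the raw score)."""
    direct = pfp_direct_score(result, db, cfg)
    if not cfg.propagate_parents:
        return direct
    return pfp_propagate_parents(direct, dag, db)


def pfp_rank_cutoffs(pred: PredictionSet, n_top: int = 1000,
                     interval: int = 10) -> list[tuple[int, frozenset[str]]]:
    """Nested prefixes of the ranked prediction list.

    Predictions are sorted by descending raw score (ties broken by ascending
    accession), truncated to ``n_top``, and returned as the nested prefix
    sets at ranks interval, 2*interval, ..., n_top.  Prefixes are capped at
    the number of scored terms.  An empty prediction set gives an empty list.
    """
    if interval < 1 or n_top < interval:
        raise ValueError("need n_top >= interval >= 1")
    ranked = [t for t, _ in pred.ranked_terms()[:n_top]]
    if not ranked:
        return []
    out: list[tuple[int, frozenset[str]]] = []
    for rank in range(interval, n_top + 1, interval):
        out.append((rank, frozenset(ranked[:rank])))
    return out
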