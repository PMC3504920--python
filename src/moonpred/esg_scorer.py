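"""The ESG scorer: two-level search with per-level -log(E) weight normalization.

ESG explores the similarity space around a query in two rounds: a first
search from the query itself, then one search seeded at each of the top
first-level hits.  Within a single search, each hit i receives the weight

    w_i = -log10(E_i) / sum_k -log10(E_k)

over the hits considered in that search (negative logs, i.e. E > 1, clamp to
zero), so weights within a level sum to one.  A GO term's score combines the
weight it gathers at the two levels; with the default convex mixture
(0.5, 0.5) every score lies in [0, 1], and a term annotating every hit at
both levels attains exactly 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from moonpred.annotation_db import AnnotationDatabase
from moonpred.predictions import PredictionSet
from moonpred.search_io import (
    DEFAULT_E_FLOOR,
    SearchHit,
    SearchProvider,
    SearchResult,
    neglog_weight,
)

logger = logging.getLogger(__name__)


class DegenerateLevelError(ValueError):
    """Every hit in a search level has E >= 1, so no weights can be formed."""


@dataclass(frozen=True)
class EsgConfig:
    """ESG parameters.

    ``level_weights`` must be non-negative and sum to 1 (this is what keeps
    the total score at most 1).  ``n_first_level`` caps how many first-level
    hits seed a second-level search; the hits' own annotations still count at
    level one even when not expanded.
    """

    level_weights: tuple[float, float] = (0.5, 0.5)
    n_first_level: int = 10
    e_floor: float = DEFAULT_E_FLOOR
    e_max: float = 100.0

    def __post_init__(self) -> None:
        w1, w2 = self.level_weights
        if w1 < 0 or w2 < 0 or abs(w1 + w2 - 1.0) > 1e-12:
            raise ValueError("level_weights must be non-negative and sum to 1")
        if self.n_first_level < 1:
            raise ValueError("n_first_level must be >= 1")


def _eligible(hits: tuple[SearchHit, ...], cfg: EsgConfig,
              exclude: frozenset[str] = frozenset()) -> list[SearchHit]:
    return [h for h in hits if h.e_value <= cfg.e_max and h.subject_id not in exclude]


def normalize_level(result: SearchResult, cfg: EsgConfig = EsgConfig()) -> dict[str, float]:
    """Per-hit weights for one search: -log10(E) as a proportion of the level total.

    Hits with E > 1 (negative log) are clamped to zero weight before
    normalizing.  Raises :class:`DegenerateLevelError` when every hit clamps
    to zero, i.e. nothing in the level is more significant than E = 1.
    """
    hits = _eligible(result.hits, cfg)
    raw = {h.subject_id: max(0.0, neglog_weight(h.e_value, b=0.0, e_floor=cfg.e_floor))
           for h in hits}
    total = sum(raw.values())
    if total <= 0:
        raise DegenerateLevelError(f"no hit with E < 1 in search for {result.query_id}")
    return {s: w / total for s, w in raw.items()}


def esg_score(query_id: str, provider: SearchProvider, db: AnnotationDatabase,
              cfg: EsgConfig = EsgConfig()) -> PredictionSet:
    """Run the two-level ESG scoring for one query.

    score(f) = lw1 * sum_i w_i [f in ann(i)]
             + lw2 * sum_i w_i * sum_j v_ij [f in ann(j)],

    where w are the first-level weights, the inner sum runs over the
    second-level search seeded at hit i (with the original query removed from
    its hit list, a leakage guard), and v_i are that search's weights.  Only
    the top ``n_first_level`` hits are expanded; a failed or degenerate
    second-level search is skipped with a warning, degrading that seed's
    level-two contribution to zero.
    """
    result = provider.search(query_id)
    first_hits = _eligible(result.hits, cfg, exclude=frozenset({query_id}))
    scores: dict[str, float] = {}
    if not first_hits:
        return PredictionSet(query_id=query_id, scores=scores, method_tag="esg")
    try:
        w = normalize_level(SearchResult(query_id, tuple(first_hits)), cfg)
    except DegenerateLevelError:
        return PredictionSet(query_id=query_id, scores=scores, method_tag="esg")
    lw1, lw2 = cfg.level_weights

    ann_of = {h.subject_id: h.annotations for h in first_hits}
    for subject, weight in w.items():
        for f in ann_of[subject]:
            scores[f] = scores.get(f, 0.0) + lw1 * weight

    seeds = [h for h in first_hits if w.get(h.subject_id, 0.0) > 0][: cfg.n_first_level]
    exclude = frozenset({query_id})
    for seed in seeds:
        try:
            second = provider.search(seed.subject_id)
        except Exception as exc:  # noqa: BLE001 - provider failures degrade gracefully
            logger.warning("second-level search for %s failed (%s); skipped", seed.subject_id, exc)
            continue
        second_hits = _eligible(second.hits, cfg, exclude=exclude | {seed.subject_id})
        if not second_hits:
            continue
        try:
            v = normalize_level(SearchResult(seed.subject_id, tuple(second_hits)), cfg)
        except DegenerateLevelError:
            logger.warning("second-level search for %s is degenerate (all E >= 1); skipped",
                           seed.subject_id)
            continue
        ann_of_2 = {h.subject_id: h.annotations for h in second_hits}
        wi = w[seed.subject_id]
        for subject, vj in v.items():
            for f in ann_of_2[subject]:
                scores[f] = scores.get(f, 0.0) + lw2 * wi * vj

    scores = {t: min(s, 1.0) if s <= 1.0 + 1e-12 else s for t, s in scores.items()}
    return PredictionSet(query_id=query_id, scores=scores, method_tag="esg")
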