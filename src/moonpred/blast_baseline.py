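"""PSI-BLAST annotation-transfer baseline.

Transfers GO terms from annotated hits strictly better than an E-value
cutoff (default 0.01) and ranks them by -log10(E) + 2, so the default grid
of prediction-score thresholds runs from 4 (E = 0.01) to 45 (E = 1e-43).
Unlike PFP's additive co-occurrence score, a term picked up from several
hits keeps the score of its single best hit.
"""

from __future__ import annotations

import numpy as np

from moonpred.predictions import PredictionSet
from moonpred.search_io import DEFAULT_E_FLOOR, SearchResult, neglog_weight


def blast_transfer(result: SearchResult, e_cutoff: float = 0.01, b: float = 2.0,
                   e_floor: float = DEFAULT_E_FLOOR, max_hits: int | None = None,
                   matrix_tag: str = "blosum62") -> PredictionSet:
    """Transfer annotations from hits with E-value strictly below ``e_cutoff``.

    Each transferred term is scored -log10(max(E, e_floor)) + b from the hit
    that carried it; a term seen from multiple hits keeps its maximum (best
    hit) score.  A boundary hit at exactly ``e_cutoff`` is excluded ("better
    than" is strict).  ``max_hits``, if given, caps how many qualifying
    annotated hits are used, best first.  No qualifying hit simply yields an
    empty prediction set.
    """
    scores: dict[str, float] = {}
    n_used = 0
    for hit in result.hits:  # ascending E-value
        if hit.e_value >= e_cutoff:
            break
        if not hit.annotations:
            continue
        if max_hits is not None and n_used >= max_hits:
            break
        n_used += 1
        score = neglog_weight(hit.e_value, b, e_floor)
        for term in hit.annotations:
            if score > scores.get(term, float("-inf")):
                scores[term] = score
    return PredictionSet(query_id=result.query_id, scores=scores, method_tag="blast",
                         metadata={"matrix": matrix_tag, "e_cutoff": repr(e_cutoff)})


def blast_cutoff_grid(lo: float = 4.0, hi: float = 45.0, n: int = 100) -> list[float]:
    """``n`` evenly spaced score thresholds from ``lo`` to ``hi`` inclusive."""
    if not lo < hi:
        raise ValueError("need lo < hi")
    if n < 2:
        raise ValueError("need n >= 2")
    return [float(x) for x in np.linspace(lo, hi, n)]
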