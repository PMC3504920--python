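"""Scored GO-term prediction sets shared by all three scorers."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class PredictionSet:
    """GO-term scores for one query protein.

    ``method_tag`` is one of {"pfp", "esg", "blast"}.  PFP and BLAST scores
    are non-negative and unbounded above; ESG scores lie in [0, 1].
    ``metadata`` carries free-form provenance (e.g. the substitution-matrix
    tag of the upstream search).
    """

    query_id: str
    scores: dict[str, float]
    method_tag: str
    metadata: dict[str, str] = field(default_factory=dict)

    def ranked_terms(self) -> list[tuple[str, float]]:
        """Terms sorted by descending score, ties broken by ascending accession."""
        return sorted(self.scores.items(), key=lambda kv: (-kv[1], kv[0]))

    def terms_at_score(self, cutoff: float) -> frozenset[str]:
        """Terms scoring at or above ``cutoff``."""
        return frozenset(t for t, s in self.scores.items() if s >= cutoff)

    def terms_at_fraction(self, fraction: float, n_top: int = 1000) -> frozenset[str]:
        """Top ``round(fraction * n_top)`` ranked terms (list-fraction cutoff).

        This is the cutoff convention for PFP raw scores, whose range varies
        wildly across queries: a fraction of 0.5 with n_top = 1000 keeps at
        most 500 predictions.
        """
        if not 0 < fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        k = round(fraction * n_top)
        return frozenset(t for t, _ in self.ranked_terms()[:k])


def write_predictions(preds: list[PredictionSet], path: str | Path) -> None:
    """Write prediction sets to a 3-column TSV (query_id, go_id, score).

    The method tag and any metadata go in header comment lines.
    """
    if not preds:
        Path(path).write_text("# method: none\n")
        return
    tags = {p.method_tag for p in preds}
    if len(tags) > 1:
        raise ValueError(f"mixed method tags in one file: {sorted(tags)}")
    lines = [f"# method: {preds[0].method_tag}"]
    meta: dict[str, str] = {}
    for p in preds:
        meta.update(p.metadata)
    for key in sorted(meta):
        lines.append(f"# {key}: {meta[key]}")
    for p in sorted(preds, key=lambda p: p.query_id):
        for term, score in p.ranked_terms():
            lines.append(f"{p.query_id}\t{term}\t{score:.10g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_predictions(path: str | Path) -> dict[str, PredictionSet]:
    """Read a prediction TSV back into per-query :class:`PredictionSet`."""
    method = "unknown"
    metadata: dict[str, str] = {}
    scores: dict[str, dict[str, float]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("# ")
                if ":" in body:
                    key, value = body.split(":", 1)
                    if key.strip() == "method":
                        method = value.strip()
                    else:
                        metadata[key.strip()] = value.strip()
                continue
            query, term, score = line.split("\t")
            scores.setdefault(query, {})[term] = float(score)
    return {
        q: PredictionSet(query_id=q, scores=s, method_tag=method, metadata=dict(metadata))
        for q, s in scores.items()
    }
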