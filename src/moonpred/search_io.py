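"""Sequence-search results: hit lists, E-value transforms, provider contract.

Scorers never invoke a search binary; they consume :class:`SearchProvider`,
which in practice is a :class:`TableSearchProvider` over a parsed BLAST
tabular file.  An adapter that shells out to ``psiblast`` is provided for
completeness but is never required.
"""

from __future__ import annotations

import gzip
import logging
import math
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, runtime_checkable

logger = logging.getLogger(__name__)

#: Floor applied to reported E-values of 0.0 before taking the log.
DEFAULT_E_FLOOR = 1e-180


@dataclass(frozen=True)
class SearchHit:
    """One subject sequence with its E-value and GO annotations."""

    subject_id: str
    e_value: float
    annotations: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError(f"negative E-value for {self.subject_id}")


@dataclass(frozen=True)
class SearchResult:
    """Hits for one query, sorted ascending by E-value (ties keep input order)."""

    query_id: str
    hits: tuple[SearchHit, ...]

    @staticmethod
    def from_hits(query_id: str, hits: list[SearchHit]) -> "SearchResult":
        ordered = sorted(hits, key=lambda h: h.e_value)  # stable: ties keep order
        return SearchResult(query_id=query_id, hits=tuple(ordered))


@runtime_checkable
class SearchProvider(Protocol):
    """Deterministic source of search results, one query at a time."""

    def search(self, query_id: str) -> SearchResult: ...


class SearchLookupError(KeyError):
    """A provider has no result for the requested query."""


class TableSearchProvider:
    """SearchProvider backed by a dict of pre-parsed results."""

    def __init__(self, results: dict[str, SearchResult]):
        self._results = dict(results)

    def search(self, query_id: str) -> SearchResult:
        try:
            return self._results[query_id]
        except KeyError:
            raise SearchLookupError(query_id) from None

    def queries(self) -> list[str]:
        return sorted(self._results)


def neglog_weight(e_value: float, b: float = 2.0, e_floor: float = DEFAULT_E_FLOOR) -> float:
    """The E-value weight −log10(max(e, e_floor)) + b.

    With b = 2 (= log10 of the E-value ceiling 100), a hit at E = 100 weighs
    exactly 0 and a hit at E = 0.01 weighs 4.  The floor keeps the weight
    finite when search tools report E = 0.
    """
    if e_floor <= 0:
        raise ValueError("e_floor must be positive")
    return -math.log10(max(e_value, e_floor)) + b


def parse_blast_tabular(path: str | Path, db=None) -> dict[str, SearchResult]:
    """Parse a BLAST ``-outfmt 6`` style tabular file into per-query results.

    Columns 1 (query), 2 (subject) and 11 (E-value) are used; anything with
    fewer than 11 columns but at least 3 is read as the compact dialect
    (query, subject, e_value).  Self-hits (subject == query) are dropped —
    keeping the query as its own annotation evidence would be leakage.
    Subjects are annotated by direct-annotation lookup in ``db`` when given.
    Transparently reads gzip files.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    raw: dict[str, list[SearchHit]] = {}
    n_bad = 0
    with opener(path, "rt") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) >= 11:
                query, subject, e_str = cols[0], cols[1], cols[10]
            elif len(cols) >= 3:
                query, subject, e_str = cols[0], cols[1], cols[2]
            else:
                n_bad += 1
                continue
            try:
                e_value = float(e_str)
            except ValueError:
                n_bad += 1
                continue
            raw.setdefault(query, [])
            if subject == query:
                continue
            annotations = db.annotations(subject) if db is not None else frozenset()
            raw[query].append(SearchHit(subject_id=subject, e_value=e_value, annotations=annotations))
    if n_bad:
        logger.warning("%s: skipped %d unparsable rows", path, n_bad)
    return {q: SearchResult.from_hits(q, hits) for q, hits in raw.items()}


def write_blast_tabular(results: dict[str, SearchResult], path: str | Path) -> None:
    """Write results back out in the compact 3-column dialect."""
    with open(path, "w") as fh:
        for query in sorted(results):
            for hit in results[query].hits:
                fh.write(f"{query}\t{hit.subject_id}\t{hit.e_value:.6g}\n")


class PsiBlastProvider:
    """Adapter running an external ``psiblast`` binary (3 iterations).

    Never exercised by the test suite; it exists so the same scorers can run
    against a live sequence database.  ``matrix`` selects the substitution
    matrix (BLOSUM62 default; BLOSUM45/BLOSUM30 reach more divergent
    homologs).
    """

    def __init__(self, db_path: str, query_fasta_dir: str, annotation_db=None,
                 matrix: str = "BLOSUM62", iterations: int = 3, binary: str = "psiblast"):
        self.db_path = db_path
        self.query_fasta_dir = Path(query_fasta_dir)
        self.annotation_db = annotation_db
        self.matrix = matrix
        self.iterations = iterations
        self.binary = binary

    def search(self, query_id: str) -> SearchResult:  # pragma: no cover - external tool
        query_file = self.query_fasta_dir / f"{query_id}.fasta"
        cmd = [
            self.binary,
            "-query", str(query_file),
            "-db", self.db_path,
            "-num_iterations", str(self.iterations),
            "-matrix", self.matrix,
            "-outfmt", "6",
        ]
        proc = subprocess.run(cmd, capture_output=True, text=True, check=True)
        hits: list[SearchHit] = []
        seen: set[str] = set()
        for line in proc.stdout.splitlines():
            cols = line.split("\t")
            if len(cols) < 11 or cols[1] == query_id or cols[1] in seen:
                continue
            seen.add(cols[1])
            ann = self.annotation_db.annotations(cols[1]) if self.annotation_db else frozenset()
            hits.append(SearchHit(subject_id=cols[1], e_value=float(cols[10]), annotations=ann))
        return SearchResult.from_hits(query_id, hits)
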