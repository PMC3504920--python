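"""Protein -> GO annotation corpus and the co-occurrence statistics PFP needs.

The corpus carries two views of every protein's annotation set: the *direct*
terms as asserted in the source file, and the *propagated* set closed under
the is_a ancestor relation.  Conditional co-occurrence P(fa|fj) is computed
on the direct view by default — propagated co-occurrence is degenerate
because ancestors co-occur with everything below them — while the
parental-proportion counts used by PFP's upward propagation use the
propagated view ("all proteins that belong to the parental term" includes
proteins annotated to its descendants).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from moonpred.go_dag import GoDag

logger = logging.getLogger(__name__)


class AnnotationFormatError(ValueError):
    """Raised when an annotation file yields no usable rows."""


class UndefinedConditionalError(ValueError):
    """P(fa|fj) requested for a term fj never seen in the corpus."""


@dataclass
class AnnotationDatabase:
    """Protein→GO corpus with direct and ancestor-closed annotation sets."""

    dag: GoDag
    direct: dict[str, frozenset[str]]
    propagated: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.propagated:
            self.propagated = {p: self.dag.propagate(terms) for p, terms in self.direct.items()}
        self._direct_index: dict[str, set[str]] = {}
        self._prop_index: dict[str, set[str]] = {}
        for protein, terms in self.direct.items():
            for t in terms:
                self._direct_index.setdefault(t, set()).add(protein)
        for protein, terms in self.propagated.items():
            for t in terms:
                self._prop_index.setdefault(t, set()).add(protein)
        # co-occurrence counts materialized lazily, one fj at a time
        self._cooc_cache: dict[str, dict[str, int]] = {}

    @property
    def n_proteins(self) -> int:
        return len(self.direct)

    def annotations(self, protein_id: str, propagated: bool = False) -> frozenset[str]:
        """Annotation set of one protein; empty set if the protein is unknown."""
        view = self.propagated if propagated else self.direct
        return view.get(protein_id, frozenset())

    def term_count(self, accession: str, propagated: bool = False) -> int:
        """Number of proteins annotated with ``accession`` (0 if unseen)."""
        try:
            acc = self.dag.resolve(accession)
        except KeyError:
            return 0
        index = self._prop_index if propagated else self._direct_index
        return len(index.get(acc, ()))

    def _cooc_counts(self, fj: str) -> dict[str, int]:
        cached = self._cooc_cache.get(fj)
        if cached is not None:
            return cached
        counts: dict[str, int] = {}
        for protein in self._direct_index.get(fj, ()):
            for fa in self.direct[protein]:
                counts[fa] = counts.get(fa, 0) + 1
        self._cooc_cache[fj] = counts
        return counts

    def cond_prob(self, fa: str, fj: str) -> float:
        """P(fa | fj): fraction of fj-annotated proteins also annotated fa.

        Computed on direct annotations.  ``cond_prob(f, f)`` is 1 whenever f
        is annotated at least once.

        Raises
        ------
        UndefinedConditionalError
            If no protein in the corpus is annotated with ``fj``.
        """
        fa = self.dag.resolve(fa)
        fj = self.dag.resolve(fj)
        denom = self.term_count(fj)
        if denom == 0:
            raise UndefinedConditionalError(fj)
        return self._cooc_counts(fj).get(fa, 0) / denom

    def cooccurring_terms(self, fj: str) -> dict[str, float]:
        """All terms with nonzero P(·|fj), as a map term -> probability.

        Returns an empty map when fj is unseen (the caller decides the
        fallback; PFP's default is to score nothing from unseen terms).
        """
        try:
            fj = self.dag.resolve(fj)
        except KeyError:
            return {}
        denom = self.term_count(fj)
        if denom == 0:
            return {}
        return {fa: c / denom for fa, c in self._cooc_counts(fj).items()}


def _build(dag: GoDag, records: Iterable[tuple[str, str]], source: str) -> AnnotationDatabase:
    direct: dict[str, set[str]] = {}
    n_rows = 0
    n_skipped = 0
    for protein_id, go_id in records:
        n_rows += 1
        try:
            resolved = dag.resolve(go_id)
        except KeyError:
            n_skipped += 1
            continue
        direct.setdefault(protein_id, set()).add(resolved)
    if n_skipped:
        logger.warning("%s: skipped %d rows with unresolvable GO ids", source, n_skipped)
    if not direct:
        raise AnnotationFormatError(f"{source}: no usable annotation rows")
    return AnnotationDatabase(dag=dag, direct={p: frozenset(s) for p, s in direct.items()})


def load_gaf(path: str | Path, dag: GoDag, evidence_allow: set[str] | None = None) -> AnnotationDatabase:
    """Load a GAF 2.x gene-association file.

    Uses columns 2 (object id), 4 (qualifier), 5 (GO id) and 7 (evidence).
    Rows with a NOT qualifier are skipped; malformed rows are skipped with a
    logged count.  ``evidence_allow``, if given, keeps only rows whose
    evidence code is in the set (no filtering by default).
    """
    records: list[tuple[str, str]] = []
    n_malformed = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            cols = line.split("\t")
            if len(cols) < 7 or not cols[4].startswith("GO:"):
                n_malformed += 1
                continue
            qualifier = cols[3]
            if "NOT" in qualifier.split("|"):
                continue
            if evidence_allow is not None and cols[6] not in evidence_allow:
                continue
            records.append((cols[1], cols[4]))
    if n_malformed:
        logger.warning("%s: skipped %d malformed GAF rows", path, n_malformed)
    return _build(dag, records, str(path))


def load_annotation_tsv(path: str | Path, dag: GoDag) -> AnnotationDatabase:
    """Load the minimal two-column dialect (protein_id <TAB> go_id)."""
    records: list[tuple[str, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) >= 2:
                records.append((cols[0], cols[1]))
    return _build(dag, records, str(path))
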