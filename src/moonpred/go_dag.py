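"""Gene Ontology DAG: OBO parsing, ancestor closure, and propagation.

The GO is three disjoint rooted DAGs (molecular_function, biological_process,
cellular_component).  Only ``is_a`` edges define the hierarchy here;
``part_of`` and other relationship types are deliberately ignored so that
"parental terms" always means the is_a closure.  Propagation therefore never
crosses namespaces.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet

GO_ID_RE = re.compile(r"^GO:[0-9]{7}$")

NAMESPACES = ("molecular_function", "biological_process", "cellular_component")


class OboFormatError(ValueError):
    """Raised when an OBO file violates structural requirements (e.g. cycles)."""


class UnknownTermError(KeyError):
    """Raised when a GO accession cannot be resolved in the DAG."""


@dataclass(frozen=True)
class GoTerm:
    """One GO term: accession, name, namespace, and its is_a parents."""

    id: str
    name: str
    namespace: str
    parents: frozenset[str] = field(default_factory=frozenset)
    obsolete: bool = False


class GoDag:
    """The ontology as a map of :class:`GoTerm` plus traversal services.

    Parameters
    ----------
    terms:
        Mapping of primary accession to :class:`GoTerm`.  Parent accessions
        must all be present in the mapping.
    alt_id_map:
        Optional mapping of alternate (merged) accessions to primary ones.
        All public entry points resolve alt_ids transparently.
    """

    def __init__(self, terms: Mapping[str, GoTerm], alt_id_map: Mapping[str, str] | None = None):
        self.terms: dict[str, GoTerm] = dict(terms)
        self.alt_id_map: dict[str, str] = dict(alt_id_map or {})
        for term in self.terms.values():
            for parent in term.parents:
                if parent not in self.terms:
                    raise OboFormatError(f"term {term.id} references unknown parent {parent}")
        self._check_acyclic()
        self.roots: frozenset[str] = frozenset(
            t.id for t in self.terms.values() if not t.parents and not t.obsolete
        )
        self._ancestor_cache: dict[str, frozenset[str]] = {}

    def _check_acyclic(self) -> None:
        graph = nx.DiGraph()
        graph.add_nodes_from(self.terms)
        for term in self.terms.values():
            for parent in term.parents:
                graph.add_edge(term.id, parent)
        try:
            cycle = nx.find_cycle(graph)
        except nx.NetworkXNoCycle:
            return
        raise OboFormatError(f"is_a graph contains a cycle through {cycle[0][0]}")

    # -- lookup ---------------------------------------------------------

    def resolve(self, accession: str) -> str:
        """Return the primary accession for ``accession`` (alt_id aware)."""
        if accession in self.terms:
            return accession
        if accession in self.alt_id_map:
            return self.alt_id_map[accession]
        raise UnknownTermError(accession)

    def __contains__(self, accession: str) -> bool:
        return accession in self.terms or accession in self.alt_id_map

    def __getitem__(self, accession: str) -> GoTerm:
        return self.terms[self.resolve(accession)]

    def __len__(self) -> int:
        return len(self.terms)

    # -- traversal ------------------------------------------------------

    def ancestors(self, accession: str) -> frozenset[str]:
        """All terms reachable via is_a parents, excluding the term itself.

        Includes the namespace root.  Obsolete terms have no parents, so
        their ancestor set is empty.
        """
        acc = self.resolve(accession)
        cached = self._ancestor_cache.get(acc)
        if cached is not None:
            return cached
        out: set[str] = set()
        stack = list(self.terms[acc].parents)
        while stack:
            p = stack.pop()
            if p in out:
                continue
            out.add(p)
            cached_p = self._ancestor_cache.get(p)
            if cached_p is not None:
                out |= cached_p
            else:
                stack.extend(self.terms[p].parents)
        result = frozenset(out)
        self._ancestor_cache[acc] = result
        return result

    def propagate(self, accessions: Iterable[str]) -> frozenset[str]:
        """Close a term set under the ancestor relation (idempotent)."""
        out: set[str] = set()
        for acc in accessions:
            primary = self.resolve(acc)
            out.add(primary)
            out |= self.ancestors(primary)
        return frozenset(out)

    # -- serialization --------------------------------------------------

    def to_obo(self, path: str | Path) -> None:
        """Re-serialize the DAG to a minimal OBO 1.2 file.

        Emits only the tags this package reads (id, name, namespace, alt_id,
        is_a, is_obsolete), in sorted accession order so output is
        deterministic.
        """
        alt_by_primary: dict[str, list[str]] = {}
        for alt, primary in sorted(self.alt_id_map.items()):
            alt_by_primary.setdefault(primary, []).append(alt)
        lines = ["format-version: 1.2", "ontology: moonpred-synthetic", ""]
        for acc in sorted(self.terms):
            term = self.terms[acc]
            lines.append("[Term]")
            lines.append(f"id: {term.id}")
            lines.append(f"name: {term.name}")
            lines.append(f"namespace: {term.namespace}")
            for alt in alt_by_primary.get(acc, []):
                lines.append(f"alt_id: {alt}")
            for parent in sorted(term.parents):
                lines.append(f"is_a: {parent} ! {self.terms[parent].name}")
            if term.obsolete:
                lines.append("is_obsolete: true")
            lines.append("")
        Path(path).write_text("\n".join(lines))


def parse_obo(path: str | Path) -> GoDag:
    """Parse an OBO 1.2/1.4 ontology file into a :class:`GoDag`.

    Only ``is_a`` edges are kept.  Obsolete terms are retained (flagged,
    parentless) so that lookups can report them, but they never participate
    in traversal.  ``alt_id`` tags populate the alt_id map.

    Raises
    ------
    OSError
        If the file cannot be read.
    OboFormatError
        If the is_a graph is cyclic or a parent reference dangles.
    """
    graph = obonet.read_obo(str(path), ignore_obsolete=False)
    terms: dict[str, GoTerm] = {}
    alt_id_map: dict[str, str] = {}
    for node, data in graph.nodes(data=True):
        obsolete = str(data.get("is_obsolete", "false")).lower() == "true"
        parents = frozenset() if obsolete else frozenset(data.get("is_a", []))
        terms[node] = GoTerm(
            id=node,
            name=data.get("name", node),
            namespace=data.get("namespace", ""),
            parents=parents,
            obsolete=obsolete,
        )
        for alt in data.get("alt_id", []):
            alt_id_map[alt] = node
    return GoDag(terms, alt_id_map)
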