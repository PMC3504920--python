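"""Deterministic synthetic fixtures: GO DAG, annotation corpus, hits, truth.

The generator emulates the study design for moonlighting-protein function
prediction: a cohort of query proteins, each with two distinct planted
functions.  Each moonlighting query receives two clusters of sequence hits —
one annotated predominantly with its function-1 terms and drawn from the
*strong* (low) half of the E-value range, one annotated with function-2
terms and drawn from the *weak* half.  The second function therefore lives
in marginal homologs, the regime a more permissive search (e.g. a shallower
substitution matrix, or a looser transfer cutoff) is needed to reach.

No sequences are generated — only hit tables, annotations, and ontology
structure — so fixtures stay tiny and byte-deterministic for a given seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from moonpred.go_dag import GoDag, GoTerm, NAMESPACES


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset; identical specs give identical bytes.

    ``e_value_log10_range`` is the log10 interval E-values are drawn from.
    Function-1 hit clusters sample its lower (strong) half; function-2
    clusters and spurious background hits sample its upper (weak) half.
    ``function_overlap`` is the number of terms labeled ``both`` per
    moonlighting query.
    """

    seed: int = 1
    n_terms: int = 60            # per namespace
    max_parents: int = 2
    n_proteins: int = 150        # background corpus proteins
    annotations_per_protein: tuple[int, int] = (3, 8)
    n_queries: int = 19
    hits_per_query: tuple[int, int] = (16, 28)
    e_value_log10_range: tuple[float, float] = (-6.0, 2.0)
    moonlighting_fraction: float = 1.0
    function_overlap: int = 1
    cluster_size: int = 4        # hits per planted function cluster
    n_function_terms: int = 3    # terms per planted function

    def validate(self) -> None:
        if self.n_terms < 3:
            raise ValueError("need at least 3 terms per namespace")
        if self.max_parents < 1:
            raise ValueError("max_parents must be >= 1")
        lo, hi = self.annotations_per_protein
        if not 1 <= lo <= hi:
            raise ValueError("bad annotations_per_protein range")
        lo, hi = self.hits_per_query
        if not (1 <= lo <= hi):
            raise ValueError("bad hits_per_query range")
        if self.e_value_log10_range[0] >= self.e_value_log10_range[1]:
            raise ValueError("bad e_value_log10_range")
        if not 0 <= self.moonlighting_fraction <= 1:
            raise ValueError("moonlighting_fraction must be in [0, 1]")


TINY = FixtureSpec(n_terms=14, max_parents=2, n_proteins=24,
                   annotations_per_protein=(2, 4), n_queries=4,
                   hits_per_query=(8, 12), cluster_size=2, n_function_terms=2)

PRESETS = {"tiny": TINY, "paper-scale": FixtureSpec()}


@dataclass
class FixtureManifest:
    """What the generator planted, for oracle-style verification."""

    seed: int
    files: dict[str, str]                       # filename -> sha256
    n_proteins: int                             # corpus proteins in the GAF
    moonlighting: list[str]                     # query ids with two functions
    function1: dict[str, list[str]]             # query -> f1 term ids
    function2: dict[str, list[str]]             # query -> f2 term ids
    term_counts: dict[str, int] = field(default_factory=dict)  # direct GAF counts

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _build_dag(spec: FixtureSpec, rng: np.random.Generator) -> GoDag:
    """Random rooted DAG per namespace: parents sampled from earlier terms."""
    terms: dict[str, GoTerm] = {}
    alt_id_map: dict[str, str] = {}
    next_id = 1

    def make_id() -> str:
        nonlocal next_id
        acc = f"GO:{next_id:07d}"
        next_id += 1
        return acc

    for namespace in NAMESPACES:
        ns_ids: list[str] = []
        for k in range(spec.n_terms):
            acc = make_id()
            if k == 0:
                parents: frozenset[str] = frozenset()
            else:
                n_par = int(rng.integers(1, min(spec.max_parents, k) + 1))
                idx = rng.choice(k, size=n_par, replace=False)
                parents = frozenset(ns_ids[i] for i in sorted(idx))
            terms[acc] = GoTerm(id=acc, name=f"synthetic {namespace} term {k}",
                                namespace=namespace, parents=parents)
            ns_ids.append(acc)
        # one obsolete stanza and one alt_id per namespace, to exercise parsing
        obsolete = make_id()
        terms[obsolete] = GoTerm(id=obsolete, name=f"obsolete {namespace} term",
                                 namespace=namespace, obsolete=True)
        alt_id_map[make_id()] = ns_ids[1]
    return GoDag(terms, alt_id_map)


def _annotatable(dag: GoDag) -> list[str]:
    return sorted(t.id for t in dag.terms.values() if not t.obsolete and t.parents)


def _log_uniform_e(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(10.0 ** rng.uniform(lo, hi))


def generate_fixtures(spec: FixtureSpec, out_dir: str | Path) -> FixtureManifest:
    """Emit fixture.obo, fixture.gaf, hits.tsv, truth.tsv and manifest.json.

    The emitted dataset is fully determined by ``spec`` (including its seed):
    the same spec always produces byte-identical files.
    """
    spec.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    dag = _build_dag(spec, rng)
    pool = _annotatable(dag)

    queries = [f"Q{k + 1:02d}" for k in range(spec.n_queries)]
    n_moon = round(spec.moonlighting_fraction * spec.n_queries)
    moonlighting = queries[:n_moon]

    # -- planted truth ---------------------------------------------------
    function1: dict[str, list[str]] = {}
    function2: dict[str, list[str]] = {}
    truth_rows: list[tuple[str, str, str]] = []
    for q in queries:
        n_pick = 2 * spec.n_function_terms + spec.function_overlap + 2
        picked = [pool[i] for i in rng.choice(len(pool), size=n_pick, replace=False)]
        f1 = picked[: spec.n_function_terms]
        f2 = picked[spec.n_function_terms: 2 * spec.n_function_terms]
        both = picked[2 * spec.n_function_terms: 2 * spec.n_function_terms + spec.function_overlap]
        neither = picked[2 * spec.n_function_terms + spec.function_overlap:]
        if q in moonlighting:
            function1[q] = sorted(f1)
            function2[q] = sorted(f2)
            for t in f1:
                truth_rows.append((q, t, "function1"))
            for t in f2:
                truth_rows.append((q, t, "function2"))
            for t in both:
                truth_rows.append((q, t, "both"))
        else:
            for t in f1 + f2 + both:
                truth_rows.append((q, t, "function1"))
        for t in neither:
            truth_rows.append((q, t, "neither"))

    # -- corpus proteins ---------------------------------------------------
    annotations: dict[str, list[str]] = {}
    lo_ann, hi_ann = spec.annotations_per_protein
    for k in range(spec.n_proteins):
        pid = f"P{k + 1:04d}"
        n_ann = int(rng.integers(lo_ann, hi_ann + 1))
        idx = rng.choice(len(pool), size=min(n_ann, len(pool)), replace=False)
        annotations[pid] = sorted(pool[i] for i in idx)

    # cluster proteins: carriers of the planted function terms
    cluster_members: dict[str, tuple[list[str], list[str]]] = {}
    for q in queries:
        c1_ids, c2_ids = [], []
        f1 = function1.get(q, [t for p, t, l in truth_rows if p == q and l == "function1"])
        f2 = function2.get(q, f1)
        both = [t for p, t, l in truth_rows if p == q and l == "both"]
        for c in range(spec.cluster_size):
            pid = f"{q}C1{c + 1:02d}"
            terms = [t for t in f1 + both if rng.random() < 0.8] or [f1[0]]
            noise = pool[int(rng.integers(len(pool)))]
            annotations[pid] = sorted(set(terms) | {noise})
            c1_ids.append(pid)
        for c in range(spec.cluster_size):
            pid = f"{q}C2{c + 1:02d}"
            terms = [t for t in f2 + both if rng.random() < 0.8] or [f2[0]]
            noise = pool[int(rng.integers(len(pool)))]
            annotations[pid] = sorted(set(terms) | {noise})
            c2_ids.append(pid)
        cluster_members[q] = (c1_ids, c2_ids)

    # -- hit tables --------------------------------------------------------
    e_lo, e_hi = spec.e_value_log10_range
    e_mid = (e_lo + e_hi) / 2.0
    background = sorted(p for p in annotations if p.startswith("P"))
    hit_rows: list[tuple[str, str, float]] = []
    for q in queries:
        c1_ids, c2_ids = cluster_members[q]
        for pid in c1_ids:  # strong cluster: function 1
            hit_rows.append((q, pid, _log_uniform_e(rng, e_lo, e_mid)))
        for pid in c2_ids:  # weak cluster: function 2
            hit_rows.append((q, pid, _log_uniform_e(rng, e_mid, e_hi)))
        lo_h, hi_h = spec.hits_per_query
        n_total = int(rng.integers(lo_h, hi_h + 1))
        n_bg = max(0, n_total - len(c1_ids) - len(c2_ids))
        idx = rng.choice(len(background), size=min(n_bg, len(background)), replace=False)
        for i in sorted(idx):
            # spurious background hits are weak, like real chance homology
            hit_rows.append((q, background[i], _log_uniform_e(rng, e_mid, e_hi)))
        # second-level searches: each cluster member finds its cluster mates
        for ids in (c1_ids, c2_ids):
            for seed_pid in ids:
                for mate in ids:
                    if mate != seed_pid:
                        hit_rows.append((seed_pid, mate, _log_uniform_e(rng, e_lo, e_mid)))

    # -- emit files --------------------------------------------------------
    dag.to_obo(out / "fixture.obo")

    aspect = {"molecular_function": "F", "biological_process": "P",
              "cellular_component": "C"}
    gaf_lines = ["!gaf-version: 2.2"]
    for pid in sorted(annotations):
        for term in annotations[pid]:
            ns = dag[term].namespace
            gaf_lines.append("\t".join([
                "MOONPRED", pid, pid, "involved_in", term, "MOONPRED:0000001",
                "IEA", "", aspect.get(ns, "P"), pid, "", "protein", "taxon:0000",
                "20120101", "MOONPRED", "", "",
            ]))
    (out / "fixture.gaf").write_text("\n".join(gaf_lines) + "\n")

    hit_lines = [f"{q}\t{s}\t{e:.4e}" for q, s, e in hit_rows]
    (out / "hits.tsv").write_text("\n".join(hit_lines) + "\n")

    truth_lines = [f"{p}\t{t}\t{l}" for p, t, l in truth_rows]
    (out / "truth.tsv").write_text("\n".join(truth_lines) + "\n")

    term_counts: dict[str, int] = {}
    for terms in annotations.values():
        for t in terms:
            term_counts[t] = term_counts.get(t, 0) + 1

    manifest = FixtureManifest(
        seed=spec.seed,
        files={},
        n_proteins=len(annotations),
        moonlighting=moonlighting,
        function1=function1,
        function2=function2,
        term_counts=dict(sorted(term_counts.items())),
    )
    for name in ("fixture.obo", "fixture.gaf", "hits.tsv", "truth.tsv"):
        manifest.files[name] = _sha256(out / name)
    (out / "manifest.json").write_text(manifest.to_json() + "\n")
    return manifest
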