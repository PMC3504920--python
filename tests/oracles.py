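"""Independent brute-force oracles and random tiny-instance generators.

These deliberately re-derive the scoring rules with plain loops and direct
counting — no code is shared with the implementations they check.
"""

from __future__ import annotations

import math
import random

from moonpred.annotation_db import AnnotationDatabase
from moonpred.go_dag import GoDag, GoTerm
from moonpred.search_io import SearchHit, SearchResult, TableSearchProvider

E_FLOOR = 1e-180


def pfp_direct_oracle(hits: list[tuple[float, set[str]]], corpus: dict[str, set[str]],
                      candidates: list[str], b: float = 2.0,
                      e_max: float = 100.0) -> dict[str, float]:
    """Quadruple loop over hits x hit annotations x candidate terms x corpus."""
    scores: dict[str, float] = {}
    for fa in candidates:
        total = 0.0
        for e_value, annotations in hits:
            if e_value > e_max:
                continue
            weight = -math.log10(max(e_value, E_FLOOR)) + b
            for fj in annotations:
                n_fj = sum(1 for terms in corpus.values() if fj in terms)
                if n_fj == 0:
                    continue
                n_co = sum(1 for terms in corpus.values() if fj in terms and fa in terms)
                total += weight * (n_co / n_fj)
        if total > 0:
            scores[fa] = total
    return scores


def pfp_raw_oracle(direct_scores: dict[str, float], parents: dict[str, set[str]],
                   prop_counts: dict[str, int]) -> dict[str, float]:
    """Raw score: direct plus descendant-sum parental transfer, per descendant once."""

    def closure(term: str) -> set[str]:
        out: set[str] = set()
        stack = list(parents[term])
        while stack:
            p = stack.pop()
            if p not in out:
                out.add(p)
                stack.extend(parents[p])
        return out

    raw = dict(direct_scores)
    for fa, score in direct_scores.items():
        n_fa = prop_counts.get(fa, 0)
        if n_fa == 0:
            continue
        for p in closure(fa):
            n_p = prop_counts.get(p, 0)
            if n_p == 0:
                continue
            raw[p] = raw.get(p, 0.0) + score * n_fa / n_p
    return raw


def esg_oracle(tables: dict[str, list[tuple[str, float, set[str]]]], query: str,
               level_weights: tuple[float, float] = (0.5, 0.5), n_first: int = 10,
               e_max: float = 100.0) -> dict[str, float]:
    """Two-level enumeration of the similarity-group score."""

    def level(rows: list[tuple[str, float, set[str]]], exclude: set[str]):
        eligible = [(s, e, a) for s, e, a in sorted(rows, key=lambda r: r[1])
                    if e <= e_max and s not in exclude]
        raw = [(s, max(0.0, -math.log10(max(e, E_FLOOR))), a) for s, e, a in eligible]
        total = sum(w for _, w, _ in raw)
        if total <= 0:
            return None
        return [(s, w / total, a) for s, w, a in raw]

    lw1, lw2 = level_weights
    scores: dict[str, float] = {}
    first = level(tables[query], exclude={query})
    if first is None:
        return scores
    for _, weight, annotations in first:
        for f in annotations:
            scores[f] = scores.get(f, 0.0) + lw1 * weight
    seeds = [(s, w) for s, w, _ in first if w > 0][:n_first]
    for seed, w_seed in seeds:
        if seed not in tables:
            continue
        second = level(tables[seed], exclude={query, seed})
        if second is None:
            continue
        for _, v, annotations in second:
            for f in annotations:
                scores[f] = scores.get(f, 0.0) + lw2 * w_seed * v
    return scores


# -- random tiny instances -------------------------------------------------


def random_small_dag(rng: random.Random, n_terms: int = 10) -> GoDag:
    ids = [f"GO:{k + 1:07d}" for k in range(n_terms)]
    terms = {}
    for k, acc in enumerate(ids):
        if k == 0:
            parents: frozenset[str] = frozenset()
        else:
            n_par = rng.randint(1, min(2, k))
            parents = frozenset(rng.sample(ids[:k], n_par))
        terms[acc] = GoTerm(acc, acc, "molecular_function", parents)
    return GoDag(terms)


def random_corpus(rng: random.Random, dag: GoDag, n_proteins: int = 8) -> dict[str, set[str]]:
    pool = sorted(dag.terms)
    return {
        f"p{k}": set(rng.sample(pool, rng.randint(1, min(4, len(pool)))))
        for k in range(n_proteins)
    }


def random_pfp_instance(seed: int):
    """A small (dag, db, result, hits-as-tuples, corpus) PFP problem."""
    rng = random.Random(seed)
    dag = random_small_dag(rng)
    corpus = random_corpus(rng, dag)
    db = AnnotationDatabase(dag=dag, direct={p: frozenset(s) for p, s in corpus.items()})
    subjects = rng.sample(sorted(corpus), rng.randint(1, 5))
    hits = [SearchHit(s, 10 ** rng.uniform(-12, 2.2), frozenset(corpus[s])) for s in subjects]
    result = SearchResult.from_hits("query", hits)
    plain = [(h.e_value, set(h.annotations)) for h in result.hits]
    return dag, db, result, plain, corpus


def random_esg_instance(seed: int):
    """A small table-backed two-level search problem.

    Returns (provider, db, query, tables) where ``tables`` is the plain-dict
    mirror the brute-force oracle consumes.
    """
    rng = random.Random(seed)
    dag = random_small_dag(rng)
    corpus = random_corpus(rng, dag, n_proteins=10)
    db = AnnotationDatabase(dag=dag, direct={p: frozenset(s) for p, s in corpus.items()})
    proteins = sorted(corpus)
    query = "query"
    tables: dict[str, list[tuple[str, float, set[str]]]] = {}
    first_subjects = rng.sample(proteins, rng.randint(1, 5))
    tables[query] = [(s, 10 ** rng.uniform(-9, 0.9), set(corpus[s])) for s in first_subjects]
    for s in first_subjects:
        if rng.random() < 0.8:  # some seeds lack a second-level search
            mates = rng.sample(proteins, rng.randint(1, 4))
            tables[s] = [(m, 10 ** rng.uniform(-9, 0.9), set(corpus[m])) for m in mates]
    results = {
        q: SearchResult.from_hits(q, [SearchHit(s, e, frozenset(a)) for s, e, a in rows])
        for q, rows in tables.items()
    }
    return TableSearchProvider(results), db, query, tables
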