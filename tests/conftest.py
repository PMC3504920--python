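"""Shared test fixtures: toy DAGs, corpora, and generated synthetic datasets."""

from __future__ import annotations

from pathlib import Path

import pytest
from hypothesis import settings

from moonpred.annotation_db import AnnotationDatabase

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from moonpred.fixtures import TINY, FixtureSpec, generate_fixtures
from moonpred.go_dag import GoDag, GoTerm


def make_dag(parents: dict[str, set[str]], namespace: str = "molecular_function",
             obsolete: set[str] = frozenset(), alt_ids: dict[str, str] | None = None) -> GoDag:
    """Build a GoDag from a plain {term: parent set} mapping."""
    terms = {
        t: GoTerm(id=t, name=t, namespace=namespace, parents=frozenset(p),
                  obsolete=t in obsolete)
        for t, p in parents.items()
    }
    return GoDag(terms, alt_ids or {})


def gid(k: int) -> str:
    """k-th synthetic GO accession."""
    return f"GO:{k:07d}"


@pytest.fixture(scope="session")
def chain_dag() -> GoDag:
    """A <- B <- C linear hierarchy."""
    a, b, c = gid(1), gid(2), gid(3)
    return make_dag({a: set(), b: {a}, c: {b}})


@pytest.fixture(scope="session")
def diamond_dag() -> GoDag:
    """A <- {B, C} <- D."""
    a, b, c, d = gid(1), gid(2), gid(3), gid(4)
    return make_dag({a: set(), b: {a}, c: {a}, d: {b, c}})


@pytest.fixture(scope="session")
def flat_dag() -> GoDag:
    """One root with five leaf children."""
    root = gid(10)
    leaves = {gid(11 + k): {root} for k in range(5)}
    return make_dag({root: set(), **leaves})


def make_db(dag: GoDag, corpus: dict[str, set[str]]) -> AnnotationDatabase:
    return AnnotationDatabase(dag=dag, direct={p: frozenset(t) for p, t in corpus.items()})


@pytest.fixture(scope="session")
def paper_fixture_dir(tmp_path_factory) -> Path:
    """The default (study-scale) synthetic dataset, generated once per session."""
    out = tmp_path_factory.mktemp("paper_fixture")
    generate_fixtures(FixtureSpec(seed=1), out)
    return out


@pytest.fixture(scope="session")
def tiny_fixture_dir(tmp_path_factory) -> Path:
    out = tmp_path_factory.mktemp("tiny_fixture")
    generate_fixtures(TINY, out)
    return out


@pytest.fixture(scope="session")
def paper_data(paper_fixture_dir):
    """Parsed DAG, corpus, search results, and truth of the study-scale dataset."""
    from moonpred import load_gaf, load_truth, parse_blast_tabular, parse_obo

    dag = parse_obo(paper_fixture_dir / "fixture.obo")
    db = load_gaf(paper_fixture_dir / "fixture.gaf", dag)
    results = parse_blast_tabular(paper_fixture_dir / "hits.tsv", db)
    truths = load_truth(paper_fixture_dir / "truth.tsv", dag)
    return dag, db, results, truths
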