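"""Precision/recall evaluation of GO predictions for moonlighting proteins.

Predicted and true term sets are both closed upward to the ontology roots
before counting, so that predicting a specific child also earns credit for
every implied ancestor:

    precision = TP / (TP + FP),   recall = TP / (TP + FN)

computed on the propagated sets.  For moonlighting proteins, each true term
carries a label — ``function1`` (the major function), ``function2`` (the
second function), ``both``, or ``neither`` — and evaluation can be
restricted to a label subset, e.g. only the terms belonging to the two
moonlighting functions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from moonpred.go_dag import GoDag
from moonpred.predictions import PredictionSet
from moonpred.search_io import neglog_weight

LABELS = frozenset({"function1", "function2", "both", "neither"})
#: truth filter keeping every labeled term (identical to no filter)
ALL_LABELS = frozenset(LABELS)
#: truth filter keeping only terms that belong to a moonlighting function;
#: terms labeled "both" belong to each function, so they stay in
MOONLIGHTING_LABELS = frozenset({"function1", "function2", "both"})


class EvaluationError(ValueError):
    """Raised on empty truth sets or empty evaluation cohorts."""


@dataclass
class MoonlightingTruth:
    """Labeled true GO terms of one (putatively moonlighting) protein."""

    protein_id: str
    labels: dict[str, str]

    def __post_init__(self) -> None:
        bad = {l for l in self.labels.values() if l not in LABELS}
        if bad:
            raise ValueError(f"unknown truth labels {sorted(bad)} for {self.protein_id}")

    def terms(self, truth_filter: frozenset[str] = ALL_LABELS) -> frozenset[str]:
        """Terms whose label is in ``truth_filter``."""
        return frozenset(t for t, l in self.labels.items() if l in truth_filter)

    def is_moonlighting(self) -> bool:
        labels = set(self.labels.values())
        return ("function1" in labels or "both" in labels) and (
            "function2" in labels or "both" in labels
        )


def load_truth(path: str | Path, dag: GoDag) -> dict[str, MoonlightingTruth]:
    """Read a truth TSV (protein_id, go_id, label) into per-protein truth.

    GO accessions are resolved through the DAG (alt_id aware); an
    unresolvable accession is an error since the truth file is curated input.
    """
    labels: dict[str, dict[str, str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            protein, go_id, label = line.split("\t")[:3]
            labels.setdefault(protein, {})[dag.resolve(go_id)] = label
    return {p: MoonlightingTruth(protein_id=p, labels=l) for p, l in labels.items()}


@dataclass(frozen=True)
class PrPoint:
    """Confusion counts and precision/recall at one score cutoff.

    ``precision`` is None when nothing was predicted (0/0)."""

    cutoff: float
    tp: int
    fp: int
    fn: int
    precision: float | None
    recall: float


@dataclass
class PrCurve:
    """A precision/recall curve for one method over a cutoff grid."""

    method_tag: str
    points: list[PrPoint]
    averaging: str = "macro_over_proteins"
    n_proteins: int = 0


def _selected_terms(pred: PredictionSet, cutoff: float, cutoff_kind: str,
                    n_top: int = 1000) -> frozenset[str]:
    if cutoff_kind == "score":
        return pred.terms_at_score(cutoff)
    if cutoff_kind == "fraction":
        return pred.terms_at_fraction(cutoff, n_top=n_top)
    if cutoff_kind == "evalue":
        # an E-value threshold t corresponds to ranking score >= -log10(t) + 2
        return pred.terms_at_score(neglog_weight(cutoff, b=2.0))
    raise ValueError(f"unknown cutoff kind {cutoff_kind!r}")


def confusion_at_cutoff(pred: PredictionSet, truth_terms: frozenset[str], dag: GoDag,
                        cutoff: float, cutoff_kind: str = "score",
                        include_roots: bool = True, n_top: int = 1000) -> PrPoint:
    """Confusion counts at one cutoff, on root-propagated term sets.

    ``cutoff_kind`` selects how the cutoff is read: a raw score threshold
    (``"score"``), a ranked-list fraction of the top ``n_top`` predictions
    (``"fraction"``, the PFP convention), or an E-value (``"evalue"``, the
    BLAST-transfer convention).  With ``include_roots=False`` the namespace
    roots are dropped from both sets before counting, for a stricter
    evaluation in which the always-true roots earn no credit.
    """
    if not truth_terms:
        raise EvaluationError("empty truth set")
    predicted = dag.propagate(_selected_terms(pred, cutoff, cutoff_kind, n_top))
    truth = dag.propagate(truth_terms)
    if not include_roots:
        predicted -= dag.roots
        truth -= dag.roots
    tp = len(predicted & truth)
    fp = len(predicted - truth)
    fn = len(truth - predicted)
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    return PrPoint(cutoff=cutoff, tp=tp, fp=fp, fn=fn, precision=precision, recall=recall)


def pr_curve(preds: dict[str, PredictionSet], truths: dict[str, MoonlightingTruth],
             dag: GoDag, cutoffs: list[float],
             truth_filter: frozenset[str] = ALL_LABELS, cutoff_kind: str = "score",
             include_roots: bool = True, average: str = "macro",
             n_top: int = 1000) -> PrCurve:
    """Average precision/recall over a protein cohort at each cutoff.

    With ``average="macro"`` (default), precision is averaged over proteins
    with at least one prediction at the cutoff, while every protein
    contributes to the recall average (recall 0 when nothing is predicted).
    ``average="micro"`` pools the confusion counts across proteins first.
    Proteins whose filtered truth set is empty are excluded throughout.
    """
    if not preds:
        raise EvaluationError("no proteins to evaluate")
    unknown = set(preds) - set(truths)
    if unknown:
        raise EvaluationError(f"predictions without truth: {sorted(unknown)}")
    cohort = {p: truths[p].terms(truth_filter) for p in sorted(preds)}
    cohort = {p: t for p, t in cohort.items() if t}
    if not cohort:
        raise EvaluationError("truth filter removed every protein")
    method_tags = {preds[p].method_tag for p in cohort}
    points: list[PrPoint] = []
    for cutoff in cutoffs:
        pts = [confusion_at_cutoff(preds[p], cohort[p], dag, cutoff, cutoff_kind,
                                   include_roots, n_top) for p in cohort]
        if average == "micro":
            tp = sum(p.tp for p in pts)
            fp = sum(p.fp for p in pts)
            fn = sum(p.fn for p in pts)
            precision = tp / (tp + fp) if (tp + fp) > 0 else None
            recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
            points.append(PrPoint(cutoff, tp, fp, fn, precision, recall))
        elif average == "macro":
            defined = [p.precision for p in pts if p.precision is not None]
            precision = sum(defined) / len(defined) if defined else None
            recall = sum(p.recall for p in pts) / len(pts)
            points.append(PrPoint(cutoff, sum(p.tp for p in pts), sum(p.fp for p in pts),
                                  sum(p.fn for p in pts), precision, recall))
        else:
            raise ValueError(f"unknown averaging mode {average!r}")
    tag = method_tags.pop() if len(method_tags) == 1 else "mixed"
    return PrCurve(method_tag=tag, points=points,
                   averaging=f"{average}_over_proteins", n_proteins=len(cohort))


#: how each method's headline fixed cutoff is interpreted
DEFAULT_CUTOFF_KINDS = {"pfp": "fraction", "esg": "score", "blast": "evalue"}
#: the headline per-protein operating points: PFP keeps the top half of its
#: 1000-term ranked list, ESG thresholds its [0,1] score at 0.35, and the
#: BLAST baseline keeps transfers from hits better than E = 0.01
DEFAULT_FIXED_CUTOFFS = {"pfp": 0.5, "esg": 0.35, "blast": 0.01}


def per_protein_recall(preds_by_method: dict[str, dict[str, PredictionSet]],
                       truths: dict[str, MoonlightingTruth], dag: GoDag,
                       fixed_cutoffs: dict[str, float] | None = None,
                       truth_filter: frozenset[str] = ALL_LABELS,
                       cutoff_kinds: dict[str, str] | None = None,
                       include_roots: bool = True,
                       n_top: int = 1000) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Recall of each method for each protein at its fixed operating cutoff.

    Returns ``(recall, flagged)``: two protein × method DataFrames, the
    second marking (protein, method) cells where the method produced no
    predictions at all — those are recorded as recall 0, mirroring a method
    that fails to predict any GO term for a protein.
    """
    fixed_cutoffs = dict(DEFAULT_FIXED_CUTOFFS if fixed_cutoffs is None else fixed_cutoffs)
    kinds = dict(DEFAULT_CUTOFF_KINDS)
    if cutoff_kinds:
        kinds.update(cutoff_kinds)
    proteins = sorted({p for preds in preds_by_method.values() for p in preds} | set(truths))
    proteins = [p for p in proteins if p in truths and truths[p].terms(truth_filter)]
    methods = sorted(preds_by_method)
    recall = pd.DataFrame(0.0, index=proteins, columns=methods)
    flagged = pd.DataFrame(False, index=proteins, columns=methods)
    for method in methods:
        cutoff = fixed_cutoffs[method]
        kind = kinds.get(method, "score")
        for protein in proteins:
            pred = preds_by_method[method].get(protein)
            if pred is None or not pred.scores:
                flagged.loc[protein, method] = True
                continue
            point = confusion_at_cutoff(pred, truths[protein].terms(truth_filter), dag,
                                        cutoff, kind, include_roots, n_top)
            recall.loc[protein, method] = point.recall
    return recall, flagged


def write_pr_curve(curve: PrCurve, path: str | Path) -> None:
    """Write a PR curve as TSV (cutoff, mean_precision, mean_recall, n_proteins)."""
    lines = [f"# method: {curve.method_tag}", f"# averaging: {curve.averaging}",
             "cutoff\tprecision\trecall\tn_proteins"]
    for pt in curve.points:
        prec = "NA" if pt.precision is None else f"{pt.precision:.10g}"
        lines.append(f"{pt.cutoff:.10g}\t{prec}\t{pt.recall:.10g}\t{curve.n_proteins}")
    Path(path).write_text("\n".join(lines) + "\n")
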