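"""Assessment statistics for binding-site predictors.

Pooling residues from different proteins into one ROC compares binding
sites of one protein against non-binding sites of another — proteins
differ in interface size and affinity, so those comparisons are not
meaningful.  The central quantities here therefore work per protein:

* ``AUC(i)`` — per-protein ROC AUC (Mann–Whitney with midrank ties);
* ``wAUC = Σ AUC(i)·len(i) / Σ len(i)`` — length-weighted mean;
* ``mAUC = Σ AUC(i) / N`` — unweighted mean;
* ``tAUC`` — the pooled ("total") AUC over all residues, kept as a
  reference for comparison with the per-protein view;
* ``sAUC`` — sample standard deviation of the per-protein AUCs, a
  dataset-stability measure.

Cutoff stability of a wAUC series over the distance-cutoff ladder:

* ``MAV  = max |ΔwAUC|`` over consecutive cutoff pairs;
* ``MAVR = max |ΔwAUC| / Δd`` (maximum accuracy variation rate);
* ``CAVR = Σ |ΔwAUC| / Δd`` (cumulated rate).

Binary metrics use the standard confusion-matrix definitions
(sensitivity TP/(TP+FN), specificity TN/(TN+FP), precision, accuracy,
F1, MCC); a zero denominator yields 0 with a degenerate flag.

The binding-funnel correlation is the Pearson ρ between a residue's
minimum distance to the nucleic acid and its prediction score over
residues within a funnel radius (12 Å default): a predictor whose score
decays smoothly away from the interface gives ρ < 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .binding_annotation import BindingAnnotation
from .prediction_io import PredictionSet

__all__ = [
    "PerProteinEval",
    "ConfusionCounts",
    "BinaryMetrics",
    "AggregateAuc",
    "StabilityReport",
    "FunnelResult",
    "roc_auc",
    "evaluate_protein",
    "aggregate_auc",
    "pooled_auc",
    "sauc",
    "confusion_counts",
    "binary_metrics",
    "stability",
    "min_performance",
    "funnel_correlation",
    "discrimination_auc",
]


# ---------------------------------------------------------------- ROC / AUC

def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float | None:
    """ROC AUC via the Mann–Whitney rank formulation, midrank ties.

    AUC = (Σ ranks of positives − n_pos(n_pos+1)/2) / (n_pos·n_neg),
    identical to counting positive–negative pairs with ties scored ½.
    Returns ``None`` (undefined) when labels are single-class; callers
    must propagate that flag rather than substitute a number.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos + n_neg != len(labels):
        raise ValueError("labels must be 0/1")
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(scores, method="average")
    rank_sum = ranks[labels == 1].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass
class PerProteinEval:
    """AUC of one protein plus the counts the aggregates weight by."""

    protein_id: str
    auc: float | None
    length: int
    n_pos: int
    n_neg: int


def evaluate_protein(
    protein_id: str, scores: Sequence[float], labels: Sequence[int]
) -> PerProteinEval:
    labels = np.asarray(labels)
    return PerProteinEval(
        protein_id=protein_id,
        auc=roc_auc(scores, labels),
        length=len(labels),
        n_pos=int((labels == 1).sum()),
        n_neg=int((labels == 0).sum()),
    )


@dataclass
class AggregateAuc:
    wauc: float
    mauc: float
    n_proteins: int  # proteins entering the averages
    n_excluded_undefined_auc: int


def aggregate_auc(evals: Sequence[PerProteinEval]) -> AggregateAuc:
    """Length-weighted and unweighted mean AUC over a dataset.

    Proteins whose AUC is undefined (single-class labels at this cutoff)
    are excluded from both sums and counted; wAUC weights by the length
    of included proteins only.
    """
    defined = [e for e in evals if e.auc is not None]
    if not defined:
        raise ValueError("no protein has a defined AUC; cannot aggregate")
    total_len = sum(e.length for e in defined)
    wauc = sum(e.auc * e.length for e in defined) / total_len
    mauc = sum(e.auc for e in defined) / len(defined)
    return AggregateAuc(
        wauc=float(wauc),
        mauc=float(mauc),
        n_proteins=len(defined),
        n_excluded_undefined_auc=len(evals) - len(defined),
    )


def pooled_auc(
    per_protein: Iterable[tuple[Sequence[float], Sequence[int]]],
) -> float | None:
    """Total AUC (tAUC): all residues of all proteins pooled into one ROC."""
    scores: list[float] = []
    labels: list[int] = []
    for s, l in per_protein:
        scores.extend(s)
        labels.extend(l)
    return roc_auc(scores, labels)


def sauc(evals: Sequence[PerProteinEval]) -> float | None:
    """Sample standard deviation (divisor N−1) of defined per-protein AUCs."""
    aucs = [e.auc for e in evals if e.auc is not None]
    if len(aucs) < 2:
        return None
    return float(np.std(aucs, ddof=1))


# ------------------------------------------------------------ binary metrics

@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def p_total(self) -> int:
        return self.tp + self.fn

    @property
    def n_total(self) -> int:
        return self.tn + self.fp

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn,
            self.fp + other.fp, self.fn + other.fn,
        )


def confusion_counts(
    predicted: Sequence[int], truth: Sequence[int]
) -> ConfusionCounts:
    """Confusion counts from 0/1 predicted and true labels."""
    pred = np.asarray(predicted)
    true = np.asarray(truth)
    if pred.shape != true.shape:
        raise ValueError("predicted and truth must have equal length")
    return ConfusionCounts(
        tp=int(((pred == 1) & (true == 1)).sum()),
        tn=int(((pred == 0) & (true == 0)).sum()),
        fp=int(((pred == 1) & (true == 0)).sum()),
        fn=int(((pred == 0) & (true == 1)).sum()),
    )


@dataclass
class BinaryMetrics:
    sen: float
    spc: float
    ppv: float
    acc: float
    f1: float
    mcc: float
    degenerate: frozenset[str] = field(default_factory=frozenset)


def binary_metrics(c: ConfusionCounts) -> BinaryMetrics:
    """Standard confusion-matrix metrics; zero denominators yield 0.

    MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)); if any factor
    of the root is 0, MCC is reported as 0 and flagged degenerate.
    """
    degenerate: set[str] = set()

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            degenerate.add(name)
            return 0.0
        return num / den

    sen = ratio(c.tp, c.tp + c.fn, "sen")
    spc = ratio(c.tn, c.tn + c.fp, "spc")
    ppv = ratio(c.tp, c.tp + c.fp, "ppv")
    acc = ratio(c.tp + c.tn, c.tp + c.tn + c.fp + c.fn, "acc")
    f1 = ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, "f1")
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        degenerate.add("mcc")
        mcc = 0.0
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
    return BinaryMetrics(sen, spc, ppv, acc, f1, mcc, frozenset(degenerate))


# ---------------------------------------------------------- cutoff stability

@dataclass
class StabilityReport:
    mavr: float
    mav: float
    cavr: float
    deltas: list[tuple[tuple[float, float], float, float]]  # ((c1,c2), |Δ|, Δd)


def stability(
    series: Mapping[float, float], all_pairs: bool = False
) -> StabilityReport | None:
    """MAVR / MAV / CAVR of an accuracy series over distance cutoffs.

    ``series`` maps cutoff (Å) → wAUC (or mAUC/tAUC).  Δ terms are
    absolute differences over consecutive cutoff pairs in ascending order
    (all unordered pairs with ``all_pairs=True``); Δd is the pair's cutoff
    spacing.  Returns ``None`` with fewer than two points.
    """
    cutoffs = sorted(series)
    if len(cutoffs) < 2:
        return None
    if all_pairs:
        pairs = [(a, b) for i, a in enumerate(cutoffs) for b in cutoffs[i + 1:]]
    else:
        pairs = list(zip(cutoffs, cutoffs[1:]))
    deltas = []
    for a, b in pairs:
        dv = abs(series[b] - series[a])
        dd = b - a
        deltas.append(((a, b), dv, dd))
    rates = [dv / dd for _, dv, dd in deltas]
    return StabilityReport(
        mavr=max(rates),
        mav=max(dv for _, dv, _ in deltas),
        cavr=sum(rates),
        deltas=deltas,
    )


def min_performance(
    results: Mapping[tuple[str, float], float],
) -> tuple[dict[str, tuple[float, float]], tuple[str, float, float]]:
    """Worst-case accuracy over datasets and cutoffs ("barrel effect").

    ``results`` maps (dataset, cutoff) → wAUC.  Returns per-dataset minima
    ``{dataset: (cutoff, wauc)}`` and the global minimum ``(dataset,
    cutoff, wauc)``.  Ties break toward the smallest cutoff, then the
    lexicographically smallest dataset name — the minimum a predictor can
    guarantee, with where it occurs.
    """
    if not results:
        raise ValueError("empty result map")
    per_dataset: dict[str, tuple[float, float]] = {}
    for (dataset, cutoff), value in results.items():
        cur = per_dataset.get(dataset)
        if cur is None or (value, cutoff) < (cur[1], cur[0]):
            per_dataset[dataset] = (cutoff, value)
    global_min = min(
        ((ds, c, v) for (ds, c), v in results.items()),
        key=lambda t: (t[2], t[1], t[0]),
    )
    return per_dataset, global_min


# -------------------------------------------------------- funnel correlation

@dataclass
class FunnelResult:
    protein_id: str
    rho: float | None  # signed Pearson ρ; None when undefined
    n_residues: int

    @property
    def abs_rho(self) -> float | None:
        return None if self.rho is None else abs(self.rho)


def funnel_correlation(
    annotations: Sequence[BindingAnnotation],
    predictions: PredictionSet,
    funnel_radius: float = 12.0,
) -> FunnelResult:
    """Pearson ρ between min distance and score near the interface.

    Only residues with ``min_dist ≤ funnel_radius`` enter; the raw signed
    ρ is returned (a funnel-shaped predictor gives ρ < 0 — scores decay
    with distance from the nucleic acid).  Undefined (``rho=None``) with
    fewer than 3 qualifying residues or a constant series.
    """
    pairs = [
        (a.min_dist, predictions.scores[a.residue_key])
        for a in annotations
        if a.min_dist <= funnel_radius and a.residue_key in predictions.scores
    ]
    n = len(pairs)
    if n < 3:
        return FunnelResult(predictions.protein_id, None, n)
    d = np.array([p[0] for p in pairs])
    s = np.array([p[1] for p in pairs])
    if np.ptp(d) == 0 or np.ptp(s) == 0:
        return FunnelResult(predictions.protein_id, None, n)
    rho = float(np.corrcoef(d, s)[0, 1])
    return FunnelResult(predictions.protein_id, rho, n)


# ----------------------------------------------------- RNA/DNA discrimination

def discrimination_auc(
    positive_scores: Sequence[float], negative_scores: Sequence[float]
) -> float:
    """AUC separating binding residues of one nucleic-acid type from the other.

    Positives are binding residues (3.5 Å cutoff in their own complexes)
    from the predictor's own target type, negatives the binding residues
    of the other type; both sides are pooled into one ROC.
    """
    if len(positive_scores) == 0 or len(negative_scores) == 0:
        raise ValueError("both positive and negative sides must be non-empty")
    scores = list(positive_scores) + list(negative_scores)
    labels = [1] * len(positive_scores) + [0] * len(negative_scores)
    auc = roc_auc(scores, labels)
    assert auc is not None  # both classes present by construction
    return auc
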