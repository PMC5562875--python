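"""Identity-stratified cross-validation and classification metrics.

Evaluation must respect sequence redundancy: two homologous proteins in
train and test would leak label information through conserved sequence.
Proteins are therefore clustered by single linkage over a pairwise
global-alignment graph (edge when identity > 25% at >= 90% coverage) and
cross-validation holds out one whole cluster per fold, mirroring the
BLASTCLUST-style stratification commonly used for small protein sets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from sklearn.metrics import roc_auc_score

from . import model as _model
from .features import ResidueProfiles, featurize_dataset
from .seqdata import Dataset

DEFAULT_SI_CUTOFF = 0.25
DEFAULT_COVERAGE_CUTOFF = 0.90

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "ClusterAssignment",
    "pairwise_identity",
    "cluster_sequences",
    "confusion",
    "metrics",
    "roc_auc",
    "best_threshold",
    "top_fraction_ppv",
    "crossvalidate",
    "CrossValResult",
]


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(a: str, b: str) -> tuple[float, float]:
    """Global-alignment sequence identity and coverage for two sequences.

    Alignment uses BLOSUM62 with gap open −11 / extend −1. Identity is the
    fraction of identical columns over the alignment length after trimming
    terminal gaps; coverage is the fraction of the longer sequence inside
    that trimmed region.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    a, b = a.upper(), b.upper()
    aln = _ALIGNER.align(a, b)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    cols = len(row_a)
    # trim columns belonging to a terminal gap in either row
    start = max(_lead_gap(row_a), _lead_gap(row_b))
    end = cols - max(_lead_gap(row_a[::-1]), _lead_gap(row_b[::-1]))
    if end <= start:
        return 0.0, 0.0
    seg_a, seg_b = row_a[start:end], row_b[start:end]
    matches = sum(x == y and x != "-" for x, y in zip(seg_a, seg_b))
    identity = matches / (end - start)
    longer_len = max(len(a), len(b))
    longer_seg = seg_a if len(a) >= len(b) else seg_b
    coverage = (len(longer_seg) - longer_seg.count("-")) / longer_len
    return identity, coverage


def _lead_gap(row: str) -> int:
    n = 0
    for ch in row:
        if ch != "-":
            break
        n += 1
    return n


@dataclass(frozen=True)
class ClusterAssignment:
    """Partition of a dataset's proteins into redundancy clusters."""

    assignment: Mapping[str, int]

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))

    def members(self, cluster: int) -> list[str]:
        return [p for p, c in self.assignment.items() if c == cluster]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"protein_id": list(self.assignment), "cluster": list(self.assignment.values())}
        )


def cluster_sequences(
    dataset: Dataset,
    si_cutoff: float = DEFAULT_SI_CUTOFF,
    cov_cutoff: float = DEFAULT_COVERAGE_CUTOFF,
) -> ClusterAssignment:
    """Single-linkage redundancy clusters at the identity/coverage cutoffs.

    An edge joins two proteins when identity > ``si_cutoff`` AND coverage
    >= ``cov_cutoff``; clusters are the connected components, indexed by
    order of their first member in the dataset.
    """
    if len(dataset) < 1:
        raise ValueError("dataset is empty")
    g = nx.Graph()
    ids = dataset.ids
    g.add_nodes_from(ids)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            ident, cov = pairwise_identity(
                dataset[i].sequence, dataset[j].sequence
            )
            if ident > si_cutoff and cov >= cov_cutoff:
                g.add_edge(ids[i], ids[j])
    order = {pid: k for k, pid in enumerate(ids)}
    components = sorted(
        (sorted(c, key=order.get) for c in nx.connected_components(g)),
        key=lambda c: order[c[0]],
    )
    assignment = {pid: k for k, comp in enumerate(components) for pid in comp}
    return ClusterAssignment({pid: assignment[pid] for pid in ids})


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(calls: Sequence[int], labels: Sequence[int]) -> ConfusionCounts:
    calls = np.asarray(calls, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if calls.shape != labels.shape:
        raise ValueError(
            f"{calls.size} calls vs {labels.size} labels: length mismatch"
        )
    return ConfusionCounts(
        tp=int(((calls == 1) & (labels == 1)).sum()),
        fp=int(((calls == 1) & (labels == 0)).sum()),
        tn=int(((calls == 0) & (labels == 0)).sum()),
        fn=int(((calls == 0) & (labels == 1)).sum()),
    )


def _ratio(num: float, den: float) -> float:
    """Zero-denominator convention: undefined ratios are 0 (with warning)."""
    if den == 0:
        warnings.warn("zero denominator in metric; returning 0", stacklevel=3)
        return 0.0
    return num / den


def metrics(c: ConfusionCounts) -> dict[str, float]:
    """Sensitivity, specificity, accuracy, balanced accuracy, precision, MCC.

    Any metric with a zero denominator is 0 by convention, keeping fold
    averages computable.
    """
    if c.n == 0:
        raise ValueError("no evaluated residues")
    sen = _ratio(c.tp, c.tp + c.fn)
    spe = _ratio(c.tn, c.tn + c.fp)
    acc = (c.tp + c.tn) / c.n
    pre = _ratio(c.tp, c.tp + c.fp)
    mcc_den = math.sqrt(
        float(c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc = _ratio(c.tp * c.tn - c.fp * c.fn, mcc_den)
    return {
        "sen": sen,
        "spe": spe,
        "acc": acc,
        "bac": (sen + spe) / 2.0,
        "pre": pre,
        "mcc": mcc,
    }


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-statistic AUC (ties count half); errors on single-class input."""
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("AUC needs both classes")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def best_threshold(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Threshold maximizing Youden's J = sen + spe − 1 over ROC vertices.

    Candidate thresholds are the observed scores (call rule: score >= tau)
    plus one value above the maximum (the all-negative vertex); ties in J
    break toward the larger threshold.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and labels must align")
    if len(set(y.tolist())) < 2:
        raise ValueError("threshold fitting needs both classes")
    uniq = np.unique(s)[::-1]
    above = np.nextafter(uniq[0], np.inf)
    candidates = np.concatenate([[above], uniq])
    n_pos = (y == 1).sum()
    n_neg = (y == 0).sum()
    best_tau, best_j = candidates[0], -np.inf
    for tau in candidates:  # descending, so first max = largest threshold
        calls = s >= tau
        j = (calls & (y == 1)).sum() / n_pos + (~calls & (y == 0)).sum() / n_neg - 1
        if j > best_j:
            best_j, best_tau = j, tau
    return float(best_tau)


def top_fraction_ppv(
    scores: Sequence[float], labels: Sequence[int], fraction: float
) -> float:
    """Precision among the ``ceil(fraction*n)`` highest-scoring residues.

    Ties at the selection boundary are resolved inclusively: every residue
    scoring at least the boundary value is selected.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction {fraction} outside (0, 1]")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.size < 1 or s.shape != y.shape:
        raise ValueError("need aligned, non-empty scores and labels")
    k = math.ceil(fraction * s.size)
    boundary = np.sort(s)[::-1][k - 1]
    selected = s >= boundary
    return float(y[selected].mean())


_METRIC_FIELDS = (
    "sen", "spe", "acc", "bac", "pre", "mcc", "auc", "ppv_top10", "ppv_top5",
)


@dataclass(frozen=True)
class MetricsReport:
    """All performance measures for one evaluation (one fold, or averaged)."""

    sen: float
    spe: float
    acc: float
    bac: float
    pre: float
    mcc: float
    auc: float
    ppv_top10: float
    ppv_top5: float
    threshold: float
    n: int = 0

    def as_dict(self) -> dict[str, float]:
        return {f: getattr(self, f) for f in _METRIC_FIELDS} | {
            "threshold": self.threshold,
            "n": self.n,
        }


def score_predictions(
    probabilities: Sequence[float],
    labels: Sequence[int],
    threshold: float,
) -> MetricsReport:
    """Full metrics report for one set of calibrated predictions."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    rep = metrics(confusion(_model.classify(p, threshold), y))
    single_class = len(set(y.tolist())) < 2
    if single_class:
        warnings.warn(
            "evaluation set has a single class; class-dependent metrics are "
            "undefined (reported as NaN)",
            stacklevel=2,
        )
    auc = np.nan if single_class else roc_auc(p, y)
    if single_class:
        for k in ("sen", "spe", "bac", "pre", "mcc"):
            rep[k] = np.nan
    return MetricsReport(
        **rep,
        auc=auc,
        ppv_top10=top_fraction_ppv(p, y, 0.10),
        ppv_top5=top_fraction_ppv(p, y, 0.05),
        threshold=threshold,
        n=int(y.size),
    )


@dataclass(frozen=True)
class CrossValResult:
    folds: tuple[MetricsReport, ...]
    average: MetricsReport
    clusters: ClusterAssignment
    pooled: MetricsReport | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"fold": k} | rep.as_dict() for k, rep in enumerate(self.folds)
        ]
        rows.append({"fold": "average"} | self.average.as_dict())
        return pd.DataFrame(rows)


def _average_reports(folds: Sequence[MetricsReport]) -> MetricsReport:
    vals = {}
    for f in _METRIC_FIELDS + ("threshold",):
        col = np.array([getattr(r, f) for r in folds], dtype=float)
        if np.isnan(col).any():
            warnings.warn(
                f"metric {f!r} undefined in {int(np.isnan(col).sum())} "
                "fold(s); excluded from the average",
                stacklevel=3,
            )
        vals[f] = float(np.nanmean(col))
    return MetricsReport(**vals, n=int(sum(r.n for r in folds)))


def crossvalidate(
    dataset: Dataset,
    profiles: Mapping[str, ResidueProfiles],
    C: float = _model.DEFAULT_C,
    gamma: float = _model.DEFAULT_GAMMA,
    class_weight="balanced",
    si_cutoff: float = DEFAULT_SI_CUTOFF,
    cov_cutoff: float = DEFAULT_COVERAGE_CUTOFF,
    calibration_cv: int = 3,
    threshold: float | None = None,
    pooled: bool = False,
    random_state: int = 0,
    clusters: ClusterAssignment | None = None,
) -> CrossValResult:
    """Leave-one-cluster-out cross-validation of the full pipeline.

    Each redundancy cluster is held out in turn; the classifier, the Platt
    calibration (fitted on internal cross-validated decision scores of the
    training portion) and the decision threshold (Youden's J on those same
    training-side probabilities, unless a fixed ``threshold`` is given) are
    all determined without the held-out cluster. Fold metrics are averaged
    unweighted; ``pooled=True`` additionally scores all held-out
    predictions pooled into one set.
    """
    if not dataset.is_labelled:
        raise ValueError("cross-validation requires labels")
    if clusters is None:
        clusters = cluster_sequences(dataset, si_cutoff, cov_cutoff)
    if clusters.n_clusters < 2:
        raise ValueError("need at least two clusters to cross-validate")

    per_protein = {
        rec.id: featurize_dataset(
            Dataset((rec,)), profiles={rec.id: profiles[rec.id]}
        )
        for rec in dataset
    }

    folds = []
    pooled_p, pooled_y, pooled_tau = [], [], []
    for k in range(clusters.n_clusters):
        held = set(clusters.members(k))
        X_tr = np.vstack([per_protein[p][0] for p in dataset.ids if p not in held])
        y_tr = np.concatenate([per_protein[p][1] for p in dataset.ids if p not in held])
        X_te = np.vstack([per_protein[p][0] for p in dataset.ids if p in held])
        y_te = np.concatenate([per_protein[p][1] for p in dataset.ids if p in held])
        fitted = _model.train(X_tr, y_tr, C=C, gamma=gamma, class_weight=class_weight)
        fitted, train_probs = _model.calibrate(
            fitted, X_tr, y_tr, cv=calibration_cv, random_state=random_state
        )
        tau = (
            float(np.clip(best_threshold(train_probs, y_tr), 0.0, 1.0))
            if threshold is None
            else threshold
        )
        p_te = _model.predict_proba(fitted, X_te)
        folds.append(score_predictions(p_te, y_te, tau))
        pooled_p.append(p_te)
        pooled_y.append(y_te)
        pooled_tau.append(tau)

    result_pooled = None
    if pooled:
        result_pooled = score_predictions(
            np.concatenate(pooled_p),
            np.concatenate(pooled_y),
            float(np.mean(pooled_tau)),
        )
    return CrossValResult(
        folds=tuple(folds),
        average=_average_reports(folds),
        clusters=clusters,
        pooled=result_pooled,
    )
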