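"""Evaluation of the reliability scoring scheme.

ROC analysis treats gold-standard membership as the positive label and the
reliability score as the ranking statistic; the same gold standard also
calibrates the confidence scores, exactly as in database-scale practice, so
an optional held-out split of the gold standard is provided (default off)
for a circularity-free variant.  Accuracy is swept over score cutoffs on
predicted DDIs only.  Dataset similarity structure is summarized by
average-linkage hierarchical clustering of the weighted-overlap matrix
(distance 1 - Wo), serializable to Newick.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage, to_tree
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .datasets import DomainPair
from .integration import GoldStandard, IntegratedDDI
from .scoring import DatasetConfidence, WoMatrix


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------


@dataclass
class RocResult:
    points: list[tuple[float, float]]  # (false-positive rate, true-positive rate)
    auc: float
    n_pos: int
    n_neg: int


def roc_curve(
    scored: Sequence[tuple[Hashable, float]], positives: set
) -> RocResult:
    """ROC curve of a score against gold-standard membership.

    Thresholds sweep the distinct scores descending; tied scores move as a
    single block; AUC by the trapezoid rule.  Requires at least one positive
    and one negative item.
    """
    if not scored:
        raise EvaluationError("no scored items")
    y_true = np.array([item in positives for item, _ in scored], dtype=bool)
    y_score = np.array([s for _, s in scored], dtype=float)
    n_pos = int(y_true.sum())
    n_neg = int(len(y_true) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError(
            f"ROC needs both classes (got {n_pos} positives, {n_neg} negatives)"
        )
    fpr, tpr, _ = _sk_roc_curve(y_true, y_score, drop_intermediate=False)
    return RocResult(
        points=list(zip(fpr.tolist(), tpr.tolist())),
        auc=float(_trapezoid_auc(fpr, tpr)),
        n_pos=n_pos,
        n_neg=n_neg,
    )


# ---------------------------------------------------------------------------
# Accuracy sweep
# ---------------------------------------------------------------------------


@dataclass
class AccuracySweep:
    rows: list[tuple[float, int, int, int, int, float]]  # cutoff, tp, fp, tn, fn, acc
    best: tuple[float, float]  # (cutoff, accuracy)


def accuracy_sweep(
    scored: Sequence[tuple[Hashable, float]],
    positives: set,
    cutoffs: Sequence[float] | None = None,
) -> AccuracySweep:
    """Accuracy of 'reliability >= cutoff' classification over a cutoff grid.

    Defaults to all distinct scores as cutoffs.  The best row maximizes
    accuracy; ties resolve to the smallest cutoff.
    """
    if not scored:
        raise EvaluationError("no scored items")
    y_true = np.array([item in positives for item, _ in scored], dtype=bool)
    y_score = np.array([s for _, s in scored], dtype=float)
    grid = sorted(set(y_score.tolist())) if cutoffs is None else sorted(set(cutoffs))
    rows = []
    best = None
    n = len(y_true)
    for c in grid:
        pred = y_score >= c
        tp = int((pred & y_true).sum())
        fp = int((pred & ~y_true).sum())
        fn = int((~pred & y_true).sum())
        tn = n - tp - fp - fn
        acc = (tp + tn) / n
        rows.append((c, tp, fp, tn, fn, acc))
        if best is None or acc > best[1]:
            best = (c, acc)
    return AccuracySweep(rows=rows, best=best)


# ---------------------------------------------------------------------------
# Scoring-scheme comparison helpers
# ---------------------------------------------------------------------------


def reliability_scores(rows: Sequence[IntegratedDDI]) -> list[tuple[DomainPair, float]]:
    """(DDI, reliability) for every DDI with predicted support."""
    return [(r.ddi, r.reliability) for r in rows if r.n_predicted > 0]


def confidence_only_scores(
    rows: Sequence[IntegratedDDI], conf: DatasetConfidence
) -> list[tuple[DomainPair, float]]:
    """Baseline score ignoring P and ID: the plain sum of supporter confidences.

    This is the scheme that scores a DDI only by which datasets contain it,
    making DDIs within one dataset indistinguishable.
    """
    return [
        (r.ddi, sum(conf[name] for name, _, _ in r.supporters))
        for r in rows
        if r.n_predicted > 0
    ]


def split_gold_standard(
    gsp: GoldStandard, holdout_fraction: float, seed: int
) -> tuple[set[DomainPair], set[DomainPair]]:
    """Optional held-out split of the gold standard (calibration, evaluation).

    Not part of the published procedure (which calibrates and labels with
    the same gold standard); offered for circularity-free evaluation.
    """
    if not 0.0 < holdout_fraction < 1.0:
        raise EvaluationError("holdout_fraction must be in (0, 1)")
    pairs = sorted(gsp.ddis)
    rng = np.random.default_rng(seed)
    rng.shuffle(pairs)
    n_hold = int(round(holdout_fraction * len(pairs)))
    return set(pairs[n_hold:]), set(pairs[:n_hold])


# ---------------------------------------------------------------------------
# Hierarchical clustering of the Wo matrix
# ---------------------------------------------------------------------------


@dataclass
class Dendrogram:
    """Average-linkage dendrogram over datasets, on distance 1 - Wo."""

    labels: list[str]
    linkage_matrix: np.ndarray  # scipy linkage format

    def merges(self) -> list[tuple[frozenset, frozenset, float]]:
        """Merge events as (members of left, members of right, height)."""
        clusters: dict[int, frozenset] = {
            i: frozenset([lab]) for i, lab in enumerate(self.labels)
        }
        out = []
        n = len(self.labels)
        for k, (i, j, height, _) in enumerate(self.linkage_matrix):
            left, right = clusters[int(i)], clusters[int(j)]
            out.append((left, right, float(height)))
            clusters[n + k] = left | right
        return out

    def to_newick(self) -> str:
        """Newick string with branch lengths (parent height - child height)."""
        tree = to_tree(self.linkage_matrix)

        def render(node, parent_height: float) -> str:
            if node.is_leaf():
                return f"{self.labels[node.id]}:{parent_height:.6f}"
            inner = ",".join(
                render(c, node.dist) for c in (node.left, node.right)
            )
            return f"({inner}):{parent_height - node.dist:.6f}"

        inner = ",".join(render(c, tree.dist) for c in (tree.left, tree.right))
        return f"({inner});"


def cluster_wo(wo: WoMatrix) -> Dendrogram:
    """Agglomerative average-linkage clustering of datasets on 1 - Wo.

    Dataset labels are processed in lexicographic order so equal-distance
    merges resolve deterministically.
    """
    labels = sorted(wo.names)
    if len(labels) < 2:
        raise EvaluationError("clustering needs at least 2 datasets")
    condensed = []
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            condensed.append(1.0 - wo.get(a, b))
    z = linkage(np.asarray(condensed, dtype=float), method="average")
    return Dendrogram(labels=labels, linkage_matrix=z)


# ---------------------------------------------------------------------------
# TSV export
# ---------------------------------------------------------------------------


def write_roc_tsv(roc: RocResult, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# auc={roc.auc:.6f}\tn_pos={roc.n_pos}\tn_neg={roc.n_neg}\n")
        fh.write("fpr\ttpr\n")
        for fpr, tpr in roc.points:
            fh.write(f"{fpr:.6f}\t{tpr:.6f}\n")


def write_sweep_tsv(sweep: AccuracySweep, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# best_cutoff={sweep.best[0]:.6f}\tbest_accuracy={sweep.best[1]:.6f}\n")
        fh.write("cutoff\ttp\tfp\ttn\tfn\taccuracy\n")
        for c, tp, fp, tn, fn, acc in sweep.rows:
            fh.write(f"{c:.6f}\t{tp}\t{fp}\t{tn}\t{fn}\t{acc:.6f}\n")
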