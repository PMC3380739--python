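"""Reliability scoring of integrated DDI evidence.

Four quantities combine heterogeneous evidence sources into a single
per-DDI reliability score:

* **Weighted overlap** ``Wo(a, b)`` — similarity between two DDI datasets:
  twice the number of shared DDIs over the numbers of DDIs in each dataset
  whose domains both occur in the other dataset's domain universe.
  Restricting to comparable DDIs prevents penalizing a dataset for domains
  the other never covers.
* **Confidence** ``C_d`` — a predicted dataset's weighted overlap against
  the structural gold-standard positive (GSP) set; a proxy for the
  accuracy of the prediction method.
* **Independence** ``ID_{d,i} = 1 / (1 + sum_e Wo(d, e))`` over the other
  datasets ``e`` that also contain DDI ``i`` — damps redundant evidence from
  methodologically similar sources (two near-identical datasets together
  contribute no more than one of them alone).
* **Prediction score** ``P_{d,i}`` — the dataset's own raw score for the
  DDI, ordinally rescaled to [0, 1] (rank-based min-max with mean-rank
  ties); score-less datasets receive an imputed average (see
  :func:`impute_scoreless`).

The reliability of a predicted DDI is ``R_i = sum_d C_d * ID_{d,i} * P_{d,i}``
over its supporting predicted datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from statistics import fmean
from typing import Iterable, Sequence

from scipy.stats import rankdata

from .datasets import HIGHER, DDIDataset, DomainPair


class ScoringError(ValueError):
    """A scoring precondition is violated (empty GSP, missing confidence, ...)."""


# ---------------------------------------------------------------------------
# Weighted overlap and confidence
# ---------------------------------------------------------------------------


def restricted_subset(a: DDIDataset, b: DDIDataset) -> set[DomainPair]:
    """DDIs of ``a`` whose both domains occur in ``b``'s domain universe.

    (Membership in ``a``'s own universe is automatic.)
    """
    shared = a.domain_universe & b.domain_universe
    return {p for p in a.ddis if p.a in shared and p.b in shared}


def weighted_overlap(a: DDIDataset, b: DDIDataset) -> float:
    """Weighted overlap Wo = 2*|Ia ∩ Ib| / (|Ia→b| + |Ib→a|), in [0, 1].

    Returns 0 when no DDI of either dataset is comparable (zero
    denominator): no comparable DDIs is evidence of no similarity.
    Symmetric by construction.
    """
    denom = len(restricted_subset(a, b)) + len(restricted_subset(b, a))
    if denom == 0:
        return 0.0
    return 2.0 * len(a.ddis & b.ddis) / denom


@dataclass
class WoMatrix:
    """Symmetric dataset-by-dataset weighted-overlap matrix."""

    names: list[str]
    scores: dict[tuple[str, str], float] = field(default_factory=dict)

    def get(self, a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        return self.scores[key]

    def to_tsv(self, path: str | Path) -> None:
        """Export with dataset-name headers, 4-decimal fixed formatting."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("dataset\t" + "\t".join(self.names) + "\n")
            for a in self.names:
                fh.write(a + "\t" + "\t".join(f"{self.get(a, b):.4f}" for b in self.names) + "\n")


def wo_matrix(datasets: Sequence[DDIDataset]) -> WoMatrix:
    """All-pairs weighted overlap; diagonal is 1 for non-empty datasets."""
    names = [d.name for d in datasets]
    if len(set(names)) != len(names):
        raise ScoringError("duplicate dataset names in Wo matrix")
    m = WoMatrix(names=names)
    for i, a in enumerate(datasets):
        for b in datasets[i:]:
            key = (a.name, b.name) if a.name <= b.name else (b.name, a.name)
            m.scores[key] = weighted_overlap(a, b)
    return m


def gsp_as_dataset(gsp: Iterable[DomainPair], name: str = "GSP") -> DDIDataset:
    """Wrap a gold-standard DDI set as a dataset for Wo computation."""
    ddis = set(gsp)
    if not ddis:
        raise ScoringError("empty gold-standard positive set")
    return DDIDataset(name=name, kind="structural", ddis=ddis)


def confidence_score(d: DDIDataset, gsp: Iterable[DomainPair]) -> float:
    """Confidence C_d = Wo(d, GSP); errors on an empty GSP."""
    return weighted_overlap(d, gsp_as_dataset(gsp))


@dataclass
class DatasetConfidence:
    """Per-dataset confidence scores C_d, each in [0, 1]."""

    values: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("dataset\tconfidence\n")
            for name in self.values:
                fh.write(f"{name}\t{self.values[name]:.4f}\n")


def confidence_table(
    predicted: Sequence[DDIDataset], gsp: Iterable[DomainPair]
) -> DatasetConfidence:
    g = gsp_as_dataset(gsp)
    return DatasetConfidence(values={d.name: weighted_overlap(d, g) for d in predicted})


# ---------------------------------------------------------------------------
# Independence
# ---------------------------------------------------------------------------


def independence_score(d: str, supporters: set[str], wo: WoMatrix) -> float:
    """ID_{d,i} = 1 / (1 + sum of Wo(d, e) over the other supporters e).

    A DDI unique to one dataset receives an independence score of one.
    """
    if d not in supporters:
        raise ScoringError(f"dataset {d!r} is not among the supporters of this DDI")
    return 1.0 / (1.0 + sum(wo.get(d, e) for e in supporters if e != d))


# ---------------------------------------------------------------------------
# Prediction-score scaling and imputation
# ---------------------------------------------------------------------------


def scale_prediction_scores(ds: DDIDataset) -> dict[DomainPair, float]:
    """Ordinal (rank-based min-max) scaling of raw scores to [0, 1].

    Scores are oriented so higher = more confident, ranked with mean-rank
    ties, then mapped through (rank - 1) / (n - 1).  A dataset with a single
    scored DDI maps it to 1.0 (its best DDI).  The result depends only on
    the rank order of the oriented raw scores.
    """
    if not ds.raw_scores:
        raise ScoringError(f"dataset {ds.name!r} has no raw scores to scale")
    pairs = sorted(ds.raw_scores)
    sign = 1.0 if ds.score_direction == HIGHER else -1.0
    oriented = [sign * ds.raw_scores[p] for p in pairs]
    n = len(pairs)
    if n == 1:
        return {pairs[0]: 1.0}
    ranks = rankdata(oriented, method="average")
    return {p: float(r - 1.0) / (n - 1.0) for p, r in zip(pairs, ranks)}


@dataclass
class EvidenceRecord:
    """One (dataset, DDI) evidence assignment with its P and ID factors."""

    dataset: str
    ddi: DomainPair
    scaled_score: float | None = None  # P_{d,i}; None until scaled/imputed
    independence: float | None = None  # ID_{d,i}
    imputed: bool = False


def impute_scoreless(
    evidence: Sequence[EvidenceRecord], scoreless_datasets: set[str]
) -> None:
    """Impute P for evidence from score-less datasets, in place.

    A score-less record for DDI ``i`` receives the mean scaled score of all
    *scored* evidence whose DDI is supported by the same total number of
    datasets as ``i`` (counting scored and score-less alike).  When that bin
    holds no scored evidence, the global mean of all scaled scores is used
    and the record is still flagged imputed.
    """
    n_supporters: dict[DomainPair, int] = {}
    for rec in evidence:
        n_supporters[rec.ddi] = n_supporters.get(rec.ddi, 0) + 1

    bins: dict[int, list[float]] = {}
    all_scored: list[float] = []
    for rec in evidence:
        if rec.dataset not in scoreless_datasets:
            if rec.scaled_score is None:
                raise ScoringError(
                    f"scored record {rec.dataset!r}/{rec.ddi} lacks a scaled score"
                )
            bins.setdefault(n_supporters[rec.ddi], []).append(rec.scaled_score)
            all_scored.append(rec.scaled_score)
    if not all_scored:
        raise ScoringError("no scored evidence exists; imputation impossible")
    global_mean = fmean(all_scored)

    for rec in evidence:
        if rec.dataset in scoreless_datasets:
            k = n_supporters[rec.ddi]
            rec.scaled_score = fmean(bins[k]) if bins.get(k) else global_mean
            rec.imputed = True


# ---------------------------------------------------------------------------
# Reliability
# ---------------------------------------------------------------------------


def reliability_score(
    evidence_for_i: Sequence[EvidenceRecord], conf: DatasetConfidence
) -> float:
    """R_i = sum over supporting datasets of C_d * ID_{d,i} * P_{d,i}."""
    if not evidence_for_i:
        raise ScoringError("reliability of a DDI with no evidence is undefined")
    total = 0.0
    for rec in evidence_for_i:
        if rec.dataset not in conf.values:
            raise ScoringError(f"no confidence score for dataset {rec.dataset!r}")
        if rec.scaled_score is None or rec.independence is None:
            raise ScoringError(
                f"evidence {rec.dataset!r}/{rec.ddi} is missing P or ID"
            )
        total += conf[rec.dataset] * rec.independence * rec.scaled_score
    return total
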