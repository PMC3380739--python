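"""Assembly of the integrated DDI table.

The gold-standard positive (GSP) set is the union of the structural
datasets.  Every DDI supported by at least one predicted dataset receives
a reliability score ``R_i = sum_d C_d * ID_{d,i} * P_{d,i}``; DDIs present
only in the gold standard are emitted with reliability 0 and a structural
flag (the scoring scheme scores predicted evidence only — downstream
consumers treat the flag as verified truth).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .datasets import PREDICTED, STRUCTURAL, DDIDataset, DomainPair, ValidationError, canonical_pair
from .scoring import (
    DatasetConfidence,
    EvidenceRecord,
    ScoringError,
    WoMatrix,
    confidence_table,
    impute_scoreless,
    independence_score,
    reliability_score,
    scale_prediction_scores,
    wo_matrix,
)


@dataclass
class GoldStandard:
    """Union of structural DDIs with per-DDI source provenance."""

    ddis: set[DomainPair] = field(default_factory=set)
    sources: dict[DomainPair, set[str]] = field(default_factory=dict)

    def __contains__(self, pair: DomainPair) -> bool:
        return pair in self.ddis

    def __len__(self) -> int:
        return len(self.ddis)


def build_gsp(structural: Sequence[DDIDataset]) -> GoldStandard:
    """Union the structural datasets into the gold-standard positive set."""
    if not structural:
        raise ScoringError("at least one structural dataset is required to build the GSP")
    gsp = GoldStandard()
    for ds in structural:
        if ds.kind != STRUCTURAL:
            raise ScoringError(f"dataset {ds.name!r} is not structural")
        for pair in ds.ddis:
            gsp.ddis.add(pair)
            gsp.sources.setdefault(pair, set()).add(ds.name)
    return gsp


@dataclass
class IntegratedDDI:
    """One row of the integrated table.

    ``supporters`` lists (dataset name, scaled P, ID) for every predicted
    dataset containing the DDI; ``structural`` flags gold-standard
    membership independently of the predicted evidence.
    """

    ddi: DomainPair
    structural: bool
    supporters: list[tuple[str, float, float]] = field(default_factory=list)
    reliability: float = 0.0

    @property
    def n_predicted(self) -> int:
        return len(self.supporters)


@dataclass
class IntegrationResult:
    """Integrated table plus the intermediates evaluation needs."""

    rows: list[IntegratedDDI]
    gsp: GoldStandard
    confidence: DatasetConfidence
    wo: WoMatrix

    def __iter__(self):
        return iter(self.rows)


def integrate(
    predicted: Sequence[DDIDataset], gsp: GoldStandard
) -> IntegrationResult:
    """Run the full scoring pipeline over canonicalized predicted datasets.

    Steps: predicted-by-predicted Wo matrix; per-dataset confidence against
    the GSP; ordinal scaling of raw scores (average-score imputation for
    score-less datasets); per-(dataset, DDI) independence; reliability sum
    per DDI.  GSP-only DDIs get structural rows with no supporters.
    """
    for ds in predicted:
        if ds.kind != PREDICTED:
            raise ScoringError(f"dataset {ds.name!r} is not a predicted dataset")
    wo = wo_matrix(list(predicted))
    conf = confidence_table(predicted, gsp.ddis)

    supporters: dict[DomainPair, set[str]] = {}
    for ds in predicted:
        for pair in ds.ddis:
            supporters.setdefault(pair, set()).add(ds.name)

    scoreless = {ds.name for ds in predicted if not ds.raw_scores}
    evidence: list[EvidenceRecord] = []
    for ds in predicted:
        scaled = scale_prediction_scores(ds) if ds.raw_scores else {}
        for pair in ds.ddis:
            evidence.append(
                EvidenceRecord(
                    dataset=ds.name,
                    ddi=pair,
                    scaled_score=scaled.get(pair),
                    independence=independence_score(ds.name, supporters[pair], wo),
                )
            )
    if scoreless:
        impute_scoreless(evidence, scoreless)

    by_ddi: dict[DomainPair, list[EvidenceRecord]] = {}
    for rec in evidence:
        by_ddi.setdefault(rec.ddi, []).append(rec)

    rows: list[IntegratedDDI] = []
    for pair, recs in by_ddi.items():
        recs.sort(key=lambda r: r.dataset)
        rows.append(
            IntegratedDDI(
                ddi=pair,
                structural=pair in gsp,
                supporters=[(r.dataset, r.scaled_score, r.independence) for r in recs],
                reliability=reliability_score(recs, conf),
            )
        )
    for pair in gsp.ddis - set(by_ddi):
        rows.append(IntegratedDDI(ddi=pair, structural=True))

    rows.sort(key=lambda r: (-r.reliability, r.ddi))
    return IntegrationResult(rows=rows, gsp=gsp, confidence=conf, wo=wo)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_HEADER = "domain_a\tdomain_b\tstructural\tn_predicted\tsupporters\treliability"


def write_integrated_table(rows: Sequence[IntegratedDDI], path: str | Path) -> None:
    """Write the integrated table as TSV.

    Supporters serialize as a semicolon list of ``name:P:ID`` (full float
    precision); reliability is fixed at 6 decimals; rows are sorted by
    reliability descending, then pair lexicographic, for byte-deterministic
    output.
    """
    ordered = sorted(rows, key=lambda r: (-r.reliability, r.ddi))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_HEADER + "\n")
        for r in ordered:
            supp = ";".join(f"{name}:{float(p)!r}:{float(i)!r}" for name, p, i in r.supporters)
            fh.write(
                f"{r.ddi.a}\t{r.ddi.b}\t{int(r.structural)}\t{r.n_predicted}\t"
                f"{supp}\t{r.reliability:.6f}\n"
            )


def read_integrated_table(path: str | Path) -> list[IntegratedDDI]:
    """Read a table written by :func:`write_integrated_table`."""
    rows: list[IntegratedDDI] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if header != _HEADER:
            raise ValidationError(f"{path}:1: unexpected header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ValidationError(f"{path}:{lineno}: expected 6 columns, got {len(fields)}")
            try:
                pair = canonical_pair(fields[0], fields[1])
                structural = bool(int(fields[2]))
                n_pred = int(fields[3])
                supporters = []
                if fields[4]:
                    for item in fields[4].split(";"):
                        name, p, ind = item.rsplit(":", 2)
                        supporters.append((name, float(p), float(ind)))
                reliability = float(fields[5])
            except (ValueError, ValidationError) as e:
                raise ValidationError(f"{path}:{lineno}: {e}") from None
            if n_pred != len(supporters):
                raise ValidationError(
                    f"{path}:{lineno}: n_predicted={n_pred} but {len(supporters)} supporters"
                )
            rows.append(
                IntegratedDDI(
                    ddi=pair, structural=structural, supporters=supporters,
                    reliability=reliability,
                )
            )
    return rows
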