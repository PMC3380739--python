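"""Bridging domain-level and protein-level interaction data.

A PPI is *covered* when at least one DDI connects a domain of one partner
to a domain of the other (either orientation; a self-PPI is covered by any
DDI between two domains of that protein).  Coverage by default uses every
integrated DDI — structural rows included, no reliability threshold —
because coverage compares whole databases, not score-thresholded subsets.
Proteins absent from the domain-composition map simply count as uncovered.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .datasets import DomainPair, PPISet, ProteinDomainMap, canonical_pair
from .integration import IntegratedDDI


class CoverageError(ValueError):
    pass


@dataclass
class CoverageReport:
    """Counts of PPIs with/without at least one supporting DDI."""

    covered: int
    uncovered: int

    @property
    def total(self) -> int:
        return self.covered + self.uncovered

    @property
    def rate_percent(self) -> float:
        """Coverage rate, percent (report to 1 decimal)."""
        return 100.0 * self.covered / self.total


def _index_rows(rows: Sequence[IntegratedDDI]) -> dict[DomainPair, IntegratedDDI]:
    return {r.ddi: r for r in rows}


def _passes(row: IntegratedDDI, min_reliability: float) -> bool:
    return row.structural or row.reliability >= min_reliability


def ddis_between(
    p1: str,
    p2: str,
    pdmap: ProteinDomainMap,
    rows: Sequence[IntegratedDDI],
    min_reliability: float = 0.0,
) -> list[IntegratedDDI]:
    """All integrated DDIs linking a domain of ``p1`` to a domain of ``p2``.

    Structural rows always pass; predicted-only rows must meet
    ``min_reliability``.  Unknown proteins yield an empty list.  Result is
    deduplicated and sorted by reliability descending (pair order breaks
    ties).
    """
    index = _index_rows(rows)
    d1, d2 = pdmap.domains(p1), pdmap.domains(p2)
    hits: dict[DomainPair, IntegratedDDI] = {}
    for a in d1:
        for b in d2:
            row = index.get(canonical_pair(a, b)) if a and b else None
            if row is not None and _passes(row, min_reliability):
                hits[row.ddi] = row
    return sorted(hits.values(), key=lambda r: (-r.reliability, r.ddi))


def ppi_coverage(
    ppis: PPISet,
    pdmap: ProteinDomainMap,
    rows: Sequence[IntegratedDDI],
    min_reliability: float = 0.0,
) -> CoverageReport:
    """Count PPIs with at least one connecting DDI passing the filter."""
    if not ppis.pairs:
        raise CoverageError("coverage rate is undefined for an empty PPI set")
    index = {r.ddi for r in rows if _passes(r, min_reliability)}
    covered = 0
    for pa, pb in ppis.pairs:
        d1, d2 = pdmap.domains(pa), pdmap.domains(pb)
        if any(canonical_pair(a, b) in index for a in d1 for b in d2):
            covered += 1
    return CoverageReport(covered=covered, uncovered=len(ppis.pairs) - covered)


def candidate_ppis(
    ddi: DomainPair, pdmap: ProteinDomainMap, ppis: PPISet
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Protein pairs that could realize a DDI, split into known and novel.

    Candidates are all protein pairs where one partner contains ``ddi.a``
    and the other ``ddi.b`` (either orientation); ``known`` are those
    present in the PPI set, ``novel`` the rest.  Both lists are sorted.
    """
    inv = pdmap.inverted()
    with_a = inv.get(ddi.a, set())
    with_b = inv.get(ddi.b, set())
    candidates = {
        (min(q1, q2), max(q1, q2)) for q1 in with_a for q2 in with_b
    }
    known = sorted(c for c in candidates if c in ppis.pairs)
    novel = sorted(c for c in candidates if c not in ppis.pairs)
    return known, novel


def query_domain(
    d: str, rows: Sequence[IntegratedDDI], pdmap: ProteinDomainMap
) -> tuple[list[tuple[str, float, bool]], list[str]]:
    """Interaction partners of a domain and the proteins containing it.

    Partners are (partner domain, reliability, structural flag), sorted by
    reliability descending; a self-DDI lists the domain itself once.
    """
    partners = [
        (r.ddi.other(d), r.reliability, r.structural)
        for r in rows
        if d in (r.ddi.a, r.ddi.b)
    ]
    partners.sort(key=lambda t: (-t[1], t[0]))
    return partners, sorted(pdmap.proteins_with(d))


def query_protein(
    p: str, pdmap: ProteinDomainMap, ppis: PPISet
) -> tuple[list[str], list[str]]:
    """A protein's domain composition and its known interaction partners."""
    partners = sorted(
        b if a == p else a for a, b in ppis.pairs if p in (a, b)
    )
    return sorted(pdmap.domains(p)), partners
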