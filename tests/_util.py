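"""Shared test helpers: dataset builders and independent brute-force oracles.

The oracles deliberately work on plain tuples/lists with naive enumeration,
staying independent of the library code paths they check.
"""

from __future__ import annotations

from iddi.datasets import DDIDataset, canonical_pair
from iddi.synthgen import CorpusSpec, DatasetSpec


def make_ds(name, pairs, kind="predicted", scores=None, direction="higher"):
    """Build a DDIDataset from (a, b) tuples and an optional parallel score list."""
    ddis = [canonical_pair(a, b) for a, b in pairs]
    raw = {}
    if scores is not None:
        raw = dict(zip(ddis, scores))
    return DDIDataset(
        name=name, kind=kind, ddis=set(ddis), raw_scores=raw, score_direction=direction
    )


def small_spec(seed=0, **overrides) -> CorpusSpec:
    """A miniature corpus spec for fast end-to-end tests."""
    defaults = dict(
        n_domains=60,
        n_gsp=150,
        n_structural_datasets=2,
        datasets=[
            DatasetSpec("good", 120, 0.6),
            DatasetSpec("mid", 120, 0.3, score_direction="lower"),
            DatasetSpec("noscore", 120, 0.2, scored=False),
            DatasetSpec("poor", 120, 0.1),
        ],
        n_proteins=60,
        domains_per_protein_range=(1, 3),
        n_ppis=80,
        ppi_ddi_coverage_target=0.5,
        seed=seed,
    )
    defaults.update(overrides)
    return CorpusSpec(**defaults)


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------


def wo_brute(pairs_a, pairs_b):
    """Naive weighted overlap on collections of canonical (a, b) tuples."""
    pa = {tuple(sorted(p)) for p in pairs_a}
    pb = {tuple(sorted(p)) for p in pairs_b}
    ua = {d for p in pa for d in p}
    ub = {d for p in pb for d in p}
    rest_a = [p for p in pa if p[0] in ub and p[1] in ub]
    rest_b = [p for p in pb if p[0] in ua and p[1] in ua]
    denom = len(rest_a) + len(rest_b)
    if denom == 0:
        return 0.0
    return 2.0 * len(pa & pb) / denom


def auc_brute(scores, labels):
    """Mann-Whitney AUC: fraction of pos-neg pairs correctly ordered (ties 1/2)."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def coverage_brute(ppi_pairs, domains_of, rows, min_reliability=0.0):
    """Double loop over PPIs x integrated rows; returns the covered count."""
    kept = [r for r in rows if r.structural or r.reliability >= min_reliability]
    covered = 0
    for pa, pb in ppi_pairs:
        hit = False
        for r in kept:
            da, db = r.ddi.a, r.ddi.b
            d1 = domains_of.get(pa, set())
            d2 = domains_of.get(pb, set())
            if (da in d1 and db in d2) or (da in d2 and db in d1):
                hit = True
                break
        covered += hit
    return covered
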