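"""Seeded generator of complete synthetic DDI/PPI corpora.

Emulates the world the integration pipeline is built for: a small set of
structural datasets whose union is the gold standard, predicted datasets of
varying accuracy (their ``tp_fraction`` controls how much of each is drawn
from the gold standard), optional near-duplicate dataset pairs (the
redundancy the independence score exists to damp), raw prediction scores
under which true positives stochastically outrank false ones, a proteome
with domain compositions, and a PPI list with a controllable fraction of
DDI-coverable interactions.

Written corpora are identifier-obfuscated: a fraction of domains is renamed
to legacy aliases and a few obsolete-domain DDIs are injected, together
with the mapping table (alias -> unified id, obsolete -> REMOVED) that
restores the clean corpus — exercising the same identifier-unification
step real domain-database releases require.  Everything is deterministic
in the spec's seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .datasets import (
    HIGHER,
    LOWER,
    PREDICTED,
    REMOVED,
    STRUCTURAL,
    DDIDataset,
    DomainPair,
    PPISet,
    ProteinDomainMap,
    canonical_pair,
)


class SpecError(ValueError):
    """The corpus spec is invalid or infeasible."""


@dataclass
class DatasetSpec:
    """One predicted dataset to generate.

    ``tp_fraction`` of its DDIs are drawn from the gold standard;
    ``score_noise`` in [0, 1] controls how much the true- and
    false-positive score distributions overlap (0 = perfectly separated,
    1 = indistinguishable); ``redundancy_with = (source name, copy
    fraction)`` makes the dataset copy that fraction of an earlier
    dataset's DDIs before drawing the rest fresh.
    """

    name: str
    size: int
    tp_fraction: float
    score_noise: float = 0.3
    redundancy_with: tuple[str, float] | None = None
    scored: bool = True
    score_direction: str = HIGHER


@dataclass
class CorpusSpec:
    """Full description of a synthetic corpus; same seed -> identical corpus."""

    n_domains: int = 400
    n_gsp: int = 2000
    n_structural_datasets: int = 3
    datasets: list[DatasetSpec] = field(default_factory=lambda: default_dataset_specs())
    n_proteins: int = 250
    domains_per_protein_range: tuple[int, int] = (1, 4)
    n_ppis: int = 400
    ppi_ddi_coverage_target: float = 0.5
    seed: int = 0
    alias_fraction: float = 0.1
    n_obsolete_domains: int = 8

    def validate(self) -> None:
        n_pairs = self.n_domains * (self.n_domains + 1) // 2
        if self.n_gsp > n_pairs:
            raise SpecError(f"n_gsp={self.n_gsp} exceeds possible pairs ({n_pairs})")
        if self.n_structural_datasets < 1:
            raise SpecError("need at least one structural dataset")
        if not self.datasets:
            raise SpecError("need at least one predicted dataset")
        names = set()
        for d in self.datasets:
            for frac, what in [
                (d.tp_fraction, "tp_fraction"),
                (d.score_noise, "score_noise"),
            ]:
                if not 0.0 <= frac <= 1.0:
                    raise SpecError(f"dataset {d.name!r}: {what}={frac} outside [0,1]")
            if d.size <= 0:
                raise SpecError(f"dataset {d.name!r}: non-positive size")
            if round(d.tp_fraction * d.size) > self.n_gsp:
                raise SpecError(
                    f"dataset {d.name!r}: needs {round(d.tp_fraction * d.size)} "
                    f"gold-standard pairs but only {self.n_gsp} exist"
                )
            if d.redundancy_with is not None:
                src, frac = d.redundancy_with
                if src not in names:
                    raise SpecError(
                        f"dataset {d.name!r}: redundancy source {src!r} must be "
                        "declared earlier"
                    )
                if not 0.0 <= frac <= 1.0:
                    raise SpecError(f"dataset {d.name!r}: copy fraction {frac} outside [0,1]")
            names.add(d.name)
        if not 0.0 <= self.ppi_ddi_coverage_target <= 1.0:
            raise SpecError("ppi_ddi_coverage_target outside [0,1]")
        if not 0.0 <= self.alias_fraction <= 1.0:
            raise SpecError("alias_fraction outside [0,1]")


def default_dataset_specs() -> list[DatasetSpec]:
    """Eight predicted datasets spanning the accuracy range of published methods.

    True-positive fractions span 0.05-0.6 (the confidence range reported
    for real prediction methods); two datasets carry no scores (a minority
    of real sources publish none) and one uses p-value-like orientation.
    """
    return [
        DatasetSpec("coevo", 2000, 0.60),
        DatasetSpec("fusion", 2000, 0.50),
        DatasetSpec("interolog", 2000, 0.40),
        DatasetSpec("phylo", 2000, 0.30),
        DatasetSpec("pval", 2000, 0.20, score_direction=LOWER),
        DatasetSpec("textmine", 2000, 0.15, scored=False),
        DatasetSpec("netprop", 2000, 0.10),
        DatasetSpec("motif", 2000, 0.05, scored=False),
    ]


@dataclass
class Corpus:
    """A generated corpus plus the truth record of its generating parameters."""

    structural: list[DDIDataset]
    predicted: list[DDIDataset]
    pdmap: ProteinDomainMap
    ppis: PPISet
    truth: dict


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _domain_names(n: int) -> list[str]:
    return [f"PF{i + 1:05d}" for i in range(n)]


def _sample_pairs(
    rng: np.random.Generator, pool: list[DomainPair], k: int
) -> list[DomainPair]:
    idx = rng.choice(len(pool), size=k, replace=False)
    return [pool[i] for i in sorted(idx)]


def _draw_scores(
    rng: np.random.Generator, n: int, is_tp: np.ndarray, noise: float
) -> np.ndarray:
    """Raw scores in (0,1): TPs ~ Beta(1+4s, 1), FPs ~ Beta(1, 1+4s), s = 1-noise."""
    s = 1.0 - noise
    a_tp, b_tp = 1.0 + 4.0 * s, 1.0
    scores = np.where(
        is_tp,
        rng.beta(a_tp, b_tp, size=n),
        rng.beta(b_tp, a_tp, size=n),
    )
    return scores


def simulate_corpus(spec: CorpusSpec) -> Corpus:
    """Generate a full corpus (structural + predicted datasets, proteome, PPIs)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    domains = _domain_names(spec.n_domains)

    all_pairs = [
        DomainPair(domains[i], domains[j])
        for i in range(spec.n_domains)
        for j in range(i, spec.n_domains)
    ]
    gsp_idx = set(rng.choice(len(all_pairs), size=spec.n_gsp, replace=False).tolist())
    gsp_pool = [all_pairs[i] for i in sorted(gsp_idx)]
    bg_pool = [p for i, p in enumerate(all_pairs) if i not in gsp_idx]
    gsp_set = set(gsp_pool)

    # Structural datasets: each gold pair lands in >= 1 of them.
    structural = [
        DDIDataset(name=f"struct{k + 1}", kind=STRUCTURAL)
        for k in range(spec.n_structural_datasets)
    ]
    for pair in gsp_pool:
        members = [k for k in range(len(structural)) if rng.random() < 0.5]
        if not members:
            members = [int(rng.integers(len(structural)))]
        for k in members:
            structural[k].ddis.add(pair)

    predicted: list[DDIDataset] = []
    by_name: dict[str, DDIDataset] = {}
    realized_tp: dict[str, float] = {}
    for dspec in spec.datasets:
        chosen: set[DomainPair] = set()
        if dspec.redundancy_with is not None:
            src_name, copy_frac = dspec.redundancy_with
            src_pairs = sorted(by_name[src_name].ddis)
            n_copy = min(round(copy_frac * dspec.size), len(src_pairs))
            chosen.update(_sample_pairs(rng, src_pairs, n_copy))
        n_fresh = dspec.size - len(chosen)
        n_tp = round(dspec.tp_fraction * n_fresh)
        tp_avail = [p for p in gsp_pool if p not in chosen]
        bg_avail = [p for p in bg_pool if p not in chosen]
        chosen.update(_sample_pairs(rng, tp_avail, min(n_tp, len(tp_avail))))
        n_bg = dspec.size - len(chosen)
        chosen.update(_sample_pairs(rng, bg_avail, min(n_bg, len(bg_avail))))

        pairs = sorted(chosen)
        ds = DDIDataset(
            name=dspec.name,
            kind=PREDICTED,
            ddis=set(pairs),
            score_direction=dspec.score_direction,
        )
        if dspec.scored:
            is_tp = np.array([p in gsp_set for p in pairs])
            raw = _draw_scores(rng, len(pairs), is_tp, dspec.score_noise)
            if dspec.score_direction == LOWER:
                raw = -raw
            ds.raw_scores = dict(zip(pairs, raw.tolist()))
        predicted.append(ds)
        by_name[dspec.name] = ds
        realized_tp[dspec.name] = len(ds.ddis & gsp_set) / len(ds.ddis)

    pdmap, ppis, realized_coverage = _simulate_proteome(
        spec, rng, domains, structural, predicted
    )

    truth = {
        "seed": spec.seed,
        "n_domains": spec.n_domains,
        "n_gsp": len(gsp_set),
        "datasets": [asdict(d) for d in spec.datasets],
        "realized_tp_fraction": realized_tp,
        "realized_ppi_coverage": realized_coverage,
        "n_proteins": len(pdmap.entries),
        "n_ppis": len(ppis),
    }
    return Corpus(
        structural=structural, predicted=predicted, pdmap=pdmap, ppis=ppis, truth=truth
    )


def _simulate_proteome(
    spec: CorpusSpec,
    rng: np.random.Generator,
    domains: list[str],
    structural: Sequence[DDIDataset],
    predicted: Sequence[DDIDataset],
) -> tuple[ProteinDomainMap, PPISet, float]:
    """Assign domains to proteins, then sample PPIs near the coverage target.

    Coverage is achieved by rejection sampling (a capped number of retries
    per PPI); the realized fraction is reported, not forced.
    """
    lo, hi = spec.domains_per_protein_range
    entries: dict[str, set[str]] = {}
    for i in range(spec.n_proteins):
        k = int(rng.integers(lo, hi + 1))
        idx = rng.choice(len(domains), size=k, replace=False)
        entries[f"P{i + 1:04d}"] = {domains[j] for j in sorted(idx)}
    pdmap = ProteinDomainMap(entries=entries)

    all_ddis: set[DomainPair] = set()
    for ds in list(structural) + list(predicted):
        all_ddis |= ds.ddis
    inv = pdmap.inverted()
    coverable = sorted(
        p for p in all_ddis if inv.get(p.a) and inv.get(p.b)
    )
    proteins = sorted(entries)

    def is_covered(pa: str, pb: str) -> bool:
        return any(
            canonical_pair(a, b) in all_ddis
            for a in entries[pa]
            for b in entries[pb]
        )

    n_cov_target = round(spec.ppi_ddi_coverage_target * spec.n_ppis)
    pairs: set[tuple[str, str]] = set()
    n_cov = 0
    cap = 200
    for want_covered in [True] * n_cov_target + [False] * (spec.n_ppis - n_cov_target):
        for _ in range(cap):
            if want_covered and coverable:
                ddi = coverable[int(rng.integers(len(coverable)))]
                pa = sorted(inv[ddi.a])[int(rng.integers(len(inv[ddi.a])))]
                pb = sorted(inv[ddi.b])[int(rng.integers(len(inv[ddi.b])))]
            else:
                pa = proteins[int(rng.integers(len(proteins)))]
                pb = proteins[int(rng.integers(len(proteins)))]
            key = (min(pa, pb), max(pa, pb))
            if key in pairs:
                continue
            if not want_covered and is_covered(*key):
                continue
            pairs.add(key)
            n_cov += is_covered(*key)
            break
        # cap exhausted: skip this PPI rather than loop forever
    ppis = PPISet(pairs=pairs)
    realized = n_cov / len(pairs) if pairs else 0.0
    return pdmap, ppis, realized


# ---------------------------------------------------------------------------
# Writing (with identifier obfuscation + mapping table)
# ---------------------------------------------------------------------------


def write_corpus(corpus: Corpus, out_dir: str | Path, spec: CorpusSpec) -> dict[str, Path]:
    """Write all corpus files plus manifest, mapping table and truth record.

    Dataset files are emitted with a fraction of domain ids replaced by
    legacy aliases and a few obsolete-domain DDIs injected; ``mapping.tsv``
    undoes both, so ``load_datasets(manifest, mapping)`` recovers the clean
    corpus exactly.  Output is byte-deterministic in the spec seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed + 10_000_019)

    domains = sorted(
        set().union(*(ds.domain_universe for ds in corpus.structural + corpus.predicted))
    )
    n_alias = round(spec.alias_fraction * len(domains))
    alias_idx = rng.choice(len(domains), size=n_alias, replace=False)
    alias_of = {domains[i]: f"LEGACY{i + 1:05d}" for i in sorted(alias_idx)}
    obsolete = [f"OBS{i + 1:03d}" for i in range(spec.n_obsolete_domains)]
    mapping_rows = sorted((alias, real) for real, alias in alias_of.items())
    mapping_rows += [(o, REMOVED) for o in obsolete]

    def obfuscate(d: str) -> str:
        return alias_of.get(d, d)

    paths: dict[str, Path] = {}
    manifest_entries = []
    for ds, dspec in [(d, None) for d in corpus.structural] + list(
        zip(corpus.predicted, spec.datasets)
    ):
        fname = f"{ds.kind}_{ds.name}.tsv"
        fpath = out / fname
        scored = bool(ds.raw_scores)
        with open(fpath, "w", encoding="utf-8") as fh:
            fh.write("# domain_a\tdomain_b" + ("\tscore\n" if scored else "\n"))
            for pair in sorted(ds.ddis):
                a, b = obfuscate(pair.a), obfuscate(pair.b)
                if scored:
                    fh.write(f"{a}\t{b}\t{ds.raw_scores[pair]!r}\n")
                else:
                    fh.write(f"{a}\t{b}\n")
            if obsolete:
                n_junk = math.ceil(0.01 * len(ds.ddis))
                for _ in range(n_junk):
                    oa = obsolete[int(rng.integers(len(obsolete)))]
                    partner = domains[int(rng.integers(len(domains)))]
                    if scored:
                        fh.write(f"{oa}\t{obfuscate(partner)}\t{rng.random()!r}\n")
                    else:
                        fh.write(f"{oa}\t{obfuscate(partner)}\n")
        paths[ds.name] = fpath
        manifest_entries.append(
            {
                "name": ds.name,
                "path": fname,
                "kind": ds.kind,
                "score_column": 2 if scored else None,
                "score_direction": ds.score_direction,
            }
        )

    with open(out / "mapping.tsv", "w", encoding="utf-8") as fh:
        fh.write("# old_id\tnew_id\n")
        for old, new in mapping_rows:
            fh.write(f"{old}\t{new}\n")

    with open(out / "pdmap.tsv", "w", encoding="utf-8") as fh:
        fh.write("# protein\tdomain\n")
        for protein in sorted(corpus.pdmap.entries):
            for d in sorted(corpus.pdmap.entries[protein]):
                fh.write(f"{protein}\t{d}\n")

    with open(out / "ppi.tsv", "w", encoding="utf-8") as fh:
        fh.write("# protein_a\tprotein_b\n")
        for a, b in sorted(corpus.ppis.pairs):
            fh.write(f"{a}\t{b}\n")

    with open(out / "manifest.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest_entries, fh, sort_keys=False)

    with open(out / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(corpus.truth, fh, indent=2, sort_keys=True)
        fh.write("\n")

    paths.update(
        mapping=out / "mapping.tsv",
        pdmap=out / "pdmap.tsv",
        ppi=out / "ppi.tsv",
        manifest=out / "manifest.yaml",
        truth=out / "truth.json",
    )
    return paths


def load_corpus_spec(path: str | Path) -> CorpusSpec:
    """Read a CorpusSpec from YAML (missing fields take the defaults)."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if "datasets" in raw:
        raw["datasets"] = [
            DatasetSpec(**{**d, "redundancy_with": tuple(d["redundancy_with"])})
            if d.get("redundancy_with")
            else DatasetSpec(**d)
            for d in raw["datasets"]
        ]
    if "domains_per_protein_range" in raw:
        raw["domains_per_protein_range"] = tuple(raw["domains_per_protein_range"])
    return CorpusSpec(**raw)
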