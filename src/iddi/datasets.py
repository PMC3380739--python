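"""Reading, validation and identifier normalization of DDI evidence datasets.

A domain-domain interaction (DDI) is an unordered pair of protein-domain
family identifiers (Pfam-style, e.g. ``PF00001``).  Evidence datasets come
in two kinds: *structural* (DDIs observed in 3D structures of protein
complexes, treated as verified) and *predicted* (computational inference,
optionally carrying a per-DDI raw prediction score).  Because source
databases use different identifier systems and domain-database releases,
every dataset passes through a mapping table (old id -> new id, or the
``REMOVED`` sentinel for domains absent from the unified release) before
integration; any DDI touching a removed domain is discarded.

All on-disk formats are plain TSV with ``#`` comment lines; datasets are
declared in a YAML/JSON manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

#: Sentinel in a mapping table marking a domain absent from the unified
#: domain-database release; DDIs touching such a domain are dropped.
REMOVED = "REMOVED"

STRUCTURAL = "structural"
PREDICTED = "predicted"

HIGHER = "higher"
LOWER = "lower"


class ValidationError(ValueError):
    """Malformed input data (bad identifier, malformed row, bad manifest)."""


@dataclass(frozen=True, order=True)
class DomainPair:
    """Canonical unordered pair of domain identifiers.

    ``a <= b`` lexicographically; ``a == b`` is a self-interacting domain.
    Construct through :func:`canonical_pair` to enforce the invariants.
    """

    a: str
    b: str

    def __iter__(self):
        return iter((self.a, self.b))

    def other(self, d: str) -> str:
        """The partner of domain ``d`` in this pair (``d`` itself for a self-pair)."""
        return self.b if d == self.a else self.a


def canonical_pair(x: str, y: str) -> DomainPair:
    """Return the canonical (lexicographically ordered) pair for two domain ids.

    Idempotent and symmetric; self-pairs are allowed.  Empty identifiers are
    rejected.
    """
    if not x or not y:
        raise ValidationError(f"empty domain identifier in pair ({x!r}, {y!r})")
    return DomainPair(x, y) if x <= y else DomainPair(y, x)


@dataclass
class DDIDataset:
    """One DDI evidence source: its DDI set, optional raw scores and metadata.

    ``score_direction`` states the orientation of the raw scores: ``higher``
    means larger raw score = more confident; ``lower`` is for p-value-like
    scores.  The orientation is explicit metadata from the manifest, never
    guessed from the data.
    """

    name: str
    kind: str
    ddis: set[DomainPair] = field(default_factory=set)
    raw_scores: dict[DomainPair, float] = field(default_factory=dict)
    score_direction: str = HIGHER

    def __post_init__(self):
        if self.kind not in (STRUCTURAL, PREDICTED):
            raise ValidationError(f"dataset {self.name!r}: unknown kind {self.kind!r}")
        if self.score_direction not in (HIGHER, LOWER):
            raise ValidationError(
                f"dataset {self.name!r}: unknown score_direction {self.score_direction!r}"
            )
        extra = set(self.raw_scores) - self.ddis
        if extra:
            raise ValidationError(
                f"dataset {self.name!r}: raw scores for pairs not in the DDI set: "
                f"{sorted(extra)[:3]}..."
            )

    @property
    def domain_universe(self) -> set[str]:
        """All domain identifiers appearing in this dataset's DDIs."""
        out: set[str] = set()
        for p in self.ddis:
            out.add(p.a)
            out.add(p.b)
        return out

    def better_score(self, s1: float, s2: float) -> float:
        """The more confident of two raw scores under this dataset's orientation."""
        return max(s1, s2) if self.score_direction == HIGHER else min(s1, s2)


@dataclass
class DomainMapping:
    """Identifier unification table: old id -> new id or :data:`REMOVED`."""

    entries: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for old, new in self.entries.items():
            if not old or not new:
                raise ValidationError(f"mapping entry with empty identifier: {old!r} -> {new!r}")

    def resolve(self, domain: str) -> str:
        """Map a domain id; identity when absent from the table."""
        return self.entries.get(domain, domain)


@dataclass
class ProteinDomainMap:
    """Protein accession -> set of constituent domain identifiers (SwissPfam-like)."""

    entries: dict[str, set[str]] = field(default_factory=dict)

    def domains(self, protein: str) -> set[str]:
        """Domains of ``protein``; empty set for unknown proteins."""
        return self.entries.get(protein, set())

    def proteins_with(self, domain: str) -> set[str]:
        return {p for p, doms in self.entries.items() if domain in doms}

    def inverted(self) -> dict[str, set[str]]:
        """domain -> set of proteins containing it."""
        out: dict[str, set[str]] = {}
        for p, doms in self.entries.items():
            for d in doms:
                out.setdefault(d, set()).add(p)
        return out


@dataclass
class PPISet:
    """Set of canonical unordered protein-accession pairs (binary PPIs)."""

    pairs: set[tuple[str, str]] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        a, b = pair
        return (min(a, b), max(a, b)) in self.pairs


# ---------------------------------------------------------------------------
# TSV readers / writers
# ---------------------------------------------------------------------------


def _rows(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    """Yield (1-based line number, fields) for non-comment, non-blank TSV lines."""
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_ddi_dataset(
    path: str | Path,
    name: str,
    kind: str,
    score_column: int | None = None,
    score_direction: str = HIGHER,
) -> DDIDataset:
    """Read a DDI TSV (columns: domain_a, domain_b[, score, ...]).

    Rows are canonicalized; duplicate pairs are resolved keeping the most
    confident raw score under the declared orientation.  ``score_column`` is
    the 0-based column index of the raw score, or None for score-less
    datasets.
    """
    ds = DDIDataset(name=name, kind=kind, score_direction=score_direction)
    for lineno, fields in _rows(path):
        if len(fields) < 2:
            raise ValidationError(f"{path}:{lineno}: expected >= 2 columns, got {len(fields)}")
        try:
            pair = canonical_pair(fields[0].strip(), fields[1].strip())
        except ValidationError as e:
            raise ValidationError(f"{path}:{lineno}: {e}") from None
        score = None
        if score_column is not None:
            if score_column >= len(fields):
                raise ValidationError(
                    f"{path}:{lineno}: declared score column {score_column} missing "
                    f"(row has {len(fields)} columns)"
                )
            try:
                score = float(fields[score_column])
            except ValueError:
                raise ValidationError(
                    f"{path}:{lineno}: non-numeric score {fields[score_column]!r}"
                ) from None
        if pair in ds.ddis:
            if score is not None:
                ds.raw_scores[pair] = ds.better_score(ds.raw_scores[pair], score)
        else:
            ds.ddis.add(pair)
            if score is not None:
                ds.raw_scores[pair] = score
    if not ds.ddis:
        raise ValidationError(f"{path}: dataset {name!r} is empty after loading")
    return ds


def write_ddi_dataset(ds: DDIDataset, path: str | Path) -> None:
    """Write the canonical TSV form (sorted rows; score column only if scored)."""
    with open(path, "w", encoding="utf-8") as fh:
        for pair in sorted(ds.ddis):
            if pair in ds.raw_scores:
                fh.write(f"{pair.a}\t{pair.b}\t{ds.raw_scores[pair]!r}\n")
            else:
                fh.write(f"{pair.a}\t{pair.b}\n")


def apply_domain_mapping(ds: DDIDataset, mapping: DomainMapping) -> DDIDataset:
    """Normalize a dataset's identifiers through a mapping table.

    Each domain is replaced via the table (identity when absent); any DDI
    with a domain mapped to :data:`REMOVED` is dropped; pairs are
    re-canonicalized, and collisions created by the mapping are resolved by
    the same best-score dedup rule used at read time.
    """
    out = DDIDataset(name=ds.name, kind=ds.kind, score_direction=ds.score_direction)
    for pair in ds.ddis:
        a, b = mapping.resolve(pair.a), mapping.resolve(pair.b)
        if a == REMOVED or b == REMOVED:
            continue
        new = canonical_pair(a, b)
        score = ds.raw_scores.get(pair)
        if new in out.ddis:
            if score is not None:
                prev = out.raw_scores.get(new)
                out.raw_scores[new] = score if prev is None else out.better_score(prev, score)
        else:
            out.ddis.add(new)
            if score is not None:
                out.raw_scores[new] = score
    return out


def read_domain_mapping(path: str | Path) -> DomainMapping:
    """Read a two-column TSV: old_id, new_id (new_id may be ``REMOVED``)."""
    entries: dict[str, str] = {}
    for lineno, fields in _rows(path):
        if len(fields) < 2:
            raise ValidationError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
        old, new = fields[0].strip(), fields[1].strip()
        if not old or not new:
            raise ValidationError(f"{path}:{lineno}: empty identifier in mapping row")
        entries[old] = new
    return DomainMapping(entries=entries)


def read_protein_domain_map(path: str | Path) -> ProteinDomainMap:
    """Read a flat protein->domain TSV (one domain assignment per row)."""
    entries: dict[str, set[str]] = {}
    for lineno, fields in _rows(path):
        if len(fields) < 2:
            raise ValidationError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
        protein, domain = fields[0].strip(), fields[1].strip()
        if not protein or not domain:
            raise ValidationError(f"{path}:{lineno}: empty identifier")
        entries.setdefault(protein, set()).add(domain)
    return ProteinDomainMap(entries=entries)


def read_ppi_list(path: str | Path) -> PPISet:
    """Read a binary PPI TSV (protein_a, protein_b); pairs canonicalized."""
    pairs: set[tuple[str, str]] = set()
    for lineno, fields in _rows(path):
        if len(fields) < 2:
            raise ValidationError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
        a, b = fields[0].strip(), fields[1].strip()
        if not a or not b:
            raise ValidationError(f"{path}:{lineno}: empty protein accession")
        pairs.add((min(a, b), max(a, b)))
    return PPISet(pairs=pairs)


def write_ppi_list(ppis: PPISet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(ppis.pairs):
            fh.write(f"{a}\t{b}\n")


def write_protein_domain_map(pdmap: ProteinDomainMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for protein in sorted(pdmap.entries):
            for domain in sorted(pdmap.entries[protein]):
                fh.write(f"{protein}\t{domain}\n")


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------


def read_manifest(path: str | Path) -> list[dict]:
    """Read a dataset manifest (YAML or JSON list of dataset declarations).

    Each entry: {name, path, kind: structural|predicted,
    score_column: int|null, score_direction: higher|lower}.  Relative dataset
    paths are resolved against the manifest's directory.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        entries = yaml.safe_load(fh)
    if not isinstance(entries, list):
        raise ValidationError(f"{path}: manifest must be a list of dataset entries")
    out = []
    for i, e in enumerate(entries):
        if not isinstance(e, Mapping) or "name" not in e or "path" not in e or "kind" not in e:
            raise ValidationError(f"{path}: entry {i} must declare name, path and kind")
        entry = dict(e)
        p = Path(entry["path"])
        entry["path"] = str(p if p.is_absolute() else path.parent / p)
        entry.setdefault("score_column", None)
        entry.setdefault("score_direction", HIGHER)
        out.append(entry)
    return out


def load_datasets(
    manifest: list[dict], mapping: DomainMapping | None = None
) -> tuple[list[DDIDataset], list[DDIDataset]]:
    """Load all manifest datasets, apply a mapping table if given.

    Returns (structural datasets, predicted datasets) in manifest order.
    """
    structural, predicted = [], []
    for entry in manifest:
        ds = read_ddi_dataset(
            entry["path"],
            name=entry["name"],
            kind=entry["kind"],
            score_column=entry["score_column"],
            score_direction=entry["score_direction"],
        )
        if mapping is not None:
            ds = apply_domain_mapping(ds, mapping)
        (structural if ds.kind == STRUCTURAL else predicted).append(ds)
    return structural, predicted
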