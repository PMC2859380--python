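"""Binary protein-protein interaction ingestion and interactome merging.

Per-database PPI files are read as flat TSVs, taxon-filtered, identifier-
normalised (see :mod:`interoscore.orthology`) and merged into one interactome
per species with non-redundant experimental evidence: each distinct
(experiment type, evidence id) pair is kept once regardless of how many
source databases report it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .orthology import FormatError
from .species import SpeciesId

logger = logging.getLogger(__name__)

PPI_COLUMNS = [
    "interactor_a",
    "interactor_b",
    "taxid_a",
    "taxid_b",
    "experiment_type",
    "evidence_id",
    "source_db",
]

# BIND-style files publish no experiment type; its rows get this sentinel.
BIND_SENTINEL_TYPE = "protein_protein"

KNOWN = "known"
PREDICTED = "predicted"


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Unordered gene pair in canonical (sorted) order, so (A,B) == (B,A)."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class EvidenceRecord:
    experiment_type: str
    evidence_id: str
    source_db: str = ""

    @property
    def key(self) -> tuple[str, str]:
        """Non-redundancy key: database of origin does not matter."""
        return (self.experiment_type, self.evidence_id)


@dataclass
class Interaction:
    """One undirected interaction with its supporting evidence."""

    pair: tuple[str, str]
    species: str
    evidence: set[EvidenceRecord] = field(default_factory=set)
    origin: str = KNOWN

    def __post_init__(self) -> None:
        self.pair = canonical_pair(*self.pair)

    @property
    def is_self(self) -> bool:
        return self.pair[0] == self.pair[1]

    def evidence_keys(self) -> set[tuple[str, str]]:
        return {e.key for e in self.evidence}

    def experiment_types(self) -> set[str]:
        return {e.experiment_type for e in self.evidence}


class Interactome:
    """A species' merged, deduplicated set of undirected interactions."""

    def __init__(self, species: str, interactions: Iterable[Interaction] = ()):
        self.species = species
        self._by_pair: dict[tuple[str, str], Interaction] = {}
        for ia in interactions:
            self.add(ia)

    def add(self, interaction: Interaction) -> None:
        if interaction.species != self.species:
            raise ValueError(
                f"interaction species {interaction.species!r} != interactome {self.species!r}"
            )
        existing = self._by_pair.get(interaction.pair)
        if existing is None:
            self._by_pair[interaction.pair] = Interaction(
                pair=interaction.pair,
                species=interaction.species,
                evidence=set(interaction.evidence),
                origin=interaction.origin,
            )
        else:
            _merge_evidence(existing.evidence, interaction.evidence)

    def __len__(self) -> int:
        return len(self._by_pair)

    def __iter__(self) -> Iterable[Interaction]:
        return iter(self._by_pair.values())

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return canonical_pair(*pair) in self._by_pair

    def get(self, pair: tuple[str, str]) -> Interaction | None:
        return self._by_pair.get(canonical_pair(*pair))

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return set(self._by_pair)

    @property
    def proteins(self) -> set[str]:
        nodes: set[str] = set()
        for a, b in self._by_pair:
            nodes.add(a)
            nodes.add(b)
        return nodes


def _merge_evidence(target: set[EvidenceRecord], new: Iterable[EvidenceRecord]) -> None:
    keys = {e.key for e in target}
    for rec in new:
        if rec.key not in keys:
            target.add(rec)
            keys.add(rec.key)


def load_ppi(
    path: str | Path,
    db_name: str,
    species: SpeciesId,
) -> list[dict]:
    """Read one database's PPI TSV and return raw rows for the given species.

    Rows are taxon-filtered (both interactors must carry the species' taxid)
    and rows flagged as involving non-protein molecules (via the optional
    molecule_type_a/b columns) are dropped. Files in the BIND dialect — no
    experiment_type column — get the ``protein_protein`` sentinel type and a
    row-derived evidence id.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        return []
    bind_dialect = "experiment_type" not in df.columns
    required = ["interactor_a", "interactor_b", "taxid_a", "taxid_b"]
    if not bind_dialect:
        required += ["experiment_type", "evidence_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")

    rows: list[dict] = []
    n_taxon = n_nonprotein = 0
    for i, row in enumerate(df.itertuples(index=False)):
        d = row._asdict()
        try:
            tax_a, tax_b = int(d["taxid_a"]), int(d["taxid_b"])
        except (TypeError, ValueError):
            n_taxon += 1
            continue
        if tax_a != species.taxid or tax_b != species.taxid:
            n_taxon += 1
            continue
        if (
            str(d.get("molecule_type_a", "protein")) != "protein"
            or str(d.get("molecule_type_b", "protein")) != "protein"
        ):
            n_nonprotein += 1
            continue
        out = {
            "interactor_a": str(d["interactor_a"]),
            "interactor_b": str(d["interactor_b"]),
            "experiment_type": (
                BIND_SENTINEL_TYPE if bind_dialect else str(d["experiment_type"])
            ),
            "evidence_id": (
                f"{db_name}:row{i}" if bind_dialect else str(d["evidence_id"])
            ),
            "source_db": str(d.get("source_db", db_name)) if not bind_dialect else db_name,
        }
        rows.append(out)
    if n_taxon or n_nonprotein:
        logger.info(
            "%s: dropped %d rows by taxon filter, %d non-protein rows",
            path, n_taxon, n_nonprotein,
        )
    return rows


def merge_interactomes(row_sets: Sequence[Iterable[dict]], species: str) -> Interactome:
    """Merge normalized per-database row sets into one interactome.

    One Interaction per unordered pair; evidence is the union with each
    (experiment_type, evidence_id) kept once regardless of source database.
    Merging is order-invariant up to evidence source_db bookkeeping.
    """
    tome = Interactome(species)
    for rows in row_sets:
        for row in rows:
            tome.add(
                Interaction(
                    pair=(row["interactor_a"], row["interactor_b"]),
                    species=species,
                    evidence={
                        EvidenceRecord(
                            experiment_type=row["experiment_type"],
                            evidence_id=row["evidence_id"],
                            source_db=row.get("source_db", ""),
                        )
                    },
                )
            )
    return tome


def overlap_stats(row_sets: Sequence[Iterable[dict]], db_names: Sequence[str] | None = None):
    """Observed per-database and pairwise gene/interaction overlap counts.

    Pure counting over merged canonical pairs. Returns a dict with per-db
    counts, pairwise overlaps, the count present in all databases, and the
    union size.
    """
    names = list(db_names) if db_names else [f"db{i+1}" for i in range(len(row_sets))]
    pair_sets: dict[str, set[tuple[str, str]]] = {}
    gene_sets: dict[str, set[str]] = {}
    for name, rows in zip(names, row_sets):
        pairs: set[tuple[str, str]] = set()
        genes: set[str] = set()
        for row in rows:
            p = canonical_pair(row["interactor_a"], row["interactor_b"])
            pairs.add(p)
            genes.update(p)
        pair_sets[name] = pairs
        gene_sets[name] = genes

    stats = {
        "per_db": {
            n: {"interactions": len(pair_sets[n]), "genes": len(gene_sets[n])}
            for n in names
        },
        "pairwise": {},
        "all": 0,
        "union_interactions": len(set().union(*pair_sets.values())) if pair_sets else 0,
        "union_genes": len(set().union(*gene_sets.values())) if gene_sets else 0,
    }
    for n1, n2 in combinations(names, 2):
        stats["pairwise"][f"{n1}&{n2}"] = {
            "interactions": len(pair_sets[n1] & pair_sets[n2]),
            "genes": len(gene_sets[n1] & gene_sets[n2]),
        }
    if pair_sets:
        common = set.intersection(*pair_sets.values())
        stats["all"] = len(common)
    return stats


def write_interactome(tome: Interactome, path: str | Path) -> None:
    """Write a merged interactome TSV: pair + pipe-joined evidence list."""
    rows = []
    for ia in sorted(tome, key=lambda x: x.pair):
        ev = ";".join(
            "|".join((e.experiment_type, e.evidence_id, e.source_db))
            for e in sorted(ia.evidence, key=lambda e: e.key)
        )
        rows.append((ia.pair[0], ia.pair[1], ia.species, ia.origin, ev))
    pd.DataFrame(
        rows, columns=["interactor_a", "interactor_b", "species", "origin", "evidence"]
    ).to_csv(path, sep="\t", index=False)


def read_interactome(path: str | Path) -> Interactome:
    """Read an interactome TSV written by :func:`write_interactome`."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["interactor_a", "interactor_b", "species", "origin", "evidence"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        raise FormatError(f"{path}: interactome file has no rows")
    species = str(df.iloc[0]["species"])
    tome = Interactome(species)
    for row in df.itertuples(index=False):
        evidence = set()
        if isinstance(row.evidence, str) and row.evidence:
            for chunk in row.evidence.split(";"):
                parts = chunk.split("|")
                if len(parts) == 3:
                    evidence.add(EvidenceRecord(*parts))
        tome.add(
            Interaction(
                pair=(str(row.interactor_a), str(row.interactor_b)),
                species=species,
                evidence=evidence,
                origin=str(row.origin),
            )
        )
    return tome
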