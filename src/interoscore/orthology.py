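"""Cross-species orthology tables and identifier synonym tables.

Orthology is an *input*: pairs of genes in different species annotated with a
homology class (one2one / one2many / many2many) and the percent of source
residues identical to the target. The map is indexed by
``(source_gene, target_species)`` so that prediction and scoring can ask
"which genes in species *t* are orthologues of gene *g*?" in O(1).

Synonym tables map external identifiers (retired accessions, gene-name
synonyms) onto current gene ids, and drive the identifier normalisation step
applied to raw interaction rows before interactomes are merged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .species import SpeciesRegistry

logger = logging.getLogger(__name__)

HOMOLOGY_TYPES = ("one2one", "one2many", "many2many")

ORTHOLOGY_COLUMNS = [
    "source_gene",
    "source_species",
    "target_gene",
    "target_species",
    "homology_type",
    "percent_identity",
]

SYNONYM_COLUMNS = ["external_id", "current_id", "species", "status"]

SYNONYM_STATUSES = ("known", "novel", "retired")


class FormatError(ValueError):
    """A required column is missing or a file is structurally invalid."""


@dataclass(frozen=True)
class OrthologyRecord:
    """A directed orthologue pair.

    ``percent_identity`` is the percent of source-protein residues identical
    to the target orthologue, in [0, 100]; the reciprocal record carries its
    own value.
    """

    source_gene: str
    source_species: str
    target_gene: str
    target_species: str
    homology_type: str
    percent_identity: float

    def __post_init__(self) -> None:
        if self.source_species == self.target_species:
            raise ValueError("orthology records must link different species")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(f"percent identity out of range: {self.percent_identity}")
        if self.homology_type not in HOMOLOGY_TYPES:
            raise ValueError(f"unknown homology type: {self.homology_type}")


class OrthologyMap:
    """All orthologue pairs of an analysis, indexed by (source gene, target species)."""

    def __init__(self, records: Iterable[OrthologyRecord] = ()):
        self._records: list[OrthologyRecord] = []
        self._index: dict[tuple[str, str], list[OrthologyRecord]] = {}
        self._seen: set[tuple[str, str, str, str]] = set()
        for rec in records:
            self.add(rec)

    def add(self, rec: OrthologyRecord) -> None:
        key = (rec.source_gene, rec.source_species, rec.target_gene, rec.target_species)
        if key in self._seen:
            return
        self._seen.add(key)
        self._records.append(rec)
        self._index.setdefault((rec.source_gene, rec.target_species), []).append(rec)

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records)

    def orthologues_of(self, gene: str, target_species: str) -> list[OrthologyRecord]:
        """Records linking ``gene`` to ``target_species``, identity-descending.

        A gene with no orthologues yields the empty list, never an error.
        """
        recs = self._index.get((gene, target_species), [])
        return sorted(recs, key=lambda r: (-r.percent_identity, r.target_gene))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.source_gene, r.source_species, r.target_gene, r.target_species,
                 r.homology_type, r.percent_identity)
                for r in self._records
            ],
            columns=ORTHOLOGY_COLUMNS,
        )


def orthologues_of(omap: OrthologyMap, gene: str, target_species: str) -> list[OrthologyRecord]:
    """Functional alias for :meth:`OrthologyMap.orthologues_of`."""
    return omap.orthologues_of(gene, target_species)


def load_orthology(path: str | Path, registry: SpeciesRegistry) -> OrthologyMap:
    """Read an orthology TSV (6 columns, header required) into an OrthologyMap.

    Rows naming a species absent from the registry, carrying an identity
    outside [0, 100], or an unknown homology type are rejected; the rejection
    count is logged, never fatal. A missing column raises :class:`FormatError`;
    an empty file yields an empty map with a warning.
    """
    df = _read_tsv(path, ORTHOLOGY_COLUMNS)
    if df.empty:
        logger.warning("orthology file %s is empty", path)
        return OrthologyMap()
    omap = OrthologyMap()
    rejected = 0
    for row in df.itertuples(index=False):
        try:
            identity = float(row.percent_identity)
        except (TypeError, ValueError):
            rejected += 1
            continue
        if (
            row.source_species not in registry
            or row.target_species not in registry
            or row.source_species == row.target_species
            or not 0.0 <= identity <= 100.0
            or row.homology_type not in HOMOLOGY_TYPES
        ):
            rejected += 1
            continue
        omap.add(
            OrthologyRecord(
                source_gene=str(row.source_gene),
                source_species=str(row.source_species),
                target_gene=str(row.target_gene),
                target_species=str(row.target_species),
                homology_type=str(row.homology_type),
                percent_identity=identity,
            )
        )
    if rejected:
        logger.info("rejected %d invalid orthology rows from %s", rejected, path)
    return omap


def write_orthology(omap: OrthologyMap, path: str | Path) -> None:
    """Write the map back as a canonical (sorted) orthology TSV."""
    df = omap.to_frame().sort_values(ORTHOLOGY_COLUMNS).reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False)


@dataclass
class SynonymEntry:
    current_id: str
    species: str
    status: str  # known | novel | retired


@dataclass
class SynonymTable:
    """Many-to-one mapping of external identifiers onto current gene ids.

    Retired entries must carry a replacement current id (entries whose
    current id is empty are dropped at load time).
    """

    mapping: dict[str, SynonymEntry] = field(default_factory=dict)

    def resolve(self, external_id: str) -> SynonymEntry | None:
        return self.mapping.get(external_id)

    def __len__(self) -> int:
        return len(self.mapping)


def load_synonyms(path: str | Path) -> SynonymTable:
    """Read a synonym TSV: external_id, current_id, species, status."""
    df = _read_tsv(path, SYNONYM_COLUMNS)
    table = SynonymTable()
    dropped = 0
    for row in df.itertuples(index=False):
        current = "" if pd.isna(row.current_id) else str(row.current_id)
        status = str(row.status)
        if status not in SYNONYM_STATUSES:
            dropped += 1
            continue
        if status == "retired" and not current:
            dropped += 1  # retired with no replacement: unmappable, drop
            continue
        table.mapping[str(row.external_id)] = SynonymEntry(
            current_id=current, species=str(row.species), status=status
        )
    if dropped:
        logger.info("dropped %d unusable synonym rows from %s", dropped, path)
    return table


def write_synonyms(table: SynonymTable, path: str | Path) -> None:
    rows = sorted(
        (ext, e.current_id, e.species, e.status) for ext, e in table.mapping.items()
    )
    pd.DataFrame(rows, columns=SYNONYM_COLUMNS).to_csv(path, sep="\t", index=False)


def normalize_identifiers(
    raw_edges: Iterable[Mapping],
    synonyms: SynonymTable,
    expected_species: str,
    known_only: bool = False,
) -> tuple[list[dict], dict[str, int]]:
    """Map raw interaction rows onto current gene ids of the expected species.

    Retired identifiers are mapped forward to their replacement; rows whose
    resolved species differs from ``expected_species`` are dropped, as are
    rows with unmappable identifiers. With ``known_only`` genes whose status
    is ``novel`` are dropped too. All failures are counted, never fatal, and
    the operation is idempotent (current ids resolve to themselves).

    Returns (normalized rows, report) with report counts
    ``{converted, dropped_species_mismatch, dropped_unmappable, dropped_novel}``.
    """
    report = {
        "converted": 0,
        "dropped_species_mismatch": 0,
        "dropped_unmappable": 0,
        "dropped_novel": 0,
    }
    out: list[dict] = []
    for row in raw_edges:
        resolved: dict[str, str] = {}
        ok = True
        converted = False
        for key in ("interactor_a", "interactor_b"):
            raw_id = str(row[key])
            entry = synonyms.resolve(raw_id)
            if entry is None:
                report["dropped_unmappable"] += 1
                ok = False
                break
            if entry.species != expected_species:
                report["dropped_species_mismatch"] += 1
                ok = False
                break
            if known_only and entry.status == "novel":
                report["dropped_novel"] += 1
                ok = False
                break
            if entry.current_id != raw_id:
                converted = True
            resolved[key] = entry.current_id
        if not ok:
            continue
        if converted:
            report["converted"] += 1
        new_row = dict(row)
        new_row.update(resolved)
        out.append(new_row)
    return out, report


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=required)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df
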