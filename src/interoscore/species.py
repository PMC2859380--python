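"""Species registry: the set of organisms an analysis spans.

Every species carries a short code used in file columns (e.g. ``hsap``), an
NCBI taxonomy id used to filter interaction rows, and the single uppercase
genus initial used to build the per-interaction species notation string
(uppercase = interaction observed in that species, lowercase = orthologues
present but no observed interaction).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import yaml


@dataclass(frozen=True)
class SpeciesId:
    """One organism in the analysis.

    Parameters
    ----------
    code : short species token, e.g. ``"hsap"``.
    genus_letter : single uppercase letter, unique within a registry.
    name : display name.
    taxid : NCBI taxonomy identifier, used for taxon filtering of PPI rows.
    """

    code: str
    genus_letter: str
    name: str = ""
    taxid: int = 0

    def __post_init__(self) -> None:
        if not self.code:
            raise ValueError("species code must be non-empty")
        if len(self.genus_letter) != 1 or not self.genus_letter.isupper():
            raise ValueError(
                f"genus_letter must be a single uppercase letter, got {self.genus_letter!r}"
            )


class SpeciesRegistry:
    """Ordered collection of :class:`SpeciesId` with unique codes and letters.

    The registry order defines the letter order of the species notation.
    """

    def __init__(self, species: Iterable[SpeciesId]):
        self._species: list[SpeciesId] = list(species)
        codes = [s.code for s in self._species]
        letters = [s.genus_letter for s in self._species]
        if len(set(codes)) != len(codes):
            raise ValueError("duplicate species codes in registry")
        if len(set(letters)) != len(letters):
            raise ValueError("genus letters must be unique within a registry")
        self._by_code = {s.code: s for s in self._species}
        self._by_taxid = {s.taxid: s for s in self._species if s.taxid}

    def __iter__(self) -> Iterator[SpeciesId]:
        return iter(self._species)

    def __len__(self) -> int:
        return len(self._species)

    def __contains__(self, code: str) -> bool:
        return code in self._by_code

    def __getitem__(self, code: str) -> SpeciesId:
        return self._by_code[code]

    @property
    def codes(self) -> list[str]:
        return [s.code for s in self._species]

    def by_taxid(self, taxid: int) -> SpeciesId | None:
        return self._by_taxid.get(taxid)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SpeciesRegistry":
        """Load a registry from a YAML list of {code, genus_letter, name, taxid}."""
        with open(path) as fh:
            entries = yaml.safe_load(fh)
        return cls(
            SpeciesId(
                code=e["code"],
                genus_letter=e["genus_letter"],
                name=e.get("name", ""),
                taxid=int(e.get("taxid", 0)),
            )
            for e in entries
        )

    def to_yaml(self, path: str | Path) -> None:
        entries = [
            {
                "code": s.code,
                "genus_letter": s.genus_letter,
                "name": s.name,
                "taxid": s.taxid,
            }
            for s in self._species
        ]
        with open(path, "w") as fh:
            yaml.safe_dump(entries, fh, sort_keys=False)


def default_registry() -> SpeciesRegistry:
    """The five-organism registry: human, mouse, fly, worm, yeast (H, M, D, C, S)."""
    return SpeciesRegistry(
        [
            SpeciesId("hsap", "H", "Homo sapiens", 9606),
            SpeciesId("mmus", "M", "Mus musculus", 10090),
            SpeciesId("dmel", "D", "Drosophila melanogaster", 7227),
            SpeciesId("cele", "C", "Caenorhabditis elegans", 6239),
            SpeciesId("scer", "S", "Saccharomyces cerevisiae", 4932),
        ]
    )
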