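"""Cytoscape-compatible output and gene-list queries.

Networks are written as SIF (``geneA <tab> relation <tab> geneB``) plus one
edge-attribute (``.eda``) file per score and a single modern edge-table TSV.
Emission is deterministic: canonical pair order, sorted lines, fixed decimal
formatting — identical inputs give identical bytes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .interolog import InterologPrediction
from .orthology import OrthologyMap, SynonymTable
from .ppi import Interactome, canonical_pair
from .scoring import ScoreBundle

logger = logging.getLogger(__name__)

# Relation tokens in SIF output; the dialect is config-overridable.
RELATION_KNOWN = "pp"
RELATION_PREDICTED = "pred"


def _edge_lines(
    interactome: Interactome,
    predictions: Sequence[InterologPrediction],
    relation_known: str,
    relation_predicted: str,
) -> list[tuple[str, str, str]]:
    lines = [(a, relation_known, b) for a, b in sorted(interactome.pairs)]
    lines += [
        (p.pair[0], relation_predicted, p.pair[1])
        for p in sorted(predictions, key=lambda p: p.pair)
    ]
    return sorted(lines)


def write_cytoscape(
    interactome: Interactome,
    predictions: Sequence[InterologPrediction],
    scores: Mapping[tuple[str, str], ScoreBundle],
    ortho: OrthologyMap | None,
    outdir: str | Path,
    prefix: str | None = None,
    relation_known: str = RELATION_KNOWN,
    relation_predicted: str = RELATION_PREDICTED,
) -> dict[str, Path]:
    """Write SIF + per-score edge-attribute files + a combined edge TSV.

    Scores are looked up by canonical pair; an unscored edge is written to the
    SIF with its attributes omitted and a warning. Numeric attributes are
    formatted to 3 decimals. Returns the mapping of logical name to path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prefix = prefix or interactome.species
    relation_of: dict[tuple[str, str], str] = {
        p: relation_known for p in interactome.pairs
    }
    for pred in predictions:
        relation_of.setdefault(pred.pair, relation_predicted)

    sif_path = outdir / f"{prefix}.sif"
    lines = _edge_lines(interactome, predictions, relation_known, relation_predicted)
    sif_path.write_text("".join(f"{a}\t{rel}\t{b}\n" for a, rel, b in lines))

    attributes = {
        "interoscore": lambda b: f"{b.intero_score:.3f}",
        "speciesscore": lambda b: f"{b.species_score:.3f}",
        "experimentscore": lambda b: str(b.experiment_score),
        "speciesnotation": lambda b: b.notation,
    }
    paths = {"sif": sif_path}
    n_unscored = 0
    for attr, fmt in attributes.items():
        path = outdir / f"{prefix}.{attr}.eda"
        out_lines = [attr.capitalize()]
        for pair in sorted(relation_of):
            bundle = scores.get(pair)
            if bundle is None:
                n_unscored += 1
                continue
            rel = relation_of[pair]
            out_lines.append(f"{pair[0]} ({rel}) {pair[1]} = {fmt(bundle)}")
        path.write_text("\n".join(out_lines) + "\n")
        paths[attr] = path
    if n_unscored:
        logger.warning("%d edge attribute entries omitted (unscored edges)", n_unscored // len(attributes))

    if ortho is not None:
        path = outdir / f"{prefix}.orthotype.eda"
        out_lines = ["Orthotype"]
        for pair in sorted(relation_of):
            rel = relation_of[pair]
            types = sorted(
                {
                    rec.homology_type
                    for gene in pair
                    for sp in _other_species(scores.get(pair))
                    for rec in ortho.orthologues_of(gene, sp)
                }
            )
            if types:
                out_lines.append(f"{pair[0]} ({rel}) {pair[1]} = {'|'.join(types)}")
        path.write_text("\n".join(out_lines) + "\n")
        paths["orthotype"] = path

    # modern single-table edge attribute TSV
    rows = []
    for pair in sorted(relation_of):
        b = scores.get(pair)
        rows.append(
            (
                pair[0],
                pair[1],
                relation_of[pair],
                f"{b.intero_score:.3f}" if b else "",
                f"{b.species_score:.3f}" if b else "",
                b.experiment_score if b else "",
                f"{b.experiment_quality_score:.3f}" if b else "",
                b.notation if b else "",
            )
        )
    tsv_path = outdir / f"{prefix}.edges.tsv"
    pd.DataFrame(
        rows,
        columns=[
            "interactor_a", "interactor_b", "relation",
            "intero_score", "species_score", "experiment_score",
            "experiment_quality_score", "species_notation",
        ],
    ).to_csv(tsv_path, sep="\t", index=False)
    paths["edges"] = tsv_path
    return paths


def _other_species(bundle: ScoreBundle | None) -> list[str]:
    return sorted(bundle.single_species_scores) if bundle else []


def read_sif(path: str | Path) -> list[tuple[str, str, str]]:
    """Parse a SIF file back into (a, relation, b) tuples with canonical pairs."""
    edges = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"malformed SIF line: {line!r}")
        a, rel, b = parts
        a, b = canonical_pair(a, b)
        edges.append((a, rel, b))
    return edges


@dataclass
class QueryResult:
    """Interactions among the queried genes vs. from queried genes to others."""

    among: list[dict] = field(default_factory=list)
    beyond: list[dict] = field(default_factory=list)
    resolved: dict[str, str] = field(default_factory=dict)
    unresolved: list[str] = field(default_factory=list)


def query(
    gene_list: Iterable[str],
    interactome: Interactome,
    predictions: Sequence[InterologPrediction],
    scores: Mapping[tuple[str, str], ScoreBundle],
    synonyms: SynonymTable | None = None,
) -> QueryResult:
    """Partition known and predicted interactions touching the queried genes.

    Gene names are resolved through the synonym table when given; inputs that
    resolve to nothing are reported as unresolved. Partition ``among`` holds
    interactions with both partners queried, ``beyond`` those with exactly one.
    """
    result = QueryResult()
    targets: set[str] = set()
    for raw in gene_list:
        raw = raw.strip()
        if not raw:
            continue
        if synonyms is not None:
            entry = synonyms.resolve(raw)
            if entry is None:
                result.unresolved.append(raw)
                continue
            result.resolved[raw] = entry.current_id
            targets.add(entry.current_id)
        else:
            result.resolved[raw] = raw
            targets.add(raw)

    def record(pair: tuple[str, str], origin: str) -> dict:
        b = scores.get(pair)
        return {
            "interactor_a": pair[0],
            "interactor_b": pair[1],
            "origin": origin,
            "intero_score": round(b.intero_score, 3) if b else None,
            "species_notation": b.notation if b else "",
            "evidence": sorted(
                interactome.get(pair).evidence_keys()
            ) if origin == "known" and interactome.get(pair) else [],
        }

    seen: set[tuple[str, str]] = set()
    for pair in sorted(interactome.pairs):
        hits = sum(1 for g in pair if g in targets)
        if hits == 0:
            continue
        seen.add(pair)
        (result.among if hits == 2 else result.beyond).append(record(pair, "known"))
    for pred in sorted(predictions, key=lambda p: p.pair):
        pair = pred.pair
        if pair in seen:
            continue
        hits = sum(1 for g in pair if g in targets)
        if hits == 0:
            continue
        (result.among if hits == 2 else result.beyond).append(record(pair, "predicted"))
    return result


def filter_high_confidence(
    scored: Mapping[tuple[str, str], ScoreBundle] | Iterable[ScoreBundle],
    cutoff: float = 1.5,
) -> tuple[list[ScoreBundle], float]:
    """Keep interactions with InteroScore >= cutoff; report the retained percentage.

    The default cutoff of 1.5 marks the high-confidence tier of predictions.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    bundles = (
        list(scored.values()) if isinstance(scored, Mapping) else list(scored)
    )
    kept = [b for b in bundles if b.intero_score >= cutoff]
    pct = 100.0 * len(kept) / len(bundles) if bundles else 0.0
    return kept, pct
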