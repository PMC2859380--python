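"""Confidence scores for known and predicted interactions.

The score family combines sequence conservation, cross-species support and
experimental evidence into one number per interaction:

* **OrthoScore** — per partner and per supporting species: relative percent
  identities of the contributing orthologues (scaled to the maximum), rounded,
  squared and summed. A single one-to-one orthologue scores exactly 1.
* **SingleSpeciesScore** — product of both partners' OrthoScores for one
  supporting species.
* **SpeciesScore** — sum of SingleSpeciesScores over supporting species, plus
  1.00 for the home species when the interaction is experimentally observed
  there. Never penalised for species with orthologues but no observed
  interaction.
* **ExperimentScore** — count of distinct (experiment type, evidence id)
  records across the interaction and all its supports.
* **ExperimentQualityScore** — sum, over distinct experiment types, of the
  fraction of that type's annotated interactions found in a reference edge
  set.
* **InteroScore** — SpeciesScore x ExperimentScore + ExperimentQualityScore.

The worked relative-identity example scales 92/87/72 to 1.0, 0.945 and 0.78
(score 2.501). Neither half-up rounding nor truncation at three decimals
reproduces both scaled values (72/92 = 0.78260 truncates to 0.782, giving
2.505); the one uniform rule that does is flooring the ratio to half-percent
granularity (multiples of 0.005), which is the default mode here. Plain
3-decimal truncation, half-up rounding and no rounding remain selectable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .interolog import InterologPrediction, InterologSupport, species_notation
from .orthology import OrthologyMap
from .ppi import EvidenceRecord, Interaction, Interactome, canonical_pair
from .species import SpeciesRegistry

ROUNDING_MODES = ("half_percent", "truncate3", "round3", "none")

DEFAULT_ROUNDING = "half_percent"


def _apply_rounding(ratio: float, mode: str) -> float:
    if mode == "half_percent":
        return math.floor(ratio * 200 + 1e-9) / 200
    if mode == "truncate3":
        return math.floor(ratio * 1000 + 1e-9) / 1000
    if mode == "round3":
        return math.floor(ratio * 1000 + 0.5) / 1000
    if mode == "none":
        return ratio
    raise ValueError(f"unknown rounding mode {mode!r}; use one of {ROUNDING_MODES}")


def ortho_score(identities: Sequence[float], rounding: str = DEFAULT_ROUNDING) -> float:
    """Sum of squared max-relative percent identities of contributing orthologues.

    Each identity is scaled to the maximum of the list, rounded per ``rounding``
    at three decimals, and squared. A one-element list returns exactly 1.0.
    """
    ids = list(identities)
    if not ids:
        raise ValueError("ortho_score is undefined without orthologues")
    m = max(ids)
    if m <= 0:
        raise ValueError("percent identities must be positive")
    for i in ids:
        if not 0 < i <= 100:
            raise ValueError(f"percent identity out of range (0, 100]: {i}")
    return sum(_apply_rounding(i / m, rounding) ** 2 for i in ids)


def single_species_score(ortho_a: float, ortho_b: float) -> float:
    """Product of both partners' OrthoScores for one supporting species."""
    return ortho_a * ortho_b


def species_score(
    single_scores: Iterable[float] | Mapping[str, float], home_known: bool = False
) -> float:
    """Sum of per-species SingleSpeciesScores, plus 1.00 if observed at home.

    ``single_scores`` may be a mapping (species -> score) or a plain iterable,
    one entry per supporting species.
    """
    values = (
        list(single_scores.values())
        if isinstance(single_scores, Mapping)
        else list(single_scores)
    )
    if not values and not home_known:
        raise ValueError("an unobserved interaction needs at least one supporting species")
    return sum(values) + (1.0 if home_known else 0.0)


def experiment_score(
    evidence: Iterable[EvidenceRecord], count_types: bool = False
) -> int:
    """Number of distinct non-redundant experiments supporting an interaction.

    Distinctness is by (experiment_type, evidence_id); ``count_types`` switches
    to counting distinct experiment types only.
    """
    if count_types:
        return len({e.experiment_type for e in evidence})
    return len({e.key for e in evidence})


@dataclass
class QualityRatioTable:
    """Per-experiment-type quality ratios q_e in [0, 1]; unknown types score 0."""

    ratios: dict[str, float] = field(default_factory=dict)
    annotated: dict[str, int] = field(default_factory=dict)
    in_reference: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for etype, q in self.ratios.items():
            if not 0.0 <= q <= 1.0:
                raise ValueError(f"quality ratio for {etype!r} out of [0,1]: {q}")

    def get(self, experiment_type: str) -> float:
        return self.ratios.get(experiment_type, 0.0)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "QualityRatioTable":
        df = pd.read_csv(path, sep="\t", dtype={"experiment_type": str})
        return cls(
            ratios=dict(zip(df["experiment_type"], df["ratio"].astype(float))),
            annotated=dict(zip(df["experiment_type"], df.get("annotated_count", 0))),
            in_reference=dict(zip(df["experiment_type"], df.get("reference_count", 0))),
        )

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            (
                e,
                int(self.annotated.get(e, 0)),
                int(self.in_reference.get(e, 0)),
                self.ratios[e],
            )
            for e in sorted(self.ratios)
        ]
        pd.DataFrame(
            rows,
            columns=["experiment_type", "annotated_count", "reference_count", "ratio"],
        ).to_csv(path, sep="\t", index=False)


def quality_ratios(
    interactome: Interactome, reference_edges: set[tuple[str, str]]
) -> QualityRatioTable:
    """Fraction of each experiment type's annotated interactions found in a reference set.

    For type e: q_e = |{interactions annotated by e} ∩ reference| /
    |{interactions annotated by e}|. Types annotating zero interactions are
    omitted.
    """
    reference = {canonical_pair(*p) for p in reference_edges}
    annotated: dict[str, set[tuple[str, str]]] = {}
    for ia in interactome:
        for etype in ia.experiment_types():
            annotated.setdefault(etype, set()).add(ia.pair)
    ratios, counts, hits = {}, {}, {}
    for etype, pairs in annotated.items():
        n_hit = len(pairs & reference)
        ratios[etype] = n_hit / len(pairs)
        counts[etype] = len(pairs)
        hits[etype] = n_hit
    return QualityRatioTable(ratios=ratios, annotated=counts, in_reference=hits)


def experiment_quality_score(
    evidence_types: Iterable[str], table: QualityRatioTable
) -> float:
    """Sum of quality ratios over *distinct* experiment types; unknown types add 0."""
    return sum(table.get(e) for e in set(evidence_types))


def intero_score(
    species_score_value: float,
    experiment_score_value: int,
    experiment_quality_score_value: float,
) -> float:
    """The unified confidence score: SpeciesScore x ExperimentScore + ExperimentQualityScore."""
    return species_score_value * experiment_score_value + experiment_quality_score_value


@dataclass
class ScoreBundle:
    """All score components for one interaction."""

    pair: tuple[str, str]
    species: str
    origin: str
    ortho_scores: dict[str, tuple[float, float]] = field(default_factory=dict)
    single_species_scores: dict[str, float] = field(default_factory=dict)
    species_score: float = 0.0
    experiment_score: int = 0
    experiment_quality_score: float = 0.0
    intero_score: float = 0.0
    notation: str = ""


def _support_orthoscores(
    supports: list[InterologSupport], rounding: str
) -> tuple[float, float]:
    """OrthoScores of both partners toward one source species.

    Contributing orthologues are only those participating in a supporting
    known interaction; identities are pooled per distinct orthologue and the
    maximum is taken among contributors.
    """
    ids_a: dict[str, float] = {}
    ids_b: dict[str, float] = {}
    for sup in supports:
        for rec in sup.ortho_a:
            ids_a[rec.target_gene] = rec.percent_identity
        for rec in sup.ortho_b:
            ids_b[rec.target_gene] = rec.percent_identity
    return (
        ortho_score(list(ids_a.values()), rounding),
        ortho_score(list(ids_b.values()), rounding),
    )


def _bundle(
    pair: tuple[str, str],
    species: str,
    origin: str,
    home_known: bool,
    own_evidence: Iterable[EvidenceRecord],
    supports: Mapping[str, list[InterologSupport]],
    table: QualityRatioTable | None,
    rounding: str,
    count_types: bool,
) -> ScoreBundle:
    bundle = ScoreBundle(pair=pair, species=species, origin=origin)
    pooled: set[EvidenceRecord] = set(own_evidence)
    seen_keys = {e.key for e in pooled}
    for src in sorted(supports):
        sups = supports[src]
        o_a, o_b = _support_orthoscores(sups, rounding)
        bundle.ortho_scores[src] = (o_a, o_b)
        bundle.single_species_scores[src] = single_species_score(o_a, o_b)
        for sup in sups:
            for rec in sup.known_interaction.evidence:
                if rec.key not in seen_keys:
                    pooled.add(rec)
                    seen_keys.add(rec.key)
    bundle.species_score = species_score(bundle.single_species_scores, home_known)
    bundle.experiment_score = experiment_score(pooled, count_types)
    if table is not None:
        bundle.experiment_quality_score = experiment_quality_score(
            {e.experiment_type for e in pooled}, table
        )
    bundle.intero_score = intero_score(
        bundle.species_score, bundle.experiment_score, bundle.experiment_quality_score
    )
    return bundle


def score_prediction(
    prediction: InterologPrediction,
    table: QualityRatioTable | None = None,
    rounding: str = DEFAULT_ROUNDING,
    count_types: bool = False,
) -> ScoreBundle:
    """Score a predicted interaction from its interolog supports.

    Evidence is pooled as the union of distinct (type, id) records over all
    supporting known interactions.
    """
    bundle = _bundle(
        pair=prediction.pair,
        species=prediction.species,
        origin="predicted",
        home_known=False,
        own_evidence=(),
        supports=prediction.supports,
        table=table,
        rounding=rounding,
        count_types=count_types,
    )
    bundle.notation = prediction.notation
    return bundle


def score_known(
    interaction: Interaction,
    known: Mapping[str, Interactome],
    ortho: OrthologyMap,
    table: QualityRatioTable | None = None,
    registry: SpeciesRegistry | None = None,
    rounding: str = DEFAULT_ROUNDING,
    count_types: bool = False,
) -> ScoreBundle:
    """Score a known interaction, including its observed interologs elsewhere.

    The home species contributes 1.00 to the SpeciesScore; every other species
    where an orthologue pair is also a known interaction contributes its
    SingleSpeciesScore, and that interolog's evidence joins the pooled
    evidence set.
    """
    a, b = interaction.pair
    supports: dict[str, list[InterologSupport]] = {}
    for t in sorted(known):
        if t == interaction.species:
            continue
        tome = known[t]
        for ra in ortho.orthologues_of(a, t):
            for rb in ortho.orthologues_of(b, t):
                if ra.target_gene == rb.target_gene:
                    continue
                observed = tome.get((ra.target_gene, rb.target_gene))
                if observed is None:
                    continue
                supports.setdefault(t, []).append(
                    InterologSupport(
                        source_species=t,
                        known_interaction=observed,
                        ortho_a=[ra],
                        ortho_b=[rb],
                    )
                )
    bundle = _bundle(
        pair=interaction.pair,
        species=interaction.species,
        origin="known",
        home_known=True,
        own_evidence=interaction.evidence,
        supports=supports,
        table=table,
        rounding=rounding,
        count_types=count_types,
    )
    if registry is not None:
        bundle.notation = species_notation(
            interaction.pair, interaction.species, known, ortho, registry,
            home_observed=True,
        )
    return bundle


def write_scores(bundles: Iterable[ScoreBundle], path: str | Path) -> None:
    """Score output TSV: pair, species, origin, the four scores, notation."""
    rows = [
        (
            b.pair[0],
            b.pair[1],
            b.species,
            b.origin,
            f"{b.species_score:.3f}",
            b.experiment_score,
            f"{b.experiment_quality_score:.3f}",
            f"{b.intero_score:.3f}",
            b.notation,
        )
        for b in sorted(bundles, key=lambda b: (b.species, b.pair))
    ]
    pd.DataFrame(
        rows,
        columns=[
            "interactor_a",
            "interactor_b",
            "species",
            "origin",
            "species_score",
            "experiment_score",
            "experiment_quality_score",
            "intero_score",
            "species_notation",
        ],
    ).to_csv(path, sep="\t", index=False)
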