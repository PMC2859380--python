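"""Interolog detection and prediction.

An interolog is an interaction conserved between species: both partners of a
known interacting pair have orthologues in another species that also
interact. Where orthologues exist for both partners in another species but no
interaction is known there, a new interaction is *predicted*. One-to-many and
many-to-many orthologies enumerate the full Cartesian product of candidate
target pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .orthology import OrthologyMap, OrthologyRecord
from .ppi import PREDICTED, Interaction, Interactome, canonical_pair
from .species import SpeciesRegistry


@dataclass
class InterologSupport:
    """One known interaction in a source species backing a target-species pair.

    ``ortho_a``/``ortho_b`` are the orthology records (from the perspective of
    the target-species partners) that link each partner to its counterpart in
    the supporting known interaction.
    """

    source_species: str
    known_interaction: Interaction
    ortho_a: list[OrthologyRecord] = field(default_factory=list)
    ortho_b: list[OrthologyRecord] = field(default_factory=list)


@dataclass
class InterologPrediction:
    interaction: Interaction
    supports: dict[str, list[InterologSupport]] = field(default_factory=dict)
    notation: str = ""

    @property
    def pair(self) -> tuple[str, str]:
        return self.interaction.pair

    @property
    def species(self) -> str:
        return self.interaction.species

    def support_species(self) -> list[str]:
        return sorted(self.supports)


def _perspective_record(
    ortho: OrthologyMap, target_gene: str, source_gene: str, source_species: str
) -> OrthologyRecord | None:
    """Record linking a target-species gene to its source-species orthologue.

    Prefers the reciprocal (target→source) record, whose percent identity is
    measured on the target protein; falls back to None if the map only holds
    the forward direction (the caller then reuses the forward record).
    """
    for rec in ortho.orthologues_of(target_gene, source_species):
        if rec.target_gene == source_gene:
            return rec
    return None


def find_conserved(
    known: Mapping[str, Interactome], ortho: OrthologyMap
) -> dict[tuple[str, str], set[tuple[str, str]]]:
    """Identify interologs conserved between every ordered pair of species.

    For species (s, t) the result holds all known pairs (A, B) in s for which
    some orthologue pair (A', B') is a known interaction in t. Bookkeeping is
    directional: (s, t) and (t, s) are reported separately.
    """
    out: dict[tuple[str, str], set[tuple[str, str]]] = {}
    species = sorted(known)
    for s in species:
        for t in species:
            if s == t:
                continue
            conserved: set[tuple[str, str]] = set()
            tome_t = known[t]
            for ia in known[s]:
                a, b = ia.pair
                orth_a = ortho.orthologues_of(a, t)
                orth_b = ortho.orthologues_of(b, t)
                found = False
                for ra in orth_a:
                    for rb in orth_b:
                        if ra.target_gene == rb.target_gene:
                            continue
                        if (ra.target_gene, rb.target_gene) in tome_t:
                            found = True
                            break
                    if found:
                        break
                if found:
                    conserved.add(ia.pair)
            out[(s, t)] = conserved
    return out


def predict_interologues(
    known: Mapping[str, Interactome],
    ortho: OrthologyMap,
    target: str,
    registry: SpeciesRegistry | None = None,
) -> list[InterologPrediction]:
    """Predict interactions in ``target`` from orthologous interacting pairs.

    Every candidate pair (A, B) in the target species such that (i) A and B
    are orthologues of a known interacting pair in at least one other species
    and (ii) (A, B) is not a known interaction in the target, is returned with
    its full support listing, one prediction per canonical pair. A prediction
    supported by several source species carries one support list per species.
    """
    if target not in known:
        raise KeyError(f"target species {target!r} has no known interactome loaded")
    target_known = known[target]
    predictions: dict[tuple[str, str], InterologPrediction] = {}

    for s in sorted(known):
        if s == target:
            continue
        for ia in known[s]:
            a_s, b_s = ia.pair
            cands_a = ortho.orthologues_of(a_s, target)
            cands_b = ortho.orthologues_of(b_s, target)
            for ra in cands_a:
                for rb in cands_b:
                    a_t, b_t = ra.target_gene, rb.target_gene
                    if a_t == b_t:
                        continue
                    pair = canonical_pair(a_t, b_t)
                    if pair in target_known:
                        continue
                    # orient support records to the canonical pair order
                    if (a_t, b_t) == pair:
                        first_gene, first_src = a_t, a_s
                        second_gene, second_src = b_t, b_s
                    else:
                        first_gene, first_src = b_t, b_s
                        second_gene, second_src = a_t, a_s
                    rec_a = _perspective_record(ortho, first_gene, first_src, s)
                    rec_b = _perspective_record(ortho, second_gene, second_src, s)
                    # fall back on the forward record if the reciprocal is absent
                    if rec_a is None:
                        rec_a = ra if (a_t, b_t) == pair else rb
                    if rec_b is None:
                        rec_b = rb if (a_t, b_t) == pair else ra
                    pred = predictions.get(pair)
                    if pred is None:
                        pred = InterologPrediction(
                            interaction=Interaction(
                                pair=pair, species=target, origin=PREDICTED
                            )
                        )
                        predictions[pair] = pred
                    pred.supports.setdefault(s, []).append(
                        InterologSupport(
                            source_species=s,
                            known_interaction=ia,
                            ortho_a=[rec_a],
                            ortho_b=[rec_b],
                        )
                    )

    result = [predictions[p] for p in sorted(predictions)]
    if registry is not None:
        for pred in result:
            pred.notation = species_notation(
                pred.pair, target, known, ortho, registry, home_observed=False
            )
    return result


def species_notation(
    pair: tuple[str, str],
    home_species: str,
    known: Mapping[str, Interactome],
    ortho: OrthologyMap,
    registry: SpeciesRegistry,
    home_observed: bool,
) -> str:
    """Genus-initial notation string for one interaction.

    One letter per registry species where both partners have orthologues (the
    home species is always included): uppercase if an interaction between
    orthologues is observed there, lowercase otherwise. Species lacking
    orthologues for either partner are omitted. Letter order follows the
    registry order.
    """
    a, b = canonical_pair(*pair)
    letters: list[str] = []
    for sp in registry:
        code, letter = sp.code, sp.genus_letter
        if code == home_species:
            letters.append(letter if home_observed else letter.lower())
            continue
        orth_a = ortho.orthologues_of(a, code)
        orth_b = ortho.orthologues_of(b, code)
        if not orth_a or not orth_b:
            continue
        observed = False
        tome = known.get(code)
        if tome is not None:
            for ra in orth_a:
                for rb in orth_b:
                    if ra.target_gene == rb.target_gene:
                        continue
                    if (ra.target_gene, rb.target_gene) in tome:
                        observed = True
                        break
                if observed:
                    break
        letters.append(letter if observed else letter.lower())
    return "".join(letters)
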