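"""Seeded multi-species fixture generation with planted ground truth.

The generator emits every input dialect the pipeline consumes — orthology
tables, per-database PPI files, synonym tables, a reference edge set and a
gene-list file — for a configurable set of toy species, together with a
ground-truth record of what was planted: conserved interologs, predictable
pairs per target species, per-database overlap bookkeeping and per-experiment
quality ratios. Generation is a pure function of the spec (same seed gives
byte-identical files).

Orthologous genes are organised into *families*: a family holds one or more
genes per member species, and every cross-species gene pair within a family
is an orthology record. Background known edges are drawn only among
species-unique genes (genes in no family), so planted interologs are the only
source of cross-species support and planted-truth recovery is exact.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import networkx as nx
import pandas as pd

from .ppi import canonical_pair
from .species import SpeciesRegistry, default_registry

DEFAULT_EVIDENCE_TYPES = {
    "MI:0019(coimmunoprecipitation)": 0.2,
    "MI:0398(two_hybrid_pooling)": 0.7,
    "MI:0114(x-ray_crystallography)": 0.5,
}


@dataclass
class FixtureSpec:
    """Parameters of one synthetic multi-species fixture.

    Defaults give a five-species fixture loosely shaped like real data: a
    conserved core shared by all species (largest between the two mammal-like
    species first in the registry), partially conserved families, the rest
    species-unique; three partially overlapping databases; a small alphabet
    of experiment types with planted quality ratios.
    """

    species_codes: tuple[str, ...] = ("hsap", "mmus", "dmel", "cele", "scer")
    genes_per_species: int = 100
    frac_conserved_all: float = 0.25
    frac_conserved_some: float = 0.25
    ortho_type_mix: tuple[float, float, float] = (0.7, 0.2, 0.1)
    identity_range: tuple[float, float] = (40.0, 99.0)
    known_edges_per_species: int = 25
    n_planted_conserved: int = 5
    n_planted_predictable: int = 5
    n_databases: int = 3
    db_overlap: dict[int, float] = field(default_factory=lambda: {2: 0.2, 3: 0.1})
    evidence_types: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EVIDENCE_TYPES)
    )
    evidence_per_interaction: tuple[int, int] = (1, 3)
    synonym_fraction: float = 0.2
    novel_fraction: float = 0.1
    n_modules: int = 0
    module_size: int = 8
    module_p_within: float = 0.6
    seed: int = 0

    def validate(self) -> None:
        for name, frac in (
            ("frac_conserved_all", self.frac_conserved_all),
            ("frac_conserved_some", self.frac_conserved_some),
            ("synonym_fraction", self.synonym_fraction),
            ("novel_fraction", self.novel_fraction),
            ("module_p_within", self.module_p_within),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {frac}")
        if self.frac_conserved_all + self.frac_conserved_some > 0.8:
            raise ValueError("conserved fractions leave too few unique genes")
        if len(self.species_codes) < 2:
            raise ValueError("need at least two species")
        if self.genes_per_species < 4:
            raise ValueError("need at least four genes per species")
        if sum(self.db_overlap.values()) > 1.0:
            raise ValueError("database overlap fractions exceed 1")
        for k in self.db_overlap:
            if not 2 <= k <= self.n_databases:
                raise ValueError(f"overlap class {k} incompatible with {self.n_databases} databases")
        if any(q < 0 or q > 1 for q in self.evidence_types.values()):
            raise ValueError("planted quality ratios must lie in [0, 1]")
        lo, hi = self.identity_range
        if not (0 < lo <= hi <= 100):
            raise ValueError("identity range must satisfy 0 < lo <= hi <= 100")
        n_unique = self.genes_per_species - int(
            (self.frac_conserved_all + self.frac_conserved_some) * self.genes_per_species
        )
        if self.n_modules * self.module_size > n_unique:
            raise ValueError("planted modules larger than the unique-gene pool")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FixtureSpec":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "species_codes" in data:
            data["species_codes"] = tuple(data["species_codes"])
        if "ortho_type_mix" in data:
            data["ortho_type_mix"] = tuple(data["ortho_type_mix"])
        if "identity_range" in data:
            data["identity_range"] = tuple(data["identity_range"])
        if "evidence_per_interaction" in data:
            data["evidence_per_interaction"] = tuple(data["evidence_per_interaction"])
        if "db_overlap" in data:
            data["db_overlap"] = {int(k): float(v) for k, v in data["db_overlap"].items()}
        return cls(**data)


@dataclass
class GroundTruth:
    """What the generator planted, keyed the way the pipeline reports results."""

    species: list[str]
    conserved: dict[str, list[list[str]]]        # "s->t" -> pairs in s conserved in t
    predictable: dict[str, list[list[str]]]      # target species -> canonical pairs
    known_counts: dict[str, int]
    db_overlap: dict[str, dict]                  # species -> overlap bookkeeping
    quality_ratios: dict                         # {"species", "ratios", "annotated"}
    n_orthology_records: int
    module_genes: list[str]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class _Family:
    """One orthologous gene family: genes per member species."""

    genes: dict[str, list[str]]

    def members(self) -> list[str]:
        return sorted(self.genes)


def _build_families(spec: FixtureSpec, rng: random.Random) -> tuple[
    list[_Family], dict[str, list[str]], dict[str, list[str]]
]:
    """Allocate genes into families and a species-unique pool.

    Returns (families, all genes per species, unique genes per species).
    """
    codes = list(spec.species_codes)
    counters = {c: 0 for c in codes}
    all_genes: dict[str, list[str]] = {c: [] for c in codes}

    def new_gene(code: str) -> str:
        counters[code] += 1
        g = f"{code.upper()}{counters[code]:04d}"
        all_genes[code].append(g)
        return g

    n_all = int(spec.frac_conserved_all * spec.genes_per_species)
    n_some = int(spec.frac_conserved_some * spec.genes_per_species)
    one2one_w, one2many_w, many2many_w = spec.ortho_type_mix
    families: list[_Family] = []
    for i in range(n_all + n_some):
        if i < n_all:
            members = codes
        else:
            k = rng.randint(2, max(2, len(codes) - 1))
            members = sorted(rng.sample(codes, k))
        u = rng.random() * (one2one_w + one2many_w + many2many_w)
        if u < one2one_w or len(members) < 2:
            multi: list[str] = []
        elif u < one2one_w + one2many_w:
            multi = [rng.choice(members)]
        else:
            multi = rng.sample(members, 2)
        genes = {}
        for code in members:
            n = rng.randint(2, 3) if code in multi else 1
            if counters[code] + n > spec.genes_per_species:
                n = 1
            if counters[code] + n > spec.genes_per_species:
                continue
            genes[code] = [new_gene(code) for _ in range(n)]
        if len(genes) >= 2:
            families.append(_Family(genes=genes))

    unique: dict[str, list[str]] = {}
    for code in codes:
        while counters[code] < spec.genes_per_species:
            new_gene(code)
        fam_genes = {g for f in families for g in f.genes.get(code, [])}
        unique[code] = [g for g in all_genes[code] if g not in fam_genes]
    return families, all_genes, unique


def _orthology_rows(
    families: list[_Family], spec: FixtureSpec, rng: random.Random
) -> list[tuple]:
    lo, hi = spec.identity_range
    rows = []
    for fam in families:
        members = fam.members()
        for i, s in enumerate(members):
            for t in members[i + 1:]:
                n_s, n_t = len(fam.genes[s]), len(fam.genes[t])
                if n_s == 1 and n_t == 1:
                    htype = "one2one"
                elif n_s == 1 or n_t == 1:
                    htype = "one2many"
                else:
                    htype = "many2many"
                for gs in fam.genes[s]:
                    for gt in fam.genes[t]:
                        ident = round(rng.uniform(lo, hi), 2)
                        rows.append((gs, s, gt, t, htype, ident))
                        rows.append((gt, t, gs, s, htype, ident))
    rows.sort()
    return rows


def generate(spec: FixtureSpec, outdir: str | Path) -> GroundTruth:
    """Emit a complete fixture directory and return its ground truth.

    Files written: ``registry.yaml``, ``orthology.tsv``, ``synonyms.tsv``,
    one ``<db>.tsv`` per database, ``reference_edges.tsv``, ``genelist.txt``
    and ``groundtruth.json``.
    """
    spec.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(spec.seed)
    codes = list(spec.species_codes)
    registry = _make_registry(codes)
    registry.to_yaml(outdir / "registry.yaml")

    families, all_genes, unique = _build_families(spec, rng)
    ortho_rows = _orthology_rows(families, spec, rng)
    pd.DataFrame(
        ortho_rows,
        columns=[
            "source_gene", "source_species", "target_gene", "target_species",
            "homology_type", "percent_identity",
        ],
    ).to_csv(outdir / "orthology.tsv", sep="\t", index=False)

    # --- known interactions -------------------------------------------------
    known_edges: dict[str, set[tuple[str, str]]] = {c: set() for c in codes}
    module_genes: list[str] = []
    for code in codes:
        pool = unique[code]
        # planted modules first (dense within-module wiring)
        offset = 0
        for _ in range(spec.n_modules):
            module = pool[offset: offset + spec.module_size]
            offset += spec.module_size
            if code == codes[0]:
                module_genes.extend(module)
            for i, a in enumerate(module):
                for b in module[i + 1:]:
                    if rng.random() < spec.module_p_within:
                        known_edges[code].add(canonical_pair(a, b))
        # background edges among unique genes
        attempts = 0
        n_module_edges = len(known_edges[code])
        while (
            len(known_edges[code]) < n_module_edges + spec.known_edges_per_species
            and attempts < 50 * spec.known_edges_per_species
            and len(pool) >= 2
        ):
            attempts += 1
            a, b = rng.sample(pool, 2)
            known_edges[code].add(canonical_pair(a, b))

    # --- planted interologs ---------------------------------------------------
    fam_all = [f for f in families if len(f.genes) == len(codes)]
    rng.shuffle(fam_all)
    needed = 2 * (spec.n_planted_conserved + spec.n_planted_predictable)
    if len(fam_all) < needed:
        raise ValueError(
            f"not enough all-species families ({len(fam_all)}) for the requested "
            f"plantings ({needed} needed); raise genes_per_species or frac_conserved_all"
        )
    plantings: list[tuple[_Family, _Family, list[str]]] = []
    idx = 0
    for _ in range(spec.n_planted_conserved):
        fa, fb = fam_all[idx], fam_all[idx + 1]
        idx += 2
        planted_in = sorted(rng.sample(codes, 2))
        plantings.append((fa, fb, planted_in))
    for _ in range(spec.n_planted_predictable):
        fa, fb = fam_all[idx], fam_all[idx + 1]
        idx += 2
        plantings.append((fa, fb, [rng.choice(codes)]))
    for fa, fb, planted_in in plantings:
        for code in planted_in:
            known_edges[code].add(
                canonical_pair(fa.genes[code][0], fb.genes[code][0])
            )

    # --- ground truth: conserved + predictable --------------------------------
    conserved: dict[str, set[tuple[str, str]]] = {}
    predictable: dict[str, set[tuple[str, str]]] = {c: set() for c in codes}
    for fa, fb, planted_in in plantings:
        for s in planted_in:
            for t in planted_in:
                if s != t:
                    conserved.setdefault(f"{s}->{t}", set()).add(
                        canonical_pair(fa.genes[s][0], fb.genes[s][0])
                    )
        for u in codes:
            if u not in fa.genes or u not in fb.genes:
                continue
            if not any(v != u for v in planted_in):
                continue
            cands = {
                canonical_pair(ga, gb)
                for ga in fa.genes[u]
                for gb in fb.genes[u]
                if ga != gb
            }
            predictable[u] |= cands - known_edges[u]

    # --- evidence + database assignment ---------------------------------------
    etypes = sorted(spec.evidence_types)
    ev_counter = 0
    lo_ev, hi_ev = spec.evidence_per_interaction
    interactions: dict[str, dict[tuple[str, str], list[tuple[str, str]]]] = {}
    for code in codes:
        interactions[code] = {}
        for pair in sorted(known_edges[code]):
            n_ev = rng.randint(lo_ev, hi_ev)
            evs = []
            for _ in range(n_ev):
                ev_counter += 1
                evs.append((rng.choice(etypes), f"EXP{ev_counter:05d}"))
            interactions[code][pair] = evs

    db_names = ["intact", "dip", "bind"][: spec.n_databases] + [
        f"db{i}" for i in range(4, spec.n_databases + 1)
    ]
    assignment: dict[str, dict[tuple[str, str], list[str]]] = {}
    overlap_truth: dict[str, dict] = {}
    for code in codes:
        assignment[code] = {}
        per_db: dict[str, set[tuple[str, str]]] = {d: set() for d in db_names}
        for pair in sorted(interactions[code]):
            u = rng.random()
            acc = 0.0
            n_db = 1
            for k in sorted(spec.db_overlap, reverse=True):
                acc += spec.db_overlap[k]
                if u < acc:
                    n_db = k
                    break
            dbs = sorted(rng.sample(db_names, n_db))
            assignment[code][pair] = dbs
            for d in dbs:
                per_db[d].add(pair)
        union = set().union(*per_db.values()) if per_db else set()
        overlap_truth[code] = {
            "per_db": {d: len(per_db[d]) for d in db_names},
            "pairwise": {
                f"{d1}&{d2}": len(per_db[d1] & per_db[d2])
                for i, d1 in enumerate(db_names)
                for d2 in db_names[i + 1:]
            },
            "all": len(set.intersection(*per_db.values())) if per_db else 0,
            "union": len(union),
        }

    # --- write PPI files -------------------------------------------------------
    synonym_rows, syn_lookup = _synonym_rows(spec, all_genes, rng)
    pd.DataFrame(
        synonym_rows, columns=["external_id", "current_id", "species", "status"]
    ).to_csv(outdir / "synonyms.tsv", sep="\t", index=False)

    taxids = {s.code: s.taxid for s in registry}
    db_rows: dict[str, list[tuple]] = {d: [] for d in db_names}
    for code in codes:
        for pair in sorted(interactions[code]):
            for db in assignment[code][pair]:
                for etype, evid in interactions[code][pair]:
                    a = _maybe_alias(pair[0], spec, rng)
                    b = _maybe_alias(pair[1], spec, rng)
                    db_rows[db].append(
                        (a, b, taxids[code], taxids[code], etype, evid, db)
                    )
    for db in db_names:
        pd.DataFrame(
            db_rows[db],
            columns=[
                "interactor_a", "interactor_b", "taxid_a", "taxid_b",
                "experiment_type", "evidence_id", "source_db",
            ],
        ).to_csv(outdir / f"{db}.tsv", sep="\t", index=False)

    # --- reference edge set + quality ratios (first species) -------------------
    ref_species = codes[0]
    annotated: dict[str, set[tuple[str, str]]] = {}
    for pair, evs in interactions[ref_species].items():
        for etype, _ in evs:
            annotated.setdefault(etype, set()).add(pair)
    reference: set[tuple[str, str]] = set()
    for etype in etypes:
        ann = annotated.get(etype, set())
        if not ann:
            continue
        target = round(spec.evidence_types[etype] * len(ann))
        current = len(ann & reference)
        if current < target:
            # prefer pairs annotated only by this type to limit cross-type coupling
            exclusive = sorted(
                p for p in ann - reference
                if all(p not in annotated[o] for o in annotated if o != etype)
            )
            shared = sorted(p for p in ann - reference if p not in set(exclusive))
            for p in exclusive + shared:
                if current >= target:
                    break
                reference.add(p)
                current += 1
    achieved = {
        etype: len(ann & reference) / len(ann)
        for etype, ann in sorted(annotated.items())
        if ann
    }
    pd.DataFrame(
        sorted(reference), columns=["interactor_a", "interactor_b"]
    ).to_csv(outdir / "reference_edges.tsv", sep="\t", index=False)

    # --- gene list --------------------------------------------------------------
    if module_genes:
        genelist = sorted(module_genes)
    else:
        genelist = sorted(rng.sample(all_genes[ref_species], min(10, len(all_genes[ref_species]))))
    (outdir / "genelist.txt").write_text("\n".join(genelist) + "\n")

    truth = GroundTruth(
        species=codes,
        conserved={k: sorted(map(list, v)) for k, v in sorted(conserved.items())},
        predictable={c: sorted(map(list, predictable[c])) for c in codes},
        known_counts={c: len(known_edges[c]) for c in codes},
        db_overlap=overlap_truth,
        quality_ratios={
            "species": ref_species,
            "ratios": achieved,
            "annotated": {e: len(annotated[e]) for e in sorted(annotated)},
        },
        n_orthology_records=len(ortho_rows),
        module_genes=sorted(module_genes),
    )
    truth.to_json(outdir / "groundtruth.json")
    return truth


def _make_registry(codes: Sequence[str]) -> SpeciesRegistry:
    base = {s.code: s for s in default_registry()}
    if all(c in base for c in codes):
        from .species import SpeciesId

        return SpeciesRegistry([base[c] for c in codes])
    from .species import SpeciesId

    letters = [chr(ord("A") + i) for i in range(len(codes))]
    return SpeciesRegistry(
        SpeciesId(code=c, genus_letter=letters[i], name=c, taxid=9000 + i)
        for i, c in enumerate(codes)
    )


def _synonym_rows(
    spec: FixtureSpec, all_genes: dict[str, list[str]], rng: random.Random
) -> tuple[list[tuple], dict[str, str]]:
    rows = []
    lookup = {}
    for code in sorted(all_genes):
        for g in all_genes[code]:
            status = "novel" if rng.random() < spec.novel_fraction else "known"
            rows.append((g, g, code, status))
            rows.append((f"syn_{g}", g, code, status))
            rows.append((f"old_{g}", g, code, "retired"))
            lookup[g] = g
    rows.sort()
    return rows, lookup


def _maybe_alias(gene: str, spec: FixtureSpec, rng: random.Random) -> str:
    u = rng.random()
    if u < spec.synonym_fraction / 2:
        return f"syn_{gene}"
    if u < spec.synonym_fraction:
        return f"old_{gene}"
    return gene


def generate_scale_free(n: int, exponent: float, seed: int) -> nx.Graph:
    """Configuration-model graph with a power-law degree sequence, simplified.

    Degrees are drawn from p(k) proportional to k^-exponent on 1..~2*sqrt(n);
    self-loops and multi-edges are removed after pairing.
    """
    if n < 10:
        raise ValueError("need n >= 10")
    rng = random.Random(seed)
    k_max = max(3, int(2 * n**0.5))
    ks = list(range(1, k_max + 1))
    weights = [k ** -exponent for k in ks]
    seq = rng.choices(ks, weights=weights, k=n)
    if sum(seq) % 2:
        seq[0] += 1
    g = nx.configuration_model(seq, seed=rng.randrange(2**31))
    g = nx.Graph(g)
    g.remove_edges_from(nx.selfloop_edges(g))
    return g


def generate_modular_known_predicted(
    n_nodes: int,
    n_modules: int,
    p_within_known: float,
    p_within_predicted: float,
    p_between: float,
    seed: int,
) -> tuple[nx.Graph, nx.Graph]:
    """Modular 'known' network plus within-module 'predicted' edges.

    Nodes are split evenly into modules. Known edges appear within a module
    with probability ``p_within_known`` and between modules with
    ``p_between``; predicted edges are drawn from the remaining within-module
    non-edges with probability ``p_within_predicted``. Emulates the structure
    where interolog prediction densifies existing complexes.
    """
    rng = random.Random(seed)
    nodes = [f"n{i:05d}" for i in range(n_nodes)]
    module_of = {v: i * n_modules // n_nodes for i, v in enumerate(nodes)}
    g_known = nx.Graph()
    g_known.add_nodes_from(nodes)
    g_pred = nx.Graph()
    g_pred.add_nodes_from(nodes)
    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            if module_of[a] == module_of[b]:
                u = rng.random()
                if u < p_within_known:
                    g_known.add_edge(a, b)
                elif u < p_within_known + p_within_predicted:
                    g_pred.add_edge(a, b)
            elif rng.random() < p_between:
                g_known.add_edge(a, b)
    return g_known, g_pred
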