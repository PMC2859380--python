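import random

import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")

import interoscore as ic
from interoscore.ppi import EvidenceRecord, Interaction, Interactome


@pytest.fixture(scope="session")
def registry():
    return ic.default_registry()


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """A complete five-species synthetic fixture directory (seed 1)."""
    d = tmp_path_factory.mktemp("fixture")
    truth = ic.generate(ic.FixtureSpec(seed=1), d)
    return d, truth


@pytest.fixture(scope="session")
def pipeline(fixture_dir):
    """Fixture files loaded through the real readers: ortho, synonyms, interactomes."""
    d, truth = fixture_dir
    reg = ic.SpeciesRegistry.from_yaml(d / "registry.yaml")
    ortho = ic.load_orthology(d / "orthology.tsv", reg)
    synonyms = ic.load_synonyms(d / "synonyms.tsv")
    known = {}
    row_sets_by_species = {}
    for code in truth.species:
        row_sets = []
        for db in ("intact", "dip", "bind"):
            raw = ic.load_ppi(d / f"{db}.tsv", db, reg[code])
            rows, _ = ic.normalize_identifiers(raw, synonyms, code)
            row_sets.append(rows)
        known[code] = ic.merge_interactomes(row_sets, code)
        row_sets_by_species[code] = row_sets
    return {
        "dir": d,
        "truth": truth,
        "registry": reg,
        "ortho": ortho,
        "synonyms": synonyms,
        "known": known,
        "row_sets": row_sets_by_species,
    }


def make_interactome(code, pairs, etype="MI:0018(two hybrid)"):
    """In-memory interactome with one distinct evidence record per pair."""
    tome = Interactome(code)
    for i, (a, b) in enumerate(pairs):
        tome.add(
            Interaction(
                pair=(a, b),
                species=code,
                evidence={EvidenceRecord(etype, f"E-{code}-{i}", "intact")},
            )
        )
    return tome


def make_ortholog_records(entries):
    """Symmetric orthology records from (gene1, sp1, gene2, sp2, type, identity)."""
    recs = []
    for g1, s1, g2, s2, htype, pid in entries:
        recs.append(ic.OrthologyRecord(g1, s1, g2, s2, htype, pid))
        recs.append(ic.OrthologyRecord(g2, s2, g1, s1, htype, pid))
    return ic.OrthologyMap(recs)


def random_simple_graph(n_nodes, n_edges, seed):
    import networkx as nx

    rng = random.Random(seed)
    nodes = [f"v{i}" for i in range(n_nodes)]
    g = nx.Graph()
    g.add_nodes_from(nodes)
    max_edges = n_nodes * (n_nodes - 1) // 2
    m = min(n_edges, max_edges)
    while g.number_of_edges() < m:
        a, b = rng.sample(nodes, 2)
        g.add_edge(a, b)
    return g
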