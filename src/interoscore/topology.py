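"""Network topology metrics, null models, and statistical comparisons.

Interactomes are treated as simple undirected graphs (self-interactions are
excluded from metric computation). The module provides the small-world
diagnostics used to validate combined known+predicted interactomes: power-law
degree-distribution fits, diameter, global clustering (transitivity),
global efficiency over optional node subsets, degree-preserving rewiring null
models, and node-set efficiency Z-scores against random same-size node sets.
"""

from __future__ import annotations

import logging
import math
import random
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .ppi import Interactome, canonical_pair

logger = logging.getLogger(__name__)


def build_graph(
    edges: Iterable[tuple[str, str]] | Interactome,
    nodes: Iterable[str] | None = None,
) -> nx.Graph:
    """Simple graph from an edge iterable or an Interactome (self-loops dropped)."""
    g = nx.Graph()
    if isinstance(edges, Interactome):
        edge_iter = (ia.pair for ia in edges)
    else:
        edge_iter = iter(edges)
    for a, b in edge_iter:
        if a == b:
            continue
        g.add_edge(*canonical_pair(a, b))
    if nodes is not None:
        g.add_nodes_from(nodes)
    return g


def degree_distribution(g: nx.Graph) -> dict[int, float]:
    """Empirical degree probability p(k) over observed degrees; sums to 1."""
    if g.number_of_nodes() == 0:
        raise ValueError("degree distribution of an empty graph is undefined")
    counts: dict[int, int] = {}
    for _, k in g.degree():
        counts[k] = counts.get(k, 0) + 1
    n = g.number_of_nodes()
    return {k: c / n for k, c in sorted(counts.items())}


@dataclass
class DegreeDistributionFit:
    """Power-law fit p(k) = c * k^-r by least squares in log-log space."""

    exponent: float
    prefactor: float
    r_squared: float
    k_min: int
    k_max: int
    method: str = "ols-loglog"


def fit_power_law(
    distribution: dict[int, float], min_probability: float = 0.0
) -> DegreeDistributionFit:
    """Fit p(k) = c k^-r on (log k, log p) over unbinned observed degrees k >= 1.

    Degrees with zero probability are excluded; at least three distinct
    positive degrees are required. ``min_probability`` restricts the fit
    domain to well-populated degrees (e.g. 10/n), which suppresses the flat
    band of singleton-occupancy degrees in the tail that otherwise biases the
    slope of the least-squares line toward zero.
    """
    pts = [(k, p) for k, p in distribution.items() if k >= 1 and p > 0 and p >= min_probability]
    if len(pts) < 3:
        raise ValueError("power-law fit needs >= 3 distinct degrees with k >= 1")
    logk = np.log([k for k, _ in pts])
    logp = np.log([p for _, p in pts])
    res = stats.linregress(logk, logp)
    return DegreeDistributionFit(
        exponent=-res.slope,
        prefactor=math.exp(res.intercept),
        r_squared=res.rvalue**2,
        k_min=min(k for k, _ in pts),
        k_max=max(k for k, _ in pts),
    )


def diameter(g: nx.Graph) -> int:
    """Maximum shortest-path length, computed on the largest connected component."""
    if g.number_of_edges() == 0:
        raise ValueError("diameter of an edgeless graph is undefined")
    comp = max(nx.connected_components(g), key=len)
    return nx.diameter(g.subgraph(comp))


def clustering_coefficient(g: nx.Graph) -> float:
    """Global transitivity c = 3 * triangles / connected triples; 0 if no triples."""
    c = nx.transitivity(g)
    if c == 0 and g.number_of_edges() > 0:
        logger.debug("graph has no triangles (or no connected triples)")
    return c


def global_efficiency(g: nx.Graph, node_set: Sequence[str] | None = None) -> float:
    """Mean reciprocal shortest-path distance over unordered node pairs.

    Distances are always computed in the FULL network, even when scoring a
    node subset; disconnected pairs contribute 0. Result lies in [0, 1].
    """
    nodes = sorted(g.nodes) if node_set is None else sorted(set(node_set))
    missing = [u for u in nodes if u not in g]
    if missing:
        raise ValueError(f"node(s) not in network: {missing[:5]}")
    if len(nodes) < 2:
        raise ValueError("global efficiency needs at least two nodes")
    node_pos = {u: i for i, u in enumerate(nodes)}
    total = 0.0
    for i, u in enumerate(nodes):
        dist = nx.single_source_shortest_path_length(g, u)
        for v, d in dist.items():
            j = node_pos.get(v)
            if j is not None and j > i and d > 0:
                total += 1.0 / d
    n = len(nodes)
    return total / (n * (n - 1) / 2)


def _double_edge_swap(
    edges: set[tuple[str, str]],
    rng: random.Random,
    n_swaps: int,
    forbidden: set[tuple[str, str]] | None = None,
    max_tries_factor: int = 100,
) -> tuple[set[tuple[str, str]], int]:
    """Degree-preserving double edge swaps avoiding duplicates, self-loops and
    any edge in ``forbidden``. Returns (edges, achieved swap count)."""
    edge_list = list(edges)
    edge_set = set(edges)
    forbidden = forbidden or set()
    achieved = 0
    tries = 0
    max_tries = max(1, max_tries_factor * n_swaps)
    m = len(edge_list)
    if m < 2:
        return edge_set, 0
    while achieved < n_swaps and tries < max_tries:
        tries += 1
        i = rng.randrange(m)
        j = rng.randrange(m)
        if i == j:
            continue
        a, b = edge_list[i]
        c, d = edge_list[j]
        # swap to (a,d), (c,b)
        if len({a, b, c, d}) < 4:
            continue
        e1 = canonical_pair(a, d)
        e2 = canonical_pair(c, b)
        if e1 in edge_set or e2 in edge_set or e1 in forbidden or e2 in forbidden:
            continue
        edge_set.discard(canonical_pair(a, b))
        edge_set.discard(canonical_pair(c, d))
        edge_set.add(e1)
        edge_set.add(e2)
        edge_list[i] = e1
        edge_list[j] = e2
        achieved += 1
    if achieved < n_swaps:
        logger.info("rewiring achieved %d of %d requested swaps", achieved, n_swaps)
    return edge_set, achieved


def rewire_full(g: nx.Graph, seed: int, n_swaps: int | None = None) -> nx.Graph:
    """Degree-preserving randomisation of the whole network by double edge swaps.

    The degree sequence is exactly preserved; no duplicate edges or self-loops
    are introduced. Deterministic under a fixed seed. Default swap budget is
    10x the edge count; if the budget cannot be met the best effort is
    returned with the achieved count logged.
    """
    if g.number_of_edges() < 2:
        raise ValueError("rewiring needs at least two edges")
    rng = random.Random(seed)
    if n_swaps is None:
        n_swaps = 10 * g.number_of_edges()
    edges = {canonical_pair(a, b) for a, b in g.edges}
    new_edges, _ = _double_edge_swap(edges, rng, n_swaps)
    out = nx.Graph()
    out.add_nodes_from(g.nodes)
    out.add_edges_from(new_edges)
    return out


def rewire_partial(
    g_known: nx.Graph, g_predicted: nx.Graph, seed: int, n_swaps: int | None = None
) -> nx.Graph:
    """Rewire only the predicted edges, keep known edges untouched, return the union.

    Predicted edges are degree-preservingly swapped among themselves; swaps
    that would collide with a known edge are re-drawn. With zero predicted
    edges this is the identity on the known network.
    """
    known_edges = {canonical_pair(a, b) for a, b in g_known.edges}
    pred_edges = {canonical_pair(a, b) for a, b in g_predicted.edges} - known_edges
    out = nx.Graph()
    out.add_nodes_from(g_known.nodes)
    out.add_nodes_from(g_predicted.nodes)
    if not pred_edges:
        out.add_edges_from(known_edges)
        return out
    rng = random.Random(seed)
    if n_swaps is None:
        n_swaps = 10 * len(pred_edges)
    new_pred, _ = _double_edge_swap(pred_edges, rng, n_swaps, forbidden=known_edges)
    out.add_edges_from(known_edges)
    out.add_edges_from((a, b, {"origin": "predicted"}) for a, b in new_pred)
    return out


def randomize_same_nodes(g: nx.Graph, seed: int) -> nx.Graph:
    """Uniform random graph on the same node set with the same edge count."""
    rng = random.Random(seed)
    nodes = sorted(g.nodes)
    m = g.number_of_edges()
    max_edges = len(nodes) * (len(nodes) - 1) // 2
    if m > max_edges:
        raise ValueError("more edges requested than simple-graph capacity")
    edges: set[tuple[str, str]] = set()
    while len(edges) < m:
        a, b = rng.sample(nodes, 2)
        edges.add(canonical_pair(a, b))
    out = nx.Graph()
    out.add_nodes_from(nodes)
    out.add_edges_from(edges)
    return out


@dataclass
class EfficiencyZScore:
    observed: float
    z: float
    p_normal: float
    p_empirical: float
    mean_null: float
    sd_null: float
    n_samples: int
    degenerate: bool = False


def node_set_efficiency_zscore(
    g: nx.Graph,
    node_set: Sequence[str],
    n_samples: int = 1000,
    seed: int = 0,
    two_sided: bool = False,
) -> EfficiencyZScore:
    """Z-score of a node set's global efficiency against random same-size sets.

    Samples ``n_samples`` uniform node subsets of equal size from the network
    and compares the observed subset efficiency with the null distribution.
    The normal-tail p is one-sided (upper) by default; an empirical p
    ((1 + #null >= obs) / (n + 1)) is always reported. If the null has zero
    spread, z is 0 when the observation equals the null value and flagged
    degenerate otherwise.
    """
    nodes = sorted(g.nodes)
    subset = sorted(set(node_set))
    if len(subset) > len(nodes):
        raise ValueError("node set larger than the network")
    obs = global_efficiency(g, subset)
    k = len(subset)
    if k == len(nodes):
        # every sample is the whole network: the null is a point mass at obs
        return EfficiencyZScore(
            observed=obs, z=0.0, p_normal=1.0, p_empirical=1.0,
            mean_null=obs, sd_null=0.0, n_samples=n_samples,
        )
    rng = random.Random(seed)
    null = np.empty(n_samples)
    for i in range(n_samples):
        sample = rng.sample(nodes, k)
        null[i] = global_efficiency(g, sample)
    mean, sd = float(null.mean()), float(null.std(ddof=1))
    if sd <= 1e-12 * max(1.0, abs(mean)):
        degenerate = abs(obs - mean) > 1e-9
        z = 0.0 if not degenerate else float("nan")
        p_norm = 1.0 if not degenerate else float("nan")
    else:
        degenerate = False
        z = (obs - mean) / sd
        p_norm = float(stats.norm.sf(abs(z)) * 2 if two_sided else stats.norm.sf(z))
    p_emp = (1 + int((null >= obs).sum())) / (n_samples + 1)
    return EfficiencyZScore(
        observed=obs,
        z=z,
        p_normal=p_norm,
        p_empirical=p_emp,
        mean_null=mean,
        sd_null=sd,
        n_samples=n_samples,
        degenerate=degenerate,
    )


def proportion_test(
    successes: int, n: int, genome_proportion: float
) -> tuple[float, float]:
    """One-sample two-tailed test for a proportion against a genome-wide value.

    statistic = (p_hat - p0) / sqrt(p0 (1 - p0) / n), with a two-sided p from
    the normal approximation.
    """
    if not 0.0 < genome_proportion < 1.0:
        raise ValueError("genome proportion must lie strictly between 0 and 1")
    if n < 1:
        raise ValueError("sample size must be at least 1")
    p_hat = successes / n
    p0 = genome_proportion
    se = math.sqrt(p0 * (1 - p0) / n)
    t = (p_hat - p0) / se
    p = float(2 * stats.norm.sf(abs(t)))
    return t, p


def network_metrics(g: nx.Graph) -> dict:
    """Diameter, clustering coefficient, global efficiency and size of one network."""
    return {
        "n_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
        "diameter": diameter(g),
        "clustering_coefficient": clustering_coefficient(g),
        "global_efficiency": global_efficiency(g),
    }
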