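"""Network-level descriptive statistics for the directed confidant network.

Density follows the duplicate-collapsing convention: two participants share a
confidant tie when at least one regards the other as a confidant, so the
observed undirected tie count (reciprocated pairs collapsed to one) is divided
by the number of potentially arising ties n(n-1)/2.  Components and geodesic
distances are likewise computed on the undirected collapse, with isolated
nodes excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Tuple

import networkx as nx
import numpy as np

from .network import PROVENANCE_COMMUNITY, PROVENANCE_HOUSEHOLD, DirectedNetwork


@dataclass(frozen=True)
class NetworkDescriptives:
    n: int
    directed_tie_count: int
    reciprocal_directed_tie_count: int  # directed ties whose reverse also exists
    one_way_tie_count: int
    household_tie_count: int
    community_tie_count: int
    vertices_with_tie: int
    undirected_tie_count: int
    density: float
    component_count: int
    component_size_range: Tuple[int, int]
    mean_geodesic: Optional[float]

    def as_dict(self) -> dict:
        d = {
            "n": self.n,
            "directed_tie_count": self.directed_tie_count,
            "reciprocal_directed_tie_count": self.reciprocal_directed_tie_count,
            "one_way_tie_count": self.one_way_tie_count,
            "household_tie_count": self.household_tie_count,
            "community_tie_count": self.community_tie_count,
            "vertices_with_tie": self.vertices_with_tie,
            "undirected_tie_count": self.undirected_tie_count,
            "density": self.density,
            "component_count": self.component_count,
            "component_size_min": self.component_size_range[0],
            "component_size_max": self.component_size_range[1],
            "mean_geodesic": self.mean_geodesic,
        }
        return d


def max_potential_ties(n: int) -> int:
    """Maximum number of ties that can potentially arise among n participants: n(n-1)/2."""
    if n < 1:
        raise ValueError("need at least one node")
    return n * (n - 1) // 2


def collapsed_tie_count(one_way: int, reciprocal_directed: int) -> int:
    """Undirected tie count from the reciprocity partition of directed ties.

    Each reciprocated pair contributes two directed ties but one collapsed
    tie, so the duplicates due to reciprocation are removed by halving.
    """
    if reciprocal_directed % 2:
        raise ValueError("reciprocal directed tie count must be even")
    return one_way + reciprocal_directed // 2


def density_from_counts(n: int, one_way: int, reciprocal_directed: int) -> float:
    """Density = collapsed tie count / n(n-1)/2, from the tie-count partition."""
    if n < 2:
        raise ValueError("density needs at least two nodes")
    return collapsed_tie_count(one_way, reciprocal_directed) / max_potential_ties(n)


def reciprocity_partition(network: DirectedNetwork) -> Tuple[int, int]:
    """(one-way count, reciprocal count): each directed tie classified by its reverse."""
    reciprocal = sum(1 for (i, j) in network.edges if (j, i) in network.edges)
    return network.n_edges - reciprocal, reciprocal


def density(network: DirectedNetwork) -> float:
    """Collapsed (undirected) density of the confidant network."""
    if network.n < 2:
        raise ValueError("density needs at least two nodes")
    collapsed = network.to_undirected_collapse().number_of_edges()
    return collapsed / max_potential_ties(network.n)


def components_and_geodesics(
    network: DirectedNetwork,
) -> Tuple[int, Tuple[int, int], Optional[float]]:
    """Connected components and mean geodesic on the undirected collapse.

    Isolated nodes are excluded.  The mean geodesic averages shortest-path
    lengths over all unordered pairs lying in the same component; with no
    ties at all it is undefined (returned as None, component count 0).
    """
    g = network.to_undirected_collapse()
    g.remove_nodes_from([v for v in list(g.nodes) if g.degree(v) == 0])
    if g.number_of_nodes() == 0:
        return 0, (0, 0), None
    sizes = [len(c) for c in nx.connected_components(g)]
    total_dist = 0
    total_pairs = 0
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            total_dist += sum(dists.values())
        k = len(comp)
        total_pairs += k * (k - 1) // 2
    # all_pairs counts each ordered pair once and the zero self-distances
    mean_geo = (total_dist / 2) / total_pairs if total_pairs else None
    return len(sizes), (min(sizes), max(sizes)), mean_geo


def score_difference_profile(
    network: DirectedNetwork,
    scores: Optional[Mapping[str, Mapping[str, Optional[int]]]] = None,
    attributes: Tuple[str, ...] = ("gds_total", "apathy", "suicidal_ideation"),
    within: int = 5,
) -> Dict[str, dict]:
    """Per-tie absolute score-difference histograms with matched-tie counts.

    For each directed tie and each symptom attribute, tallies |score_i -
    score_j|, the number of exact matches (difference 0) and the number of
    ties within ``within`` points.  Ties with a missing endpoint score are
    excluded and counted.
    """
    if scores is None:
        scores = network.node_attributes
    out: Dict[str, dict] = {}
    for attr in attributes:
        diffs = []
        n_missing = 0
        for (i, j) in sorted(network.edges):
            si = scores.get(i, {}).get(attr)
            sj = scores.get(j, {}).get(attr)
            if si is None or sj is None:
                n_missing += 1
                continue
            diffs.append(abs(int(si) - int(sj)))
        hist: Dict[int, int] = {}
        for d in diffs:
            hist[d] = hist.get(d, 0) + 1
        out[attr] = {
            "histogram": dict(sorted(hist.items())),
            "n_ties": len(diffs),
            "n_excluded_missing": n_missing,
            "exact_matches": hist.get(0, 0),
            "within_threshold": sum(v for k, v in hist.items() if k <= within),
            "threshold": within,
        }
    return out


def describe(network: DirectedNetwork) -> NetworkDescriptives:
    """Full descriptive summary of a directed confidant network."""
    one_way, reciprocal = reciprocity_partition(network)
    collapse = network.to_undirected_collapse()
    vertices_with_tie = sum(1 for v in collapse.nodes if collapse.degree(v) > 0)
    n_components, size_range, mean_geo = components_and_geodesics(network)
    provenance = network.tie_provenance
    household = sum(
        1 for e in network.edges if provenance.get(e) == PROVENANCE_HOUSEHOLD
    )
    community = sum(
        1 for e in network.edges if provenance.get(e) == PROVENANCE_COMMUNITY
    )
    return NetworkDescriptives(
        n=network.n,
        directed_tie_count=network.n_edges,
        reciprocal_directed_tie_count=reciprocal,
        one_way_tie_count=one_way,
        household_tie_count=household,
        community_tie_count=community,
        vertices_with_tie=vertices_with_tie,
        undirected_tie_count=collapse.number_of_edges(),
        density=density(network) if network.n >= 2 else float("nan"),
        component_count=n_components,
        component_size_range=size_range,
        mean_geodesic=mean_geo,
    )
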