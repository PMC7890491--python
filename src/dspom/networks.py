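"""Emergent dispersal networks of occupied patches and the NLDC.

At each time step the occupied patches form the nodes of an undirected
graph; a link joins two nodes when their perimeter-to-perimeter gap is less
than or equal to the species dispersal distance D (the boundary case
``gap == D`` is connected).  Topology is summarised by node degree k,
shortest-path node betweenness beta (unweighted hop counts), the number of
connected components, and the network length L: the gap-weighted
shortest-path diameter, taken as the maximum over connected components so
that L tracks the longest surviving corridor through fragmentation episodes
(a largest-component variant is available).

The network length duration curve (NLDC) is the empirical exceedance curve
of L over time, using the Weibull plotting position rank / (n + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_array
from scipy.sparse.csgraph import connected_components, shortest_path

from .landscape import Wetlandscape
from .hydrology import HydroStateSeries
from .geometry import centre_distances, gap_matrix

__all__ = [
    "NetworkSnapshot",
    "build_network",
    "node_degree",
    "node_betweenness",
    "network_length",
    "nldc",
    "network_series",
]


@dataclass
class NetworkSnapshot:
    """The thresholded dispersal graph of occupied patches at one time step.

    ``graph`` is an undirected simple ``networkx`` graph whose nodes are the
    occupied patch indices and whose edges carry the gap length (m) in the
    ``gap`` attribute.
    """

    day: int
    graph: nx.Graph

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple]:
        return [(u, v, d["gap"]) for u, v, d in self.graph.edges(data=True)]

    @property
    def n_components(self) -> int:
        return nx.number_connected_components(self.graph) if len(self.graph) else 0


def build_network(
    occupied,
    gaps: np.ndarray,
    D: float,
    day: int = 0,
) -> NetworkSnapshot:
    """Dispersal graph over the occupied patches with gap threshold D.

    ``occupied`` is an iterable of patch indices (or a boolean mask over the
    rows of ``gaps``); an edge is placed between every occupied pair with
    ``gap <= D`` and carries the gap as its weight.  Deterministic for given
    inputs.
    """
    gaps = np.asarray(gaps, dtype=float)
    occupied = np.asarray(list(occupied))
    if occupied.dtype == bool:
        nodes = np.flatnonzero(occupied)
    else:
        nodes = occupied.astype(int)
    g = nx.Graph()
    g.add_nodes_from(int(i) for i in nodes)
    if len(nodes) > 1:
        sub = gaps[np.ix_(nodes, nodes)]
        ii, jj = np.nonzero(np.triu(sub <= D, k=1))
        g.add_edges_from(
            (int(nodes[a]), int(nodes[b]), {"gap": float(sub[a, b])})
            for a, b in zip(ii, jj)
        )
    return NetworkSnapshot(day=day, graph=g)


def node_degree(snapshot: NetworkSnapshot) -> dict[int, int]:
    """Number of links incident to each node (isolated nodes have 0)."""
    return dict(snapshot.graph.degree())


def node_betweenness(snapshot: NetworkSnapshot) -> dict[int, float]:
    """Shortest-path betweenness on the unweighted graph.

    Pair counts with equal split among equally short paths, endpoints
    excluded, unnormalised — the number of times a node bridges the shortest
    path between two others.
    """
    return nx.betweenness_centrality(snapshot.graph, normalized=False, weight=None)


def network_length(
    snapshot: NetworkSnapshot, fragmented: str = "max_component"
) -> float:
    """Network length L (m): gap-weighted shortest-path diameter.

    For a fragmented graph, ``"max_component"`` (default) returns the
    maximum over connected components of their weighted diameters;
    ``"largest_component"`` returns the diameter of the component with the
    most nodes.  Graphs with no edges have L = 0.
    """
    g = snapshot.graph
    if g.number_of_edges() == 0:
        return 0.0
    nodes = list(g.nodes)
    index = {u: k for k, u in enumerate(nodes)}
    rows, cols, vals = [], [], []
    for u, v, d in g.edges(data=True):
        rows += [index[u], index[v]]
        cols += [index[v], index[u]]
        vals += [d["gap"], d["gap"]]
    adj = csr_array((vals, (rows, cols)), shape=(len(nodes), len(nodes)))
    dist = shortest_path(adj, directed=False)
    if fragmented == "max_component":
        finite = np.isfinite(dist)
        return float(dist[finite].max())
    if fragmented == "largest_component":
        n_comp, labels = connected_components(adj, directed=False)
        sizes = np.bincount(labels)
        members = np.flatnonzero(labels == np.argmax(sizes))
        sub = dist[np.ix_(members, members)]
        return float(sub[np.isfinite(sub)].max())
    raise ValueError(f"unknown fragmented rule {fragmented!r}")


def nldc(lengths: np.ndarray) -> pd.DataFrame:
    """Network length duration curve: exceedance probability of L over time.

    Returns a table sorted by decreasing length with the Weibull plotting
    position ``P(L >= l_(k)) = k / (n + 1)`` for the k-th largest length; a
    valid survival curve (non-increasing length in exceedance probability).
    """
    lengths = np.asarray(lengths, dtype=float)
    lengths = lengths[np.isfinite(lengths)]
    if len(lengths) == 0:
        raise ValueError("need at least one length")
    ordered = np.sort(lengths)[::-1]
    n = len(ordered)
    return pd.DataFrame(
        {"exceedance": np.arange(1, n + 1) / (n + 1), "length": ordered}
    )


def network_series(
    landscape: Wetlandscape,
    hydro: HydroStateSeries,
    occupancy: np.ndarray,
    D: float,
    betweenness: bool = False,
    fragmented: str = "max_component",
) -> pd.DataFrame:
    """Per-day network metrics along one occupancy realisation.

    ``occupancy`` is (T, n) boolean.  Emits per-day node counts, edge
    counts, daily node-mean degree (and betweenness when requested),
    component count and network length L.
    """
    centres = centre_distances(landscape)
    T = hydro.n_days
    if occupancy.shape != (T, hydro.n_wetlands):
        raise ValueError("occupancy shape inconsistent with hydrology")
    rows = []
    for t in range(T):
        gaps = gap_matrix(centres, hydro.A[t])
        snap = build_network(occupancy[t], gaps, D, day=t)
        degs = node_degree(snap)
        row = {
            "day": t,
            "n_nodes": len(snap.nodes),
            "n_edges": snap.graph.number_of_edges(),
            "mean_degree": float(np.mean(list(degs.values()))) if degs else np.nan,
            "n_components": snap.n_components,
            "L": network_length(snap, fragmented=fragmented),
        }
        if betweenness:
            bc = node_betweenness(snap)
            row["mean_betweenness"] = float(np.mean(list(bc.values()))) if bc else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
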