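"""Confidence-filtered PPI graphs and iterative six-centrality hub extraction.

The hub-extraction procedure scores every protein on six centrality indices —
degree (DC), betweenness (BC), closeness (CC), eigenvector (EC), local average
connectivity (LAC) and network centrality (NC, the sum of edge clustering
coefficients) — keeps the nodes above the per-index median on *all six*,
induces the subgraph on the survivors, and repeats (three rounds by default)
to distil a hub sub-network.

Index definitions
-----------------
- ``dc(v)``  : degree.
- ``bc(v)``  : unnormalized shortest-path betweenness over unordered pairs;
  pairs in different components contribute 0.
- ``cc(v)``  : per-component closeness ``(n_comp - 1) / sum_u d(v, u)`` with
  the sum over ``v``'s connected component.
- ``ec(v)``  : principal eigenvector of the adjacency matrix, rescaled so the
  largest entry equals 1.
- ``lac(v)`` : mean degree of ``v``'s neighbours inside the subgraph induced
  by the neighbourhood ``N(v)``; 0 for degree-0 nodes.
- ``nc(v)``  : ``sum_{w in N(v)} ECC(v, w)`` where
  ``ECC(u, v) = #triangles on uv / min(deg u - 1, deg v - 1)`` and a 0
  denominator yields 0 (pendant edges and stars score 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "build_ppi_graph",
    "compute_centralities",
    "median_filter_step",
    "extract_hub_subnetwork",
    "HubExtractionTrace",
    "CENTRALITY_COLUMNS",
]

DEFAULT_CONF_MIN = 0.7
CENTRALITY_COLUMNS = ["dc", "bc", "cc", "ec", "lac", "nc"]

Comparator = Literal["strict", "inclusive"]


def build_ppi_graph(
    edges: Iterable[tuple[str, str, float]],
    conf_min: float = DEFAULT_CONF_MIN,
) -> nx.Graph:
    """Filter an edge list into a simple confidence-weighted PPI graph.

    Keeps edges with ``confidence >= conf_min`` (inclusive), drops self-loops,
    collapses duplicate edges keeping the maximum confidence, and removes
    nodes isolated after filtering.
    """
    g = nx.Graph()
    for a, b, c in edges:
        c = float(c)
        if not 0.0 <= c <= 1.0:
            raise ValueError(f"confidence {c} for edge ({a}, {b}) outside [0, 1]")
        if a == b:
            continue
        if c < conf_min:
            continue
        if g.has_edge(a, b):
            g[a][b]["confidence"] = max(g[a][b]["confidence"], c)
        else:
            g.add_edge(a, b, confidence=c)
    # adding edges never creates isolated nodes; nothing else added
    return g


def _eigenvector_scores(g: nx.Graph, nodes: list) -> np.ndarray:
    a = nx.to_numpy_array(g, nodelist=nodes)
    w, v = np.linalg.eigh(a)
    vec = np.abs(v[:, int(np.argmax(w))])
    m = vec.max()
    return vec / m if m > 0 else vec


def _lac(g: nx.Graph, v) -> float:
    nbrs = list(g.neighbors(v))
    if not nbrs:
        return 0.0
    sub = g.subgraph(nbrs)
    return sum(dict(sub.degree()).values()) / len(nbrs)


def _nc(g: nx.Graph, v) -> float:
    total = 0.0
    dv = g.degree(v)
    nv = set(g.neighbors(v))
    for w in nv:
        denom = min(dv - 1, g.degree(w) - 1)
        if denom <= 0:
            continue
        tri = len(nv & set(g.neighbors(w)))
        total += tri / denom
    return total


def compute_centralities(g: nx.Graph) -> pd.DataFrame:
    """Six-index centrality table, one row per node.

    Returns a DataFrame indexed by node with columns
    ``dc, bc, cc, ec, lac, nc``; per-index medians are ``table.median()``.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("cannot compute centralities of an empty graph")
    nodes = list(g.nodes)
    dc = dict(g.degree())
    bc = nx.betweenness_centrality(g, normalized=False)
    cc = nx.closeness_centrality(g, wf_improved=False)
    ec = dict(zip(nodes, _eigenvector_scores(g, nodes)))
    table = pd.DataFrame(
        {
            "dc": [float(dc[n]) for n in nodes],
            "bc": [bc[n] for n in nodes],
            "cc": [cc[n] for n in nodes],
            "ec": [ec[n] for n in nodes],
            "lac": [_lac(g, n) for n in nodes],
            "nc": [_nc(g, n) for n in nodes],
        },
        index=nodes,
    )
    # eigensolver jitter (~1e-16) would break median ties on symmetric
    # graphs; 12 decimals is far below any real score difference
    return table.round(12)


def median_filter_step(
    g: nx.Graph, comparator: Comparator = "strict"
) -> tuple[set, pd.Series]:
    """One round of above-median selection on all six indices.

    A node survives iff its score beats the per-index median for *every*
    index — strictly greater by default, or ``>=`` with
    ``comparator="inclusive"``.  An empty survivor set is a legal outcome.
    """
    if g.number_of_nodes() < 2:
        raise ValueError("median filtering needs at least 2 nodes")
    table = compute_centralities(g)
    medians = table.median()
    if comparator == "strict":
        mask = (table > medians).all(axis=1)
    elif comparator == "inclusive":
        mask = (table >= medians).all(axis=1)
    else:
        raise ValueError(f"unknown comparator {comparator!r}")
    return set(table.index[mask]), medians


@dataclass
class HubExtractionTrace:
    """Audit trail of the iterative extraction."""

    rounds: list[dict] = field(default_factory=list)
    stop_reason: str = "completed"

    def to_dict(self) -> dict:
        return {
            "stop_reason": self.stop_reason,
            "rounds": [
                {
                    "input_nodes": sorted(map(str, r["input_nodes"])),
                    "medians": {k: float(v) for k, v in r["medians"].items()},
                    "survivors": sorted(map(str, r["survivors"])),
                }
                for r in self.rounds
            ],
        }


def extract_hub_subnetwork(
    g: nx.Graph,
    rounds: int = 3,
    min_size: int = 3,
    comparator: Comparator = "strict",
) -> tuple[nx.Graph, HubExtractionTrace]:
    """Iterate :func:`median_filter_step`, inducing the survivor subgraph.

    After each round the subgraph is induced on the survivors and isolated
    nodes are dropped again.  Iteration stops early when the survivor set is
    empty, unchanged, or smaller than ``min_size``; the *last valid*
    sub-network is returned together with a full trace.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    current = g
    trace = HubExtractionTrace()
    for _ in range(rounds):
        if current.number_of_nodes() < 2:
            trace.stop_reason = "below-min-size"
            break
        survivors, medians = median_filter_step(current, comparator)
        sub = current.subgraph(survivors).copy()
        sub.remove_nodes_from([n for n, d in sub.degree() if d == 0])
        trace.rounds.append(
            {
                "input_nodes": set(current.nodes),
                "medians": medians.to_dict(),
                "survivors": set(sub.nodes),
            }
        )
        if sub.number_of_nodes() == 0:
            trace.stop_reason = "empty-result"
            break
        if set(sub.nodes) == set(current.nodes):
            current = sub
            trace.stop_reason = "unchanged"
            break
        if sub.number_of_nodes() < min_size:
            trace.stop_reason = "below-min-size"
            break
        current = sub
    return current, trace
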