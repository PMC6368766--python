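"""Interaction-network construction, disease subnetworks, and centrality ranking.

The predicted-positive gene pairs form a simple undirected graph.  Candidate
disease genes are prioritized by extracting a seed-anchored subnetwork (every
edge touches at least one seed gene) and ranking its nodes by one of four
centrality measures:

* degree — raw neighbor count;
* closeness — (|comp|-1) / sum of BFS distances, within each component;
* betweenness — Brandes pair-dependencies, endpoints excluded, each
  unordered pair counted once, unnormalized;
* eigenvector — power iteration on the adjacency structure (all-ones start,
  L2 normalization, tolerance 1e-10, up to 1000 iterations).

Predicted probabilities are carried as edge annotations only; centrality is
computed on the unweighted graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "InteractionNetwork",
    "SeedList",
    "CentralityScores",
    "NetworkStats",
    "build_network",
    "extract_disease_subnetwork",
    "degree_centrality",
    "closeness_centrality",
    "betweenness_centrality",
    "eigenvector_centrality",
    "centrality",
    "network_stats",
    "rank_top_n",
    "load_seed_list",
    "read_edge_list",
    "write_edge_list",
]

MEASURES = ("degree", "closeness", "betweenness", "eigenvector")


@dataclass
class InteractionNetwork:
    """Simple undirected graph over gene symbols, backed by networkx."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {tuple(sorted(e)) for e in self.graph.edges}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class SeedList:
    """Genes known a priori to be associated with a disease."""

    disease: str
    symbols: list[str]

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("seed symbols must be unique")


@dataclass
class CentralityScores:
    measure: str
    scores: dict[str, float]


@dataclass
class NetworkStats:
    n_nodes: int
    n_edges: int
    diameter: int
    clustering_coefficient: float


def build_network(edges: Iterable[tuple]) -> InteractionNetwork:
    """Deduplicated simple graph from (g1, g2[, probability]) rows.

    Self-pairs are dropped with a warning.  Node iteration order is
    lexicographic and deterministic.
    """
    g = nx.Graph()
    for row in edges:
        a, b = row[0], row[1]
        prob = float(row[2]) if len(row) > 2 else None
        if a == b:
            warnings.warn(f"self-pair ({a}, {b}) dropped")
            continue
        if prob is None:
            g.add_edge(a, b)
        else:
            g.add_edge(a, b, probability=prob)
    ordered = nx.Graph()
    ordered.add_nodes_from(sorted(g.nodes))
    ordered.add_edges_from(sorted((tuple(sorted(e)) for e in g.edges)))
    for a, b, data in g.edges(data=True):
        ordered[a][b].update(data)
    return InteractionNetwork(graph=ordered)


def extract_disease_subnetwork(net: InteractionNetwork, seeds: SeedList) -> InteractionNetwork:
    """Subnetwork of edges touching at least one seed gene.

    Nodes are the endpoints of the retained edges; an edge between two
    non-seed genes is excluded even if both endpoints neighbor seeds.  Seeds
    absent from the network are recorded on the result as ``missing_seeds``
    (this feeds the seed-recall metric).
    """
    if not seeds.symbols:
        raise ValueError("seed list is empty")
    seed_set = set(seeds.symbols)
    sub = nx.Graph()
    for a, b, data in net.graph.edges(data=True):
        if a in seed_set or b in seed_set:
            sub.add_edge(a, b, **data)
    result = build_network(
        [(a, b, d["probability"]) if "probability" in d else (a, b)
         for a, b, d in sub.edges(data=True)]
    )
    result.missing_seeds = sorted(seed_set - set(net.graph.nodes))  # type: ignore[attr-defined]
    return result


# ---------------------------------------------------------------------------
# centrality

def degree_centrality(net: InteractionNetwork) -> CentralityScores:
    """Raw neighbor counts (unnormalized)."""
    return CentralityScores(
        measure="degree", scores={n: float(d) for n, d in net.graph.degree()}
    )


def closeness_centrality(net: InteractionNetwork, scope: str = "component") -> CentralityScores:
    """Within-component closeness (|comp|-1) / sum of shortest distances.

    Isolated nodes score 0.  ``scope="harmonic"`` switches to harmonic
    closeness (sum of inverse distances over all reachable nodes), which is
    also well-defined on disconnected graphs.
    """
    if scope == "component":
        scores = nx.closeness_centrality(net.graph, wf_improved=False)
    elif scope == "harmonic":
        scores = nx.harmonic_centrality(net.graph)
    else:
        raise ValueError(f"unknown closeness scope: {scope!r}")
    return CentralityScores(measure="closeness", scores={n: float(v) for n, v in scores.items()})


def betweenness_centrality(net: InteractionNetwork, normalized: bool = False) -> CentralityScores:
    """Shortest-path betweenness, endpoints excluded, unordered pairs once."""
    scores = nx.betweenness_centrality(net.graph, normalized=normalized)
    return CentralityScores(
        measure="betweenness", scores={n: float(v) for n, v in scores.items()}
    )


def eigenvector_centrality(
    net: InteractionNetwork, tol: float = 1e-10, max_iter: int = 1000
) -> CentralityScores:
    """Power iteration on the adjacency structure.

    Starts from the all-ones vector and L2-normalizes each step.  The
    iteration matrix is A + I (same eigenvectors as A, strictly dominant top
    eigenvalue), which avoids the sign oscillation a raw adjacency iteration
    exhibits on bipartite graphs.  On disconnected graphs the result
    reflects the dominant component(s).  Scores are nonnegative; an edgeless
    graph scores all zeros.
    """
    nodes = net.nodes
    n = len(nodes)
    if n == 0 or net.n_edges == 0:
        return CentralityScores(measure="eigenvector", scores={v: 0.0 for v in nodes})
    A = nx.to_numpy_array(net.graph, nodelist=nodes)
    v = np.ones(n) / np.sqrt(n)
    for _ in range(max_iter):
        nxt = A @ v + v
        norm = np.linalg.norm(nxt)
        if norm == 0:
            break
        nxt /= norm
        if np.max(np.abs(nxt - v)) <= tol:
            v = nxt
            break
        v = nxt
    v = np.clip(v, 0.0, None)
    return CentralityScores(
        measure="eigenvector", scores={node: float(val) for node, val in zip(nodes, v)}
    )


def centrality(net: InteractionNetwork, measure: str) -> CentralityScores:
    """Dispatch by measure name (degree/closeness/betweenness/eigenvector)."""
    if measure == "degree":
        return degree_centrality(net)
    if measure == "closeness":
        return closeness_centrality(net)
    if measure == "betweenness":
        return betweenness_centrality(net)
    if measure == "eigenvector":
        return eigenvector_centrality(net)
    raise ValueError(f"unknown centrality measure: {measure!r}")


def network_stats(net: InteractionNetwork) -> NetworkStats:
    """Node/edge counts, largest-component diameter, mean local clustering.

    Nodes of degree < 2 contribute 0 to the clustering coefficient; the
    diameter of an edgeless graph is reported as 0.
    """
    g = net.graph
    if g.number_of_edges() == 0:
        diameter = 0
    else:
        comp = max(nx.connected_components(g), key=len)
        diameter = int(nx.diameter(g.subgraph(comp)))
    cc = float(nx.average_clustering(g)) if g.number_of_nodes() else 0.0
    return NetworkStats(
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        diameter=diameter,
        clustering_coefficient=cc,
    )


def rank_top_n(scores: CentralityScores, n: int = 15) -> list[str]:
    """Top-n genes by descending score, ties broken by ascending symbol."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ordered = sorted(scores.scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return [gene for gene, _ in ordered[:n]]


# ---------------------------------------------------------------------------
# I/O

def load_seed_list(path: str | Path, disease: str | None = None) -> SeedList:
    """One gene symbol per line; duplicates within the file are rejected."""
    path = Path(path)
    symbols = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            sym = line.strip()
            if sym:
                symbols.append(sym)
    return SeedList(disease=disease or path.stem, symbols=symbols)


def read_edge_list(path: str | Path) -> list[tuple]:
    """TSV rows ``g1<TAB>g2[<TAB>probability]`` (no header)."""
    rows: list[tuple] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) == 2:
                rows.append((parts[0], parts[1]))
            elif len(parts) == 3:
                rows.append((parts[0], parts[1], float(parts[2])))
            else:
                raise ValueError(f"bad edge row: {line!r}")
    return rows


def write_edge_list(net: InteractionNetwork, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(net.edges):
            data = net.graph[a][b]
            if "probability" in data:
                fh.write(f"{a}\t{b}\t{data['probability']:.6g}\n")
            else:
                fh.write(f"{a}\t{b}\n")
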