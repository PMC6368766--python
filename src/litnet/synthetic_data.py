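"""Synthetic inputs for every pipeline stage.

Three generators:

* :func:`simulate_corpus` — an abstract corpus in which a hidden interaction
  graph drives co-occurrence.  Each abstract is "about" one focal gene pair;
  sentences jointly mention the pair with probability ``p_cooccur_pos`` when
  the pair is a true edge and ``p_cooccur_neg`` otherwise, and joint mentions
  carry an interaction cue phrase with probability ``p_cue``.  A dense
  disease module around designated seed genes is planted into the graph, so
  downstream subnetwork extraction and ranking can be validated against
  ground truth.
* :func:`simulate_feature_table` — labeled 9-feature rows drawn from a known
  logistic model at a low event prevalence (the intercept is solved
  numerically to hit the target prevalence).
* :func:`fixture_graphs` — named small graphs together with centrality tables
  computed by brute-force oracles (exhaustive shortest-path enumeration and a
  dense eigendecomposition), for verifying the network module.

All randomness flows from one explicit seed through spawned child streams,
so the generation order of one component cannot perturb another.  Synthetic
gene symbols (``G0001`` ...) and GO term names (``process alpha 17`` ...) are
collision-free under alphanumeric tokenization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
from scipy.optimize import brentq

from .corpus_io import AbstractRecord, GeneLexicon, GOAnnotationMap, write_abstracts_tsv
from .models import LabeledPairTable, _sigmoid
from .network import InteractionNetwork, build_network

__all__ = [
    "CorpusSimConfig",
    "ModelSimConfig",
    "SimulatedCorpus",
    "simulate_corpus",
    "simulate_feature_table",
    "fixture_graphs",
    "brute_degree",
    "brute_closeness",
    "brute_betweenness",
    "brute_eigenvector",
]

_GREEK = (
    "alpha", "beta", "gamma", "delta", "epsilon", "zeta", "eta", "theta",
    "iota", "kappa", "lambda", "mu", "nu", "xi", "omicron", "rho",
)

_CUE_TEMPLATES = (
    "{a} interacts with {b} in tumor cells.",
    "{a} binds to {b} during replication.",
    "{a} binds with {b} under stress.",
    "{a} is associated with {b} expression.",
)

#: joint-mention wording with no cue token between the two gene mentions
_PLAIN_TEMPLATES = (
    "{a} modulates {b} levels.",
    "{a} regulates expression near {b}.",
    "{a} was measured while {b} stayed high.",
)

_CUE_GO_TEMPLATE = "{a} interacts with {b} via {go}."
#: gene linked by a cue directly to a GO term of its partner (partner unnamed)
_CUE_GO_PROXY_TEMPLATE = "{a} is associated with {go}."
_SINGLE_TEMPLATES = (
    "{g} was strongly expressed.",
    "{g} showed reduced activity.",
)
_SINGLE_GO_TEMPLATE = "{g} contributes to {go}."


@dataclass
class CorpusSimConfig:
    """Study conditions for the corpus generator.

    The default scale (200 genes, 2000 abstracts, strong signal
    p_cooccur_pos=0.3 vs p_cooccur_neg=0.005) is the strong-signal recovery
    condition used throughout the test suite; ``er_mean_degree`` sets the
    background Erdos-Renyi edge density and a ``module_size`` clique around
    ``module_seeds`` designated seed genes is planted on top.
    """

    n_genes: int = 200
    go_terms_per_gene: int = 2
    n_abstracts: int = 2000
    sentences_per_abstract: int = 6
    interaction_edges: Sequence[tuple[str, str]] | None = None
    er_mean_degree: float = 2.0
    module_size: int = 10
    module_seeds: int = 3
    p_cooccur_pos: float = 0.3
    p_cooccur_neg: float = 0.005
    p_cue: float = 0.6
    p_focus_edge: float = 0.5
    p_go_mention: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "go_terms_per_gene", "n_abstracts", "sentences_per_abstract"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.p_cooccur_neg <= self.p_cooccur_pos <= 1.0):
            raise ValueError("need 0 <= p_cooccur_neg <= p_cooccur_pos <= 1")
        for name in ("p_cue", "p_focus_edge", "p_go_mention"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.module_size > self.n_genes:
            raise ValueError("module_size exceeds n_genes")
        if self.module_seeds > self.module_size:
            raise ValueError("module_seeds exceeds module_size")


@dataclass
class SimulatedCorpus:
    """Generator output: corpus, lexicons and the ground-truth graph."""

    records: list[AbstractRecord]
    genes: GeneLexicon
    go: GOAnnotationMap
    true_edges: set[tuple[str, str]]
    module_genes: list[str]
    seed_genes: list[str]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_abstracts_tsv(self.records, out / "corpus.tsv")
        with open(out / "genes.txt", "w", encoding="utf-8") as fh:
            for sym in sorted(self.genes.symbols):
                fh.write(sym + "\n")
        with open(out / "go_annotations.tsv", "w", encoding="utf-8") as fh:
            for gene in sorted(self.go.annotations):
                for go_id in sorted(self.go.annotations[gene]):
                    fh.write(f"{gene}\t{go_id}\t{self.go.names[go_id]}\n")
        with open(out / "true_edges.tsv", "w", encoding="utf-8") as fh:
            for a, b in sorted(self.true_edges):
                fh.write(f"{a}\t{b}\n")
        with open(out / "seed_genes.txt", "w", encoding="utf-8") as fh:
            for sym in self.seed_genes:
                fh.write(sym + "\n")


def _gene_symbols(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _go_vocabulary(n_terms: int) -> tuple[list[str], list[str]]:
    ids = [f"GO:{i:07d}" for i in range(1, n_terms + 1)]
    names = [f"process {_GREEK[i % len(_GREEK)]} {i}" for i in range(1, n_terms + 1)]
    return ids, names


def _interaction_graph(cfg: CorpusSimConfig, symbols: list[str], rng: np.random.Generator):
    """True edge set: explicit edges, or ER background + planted module clique."""
    if cfg.interaction_edges is not None:
        edges = {tuple(sorted(e)) for e in cfg.interaction_edges}
        module = sorted({g for e in edges for g in e})[: cfg.module_size]
    else:
        p = min(1.0, cfg.er_mean_degree / max(1, cfg.n_genes - 1))
        edges = set()
        for a, b in combinations(symbols, 2):
            if rng.random() < p:
                edges.add((a, b))
        module = list(rng.choice(symbols, size=cfg.module_size, replace=False))
        for a, b in combinations(sorted(module), 2):
            edges.add((a, b))
    seeds = sorted(module)[: cfg.module_seeds]
    return edges, sorted(module), seeds


def simulate_corpus(cfg: CorpusSimConfig) -> SimulatedCorpus:
    """Generate a corpus whose co-occurrence statistics encode a hidden graph.

    Deterministic under ``cfg.seed`` (byte-identical output files).
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_graph, rng_text = (np.random.default_rng(s) for s in ss.spawn(2))

    symbols = _gene_symbols(cfg.n_genes)
    go_ids, go_names = _go_vocabulary(cfg.n_genes * cfg.go_terms_per_gene)
    annotations = {}
    names = dict(zip(go_ids, go_names))
    for i, sym in enumerate(symbols):
        terms = go_ids[i * cfg.go_terms_per_gene : (i + 1) * cfg.go_terms_per_gene]
        annotations[sym] = set(terms)
    go = GOAnnotationMap(annotations=annotations, names=names)
    genes = GeneLexicon(symbols=set(symbols))

    edges, module, seeds = _interaction_graph(cfg, symbols, rng_graph)
    edge_list = sorted(edges)

    records = []
    all_pairs_n = cfg.n_genes * (cfg.n_genes - 1) // 2
    for a_idx in range(cfg.n_abstracts):
        # focal pair: biased toward true edges so each edge accrues evidence
        if edge_list and rng_text.random() < cfg.p_focus_edge:
            pair = edge_list[rng_text.integers(len(edge_list))]
        else:
            i = int(rng_text.integers(all_pairs_n))
            pair = _pair_from_index(symbols, i)
        ga, gb = pair
        is_edge = pair in edges
        p_joint = cfg.p_cooccur_pos if is_edge else cfg.p_cooccur_neg
        title_gene = ga if rng_text.random() < 0.5 else gb
        title = f"Characterization of {title_gene} signaling activity."
        sentences = []
        for _ in range(cfg.sentences_per_abstract - 1):
            x, ybis = (ga, gb) if rng_text.random() < 0.5 else (gb, ga)
            if rng_text.random() < p_joint:
                if rng_text.random() < cfg.p_cue:
                    if rng_text.random() < cfg.p_go_mention:
                        go_name = names[sorted(annotations[ybis])[int(rng_text.integers(cfg.go_terms_per_gene))]]
                        if rng_text.random() < 0.5:
                            sentences.append(_CUE_GO_TEMPLATE.format(a=x, b=ybis, go=go_name))
                        else:
                            sentences.append(_CUE_GO_PROXY_TEMPLATE.format(a=x, go=go_name))
                    else:
                        tpl = _CUE_TEMPLATES[int(rng_text.integers(len(_CUE_TEMPLATES)))]
                        sentences.append(tpl.format(a=x, b=ybis))
                else:
                    tpl = _PLAIN_TEMPLATES[int(rng_text.integers(len(_PLAIN_TEMPLATES)))]
                    sentences.append(tpl.format(a=x, b=ybis))
            else:
                if rng_text.random() < cfg.p_go_mention:
                    go_name = names[sorted(annotations[x])[int(rng_text.integers(cfg.go_terms_per_gene))]]
                    sentences.append(_SINGLE_GO_TEMPLATE.format(g=x, go=go_name))
                else:
                    tpl = _SINGLE_TEMPLATES[int(rng_text.integers(len(_SINGLE_TEMPLATES)))]
                    sentences.append(tpl.format(g=x))
        records.append(
            AbstractRecord(id=f"A{a_idx + 1:06d}", title=title, body=" ".join(sentences))
        )
    return SimulatedCorpus(
        records=records,
        genes=genes,
        go=go,
        true_edges=edges,
        module_genes=module,
        seed_genes=seeds,
    )


def _pair_from_index(symbols: list[str], idx: int) -> tuple[str, str]:
    """idx-th unordered pair in lexicographic enumeration order."""
    n = len(symbols)
    for i in range(n - 1):
        row = n - 1 - i
        if idx < row:
            return symbols[i], symbols[i + 1 + idx]
        idx -= row
    raise IndexError("pair index out of range")


# ---------------------------------------------------------------------------
# labeled feature tables from a known logistic model

@dataclass
class ModelSimConfig:
    """Rare-event logistic sampling model for labeled feature rows."""

    n_rows: int = 5000
    beta_star: Sequence[float] = (2.0, 1.5, 1.0, 0.0, 0.0, 0.0, -1.0, 0.0, 0.5)
    prevalence: float = 0.05
    feature_dist: str = "uniform"  # or "beta" (sparse-skewed)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 0.5:
            raise ValueError("prevalence must lie in (0, 0.5)")
        if self.n_rows <= 0:
            raise ValueError("n_rows must be positive")


def simulate_feature_table(cfg: ModelSimConfig) -> tuple[LabeledPairTable, dict]:
    """Draw features in [0, 1] and labels from logistic(beta0 + x beta*).

    The intercept beta0 is solved numerically so that the mean event
    probability matches the target prevalence; the achieved label fraction is
    within sampling noise of it.  Returns the table and a record with the
    true coefficients, solved intercept and achieved prevalence.
    """
    rng = np.random.default_rng(cfg.seed)
    beta = np.asarray(cfg.beta_star, dtype=float)
    d = len(beta)
    if cfg.feature_dist == "uniform":
        X = rng.uniform(0.0, 1.0, size=(cfg.n_rows, d))
    elif cfg.feature_dist == "beta":
        X = rng.beta(0.5, 3.0, size=(cfg.n_rows, d))
    else:
        raise ValueError(f"unknown feature distribution: {cfg.feature_dist!r}")
    X = np.clip(X, 0.0, 1.0)
    xb = X @ beta

    def mean_prob(b0: float) -> float:
        return float(np.mean(_sigmoid(b0 + xb))) - cfg.prevalence

    beta0 = brentq(mean_prob, -50.0, 50.0)
    p = _sigmoid(beta0 + xb)
    y = (rng.random(cfg.n_rows) < p).astype(int)
    pairs = [(f"P{i:06d}a", f"P{i:06d}b") for i in range(cfg.n_rows)]
    table = LabeledPairTable(pairs=pairs, X=X, y=y)
    record = {
        "beta_star": beta.tolist(),
        "intercept": float(beta0),
        "target_prevalence": cfg.prevalence,
        "achieved_prevalence": float(y.mean()),
    }
    return table, record


# ---------------------------------------------------------------------------
# fixture graphs with brute-force centrality oracles

def brute_degree(g: nx.Graph) -> dict[str, float]:
    return {v: float(sum(1 for _ in g.neighbors(v))) for v in g.nodes}


def _bfs_distances(g: nx.Graph, source) -> dict:
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in g.neighbors(u):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def brute_closeness(g: nx.Graph) -> dict[str, float]:
    """(|comp|-1)/sum(d) within each component; isolated nodes 0."""
    out = {}
    for v in g.nodes:
        dist = _bfs_distances(g, v)
        total = sum(dist.values())
        out[v] = (len(dist) - 1) / total if total > 0 else 0.0
    return out


def _all_shortest_paths(g: nx.Graph, s, t) -> list[list]:
    dist = _bfs_distances(g, s)
    if t not in dist:
        return []
    paths = []

    def backtrack(node, acc):
        if node == s:
            paths.append(list(reversed(acc + [s])))
            return
        for u in g.neighbors(node):
            if dist.get(u, -1) == dist[node] - 1:
                backtrack(u, acc + [node])

    backtrack(t, [])
    return paths


def brute_betweenness(g: nx.Graph) -> dict[str, float]:
    """Sum over unordered pairs of sigma_st(v)/sigma_st; endpoints excluded."""
    score = {v: 0.0 for v in g.nodes}
    nodes = list(g.nodes)
    for s, t in combinations(nodes, 2):
        paths = _all_shortest_paths(g, s, t)
        if not paths:
            continue
        for path in paths:
            for v in path[1:-1]:
                score[v] += 1.0 / len(paths)
    return score


def brute_eigenvector(g: nx.Graph) -> dict[str, float]:
    """Normalized projection of the all-ones vector onto the dominant
    eigenspace of the adjacency matrix (the limit of power iteration)."""
    nodes = sorted(g.nodes)
    n = len(nodes)
    if n == 0 or g.number_of_edges() == 0:
        return {v: 0.0 for v in nodes}
    A = nx.to_numpy_array(g, nodelist=nodes)
    vals, vecs = np.linalg.eigh(A)
    top = vals[-1]
    space = vecs[:, np.abs(vals - top) <= 1e-9 * max(1.0, abs(top))]
    proj = space @ (space.T @ np.ones(n))
    norm = np.linalg.norm(proj)
    if norm < 1e-12:  # pathological start orthogonal to the eigenspace
        proj = np.abs(space[:, 0])
        norm = np.linalg.norm(proj)
    v = np.clip(proj / norm, 0.0, None)
    return {node: float(val) for node, val in zip(nodes, v)}


_ORACLES = {
    "degree": brute_degree,
    "closeness": brute_closeness,
    "betweenness": brute_betweenness,
    "eigenvector": brute_eigenvector,
}


def fixture_graphs(n_random: int = 50, seed: int = 0) -> dict[str, tuple[InteractionNetwork, dict]]:
    """Named graphs with brute-force centrality answer tables.

    Includes the path P3, the star K1,4, cliques K3 and K4, a barbell, and
    ``n_random`` seeded Erdos-Renyi graphs of at most 8 nodes.  Answers are
    regenerated from the oracles on every call, so they are bit-identical
    across runs.
    """
    graphs: dict[str, nx.Graph] = {
        "path_p3": nx.path_graph(["a", "b", "c"]),
        "star_k14": nx.star_graph(4),
        "k3": nx.complete_graph(3),
        "k4": nx.complete_graph(4),
        "barbell": nx.barbell_graph(3, 1),
    }
    rng = np.random.default_rng(seed)
    for i in range(n_random):
        n = int(rng.integers(4, 9))
        p = float(rng.uniform(0.2, 0.8))
        g = nx.Graph()
        g.add_nodes_from(range(n))
        for a, b in combinations(range(n), 2):
            if rng.random() < p:
                g.add_edge(a, b)
        graphs[f"random_{i:02d}"] = g
    out = {}
    for name, g in graphs.items():
        relabeled = nx.relabel_nodes(g, {v: str(v) for v in g.nodes})
        net = build_network([tuple(sorted(e)) for e in relabeled.edges])
        # keep isolated nodes too
        net.graph.add_nodes_from(str(v) for v in g.nodes)
        answers = {m: oracle(net.graph) for m, oracle in _ORACLES.items()}
        out[name] = (net, answers)
    return out
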