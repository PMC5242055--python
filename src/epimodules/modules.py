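"""Module discovery on a scored gene interaction network.

Gene scores are overlaid on an undirected interaction network and modules
are found either by spin-glass community detection (resolution parameter
0.5, module size 8-100 by default) on edge weights uplifted by the endpoint
scores, or by a greedy maximum-weight connected subgraph (MWCS) heuristic
that plays the role of an exact branch-and-cut MWCS solver and typically
returns one larger summary subnetwork. Each module is assigned a Fisher /
chi-square significance: -2 sum(ln p_g) referred to chi-square with 2k
degrees of freedom for k genes, which is used to rank and filter modules.

Nodes present in the network but absent from the score table keep p = 1 and
score 0: they participate in the topology (and may be pulled into modules as
potentially important members without direct statistical evidence) but
contribute nothing to module significance.
"""

from __future__ import annotations

import heapq
import logging
import random as _pyrandom
from dataclasses import dataclass, field

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

SPINGLASS_GAMMA = 0.5
MODULE_MIN_SIZE = 8
MODULE_MAX_SIZE = 100


@dataclass
class Module:
    """A connected gene subnetwork with chi-square aggregate significance."""

    module_id: str
    genes: frozenset[str]
    chi2_stat: float
    df: int
    p_value: float
    mean_score: float
    modularity_contribution: float = 0.0

    def __post_init__(self) -> None:
        if self.df != 2 * len(self.genes):
            raise ValueError("df must equal 2 * number of genes")


def build_scored_network(
    edge_list: list[tuple[str, str]],
    gene_scores: dict[str, "object"],
) -> nx.Graph:
    """Assemble the scored interaction network.

    Self-loops and duplicate edges collapse; only the largest connected
    component is retained (smaller components are logged). Each node carries
    ``fisher_score`` and ``combined_p`` attributes; network nodes without a
    score get score 0 / p 1 and ``no_data=True``.
    """
    g = nx.Graph()
    for a, b in edge_list:
        if a == b:
            continue
        g.add_edge(str(a), str(b))
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    components = sorted(nx.connected_components(g), key=len, reverse=True)
    if len(components) > 1:
        dropped = sum(len(c) for c in components[1:])
        logger.info("retained largest component (%d nodes); dropped %d nodes in %d smaller components",
                    len(components[0]), dropped, len(components) - 1)
    g = g.subgraph(components[0]).copy()

    n_unscored = 0
    for node in g.nodes:
        gs = gene_scores.get(node)
        if gs is None:
            g.nodes[node].update(fisher_score=0.0, combined_p=1.0, no_data=True)
            n_unscored += 1
        else:
            g.nodes[node].update(
                fisher_score=float(gs.fisher_score),
                combined_p=float(gs.combined_p),
                no_data=False,
            )
    if n_unscored:
        logger.info("%d network nodes have no gene score (kept with p = 1)", n_unscored)
    missing_from_network = set(gene_scores) - set(g.nodes)
    if missing_from_network:
        logger.info("%d scored genes are absent from the network", len(missing_from_network))
    return g


def _edge_weights(g: nx.Graph) -> list[float]:
    """Edge weight = 1 + mean of endpoint scores normalized to [0, 1] by the max."""
    scores = {n: g.nodes[n].get("fisher_score", 0.0) for n in g.nodes}
    max_score = max(scores.values()) if scores else 0.0
    if max_score <= 0:
        return [(u, v, 1.0) for u, v in g.edges]
    return [
        (u, v, 1.0 + 0.5 * (scores[u] + scores[v]) / max_score)
        for u, v in g.edges
    ]


def _spinglass_communities(g: nx.Graph, gamma: float, seed: int) -> list[set[str]]:
    nodes = list(g.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    weighted = _edge_weights(g)
    igg = ig.Graph(
        n=len(nodes),
        edges=[(index[u], index[v]) for u, v, _ in weighted],
    )
    weights = [w for _, _, w in weighted]
    _pyrandom.seed(seed)  # igraph's default RNG is Python's random module
    clustering = igg.community_spinglass(weights=weights, gamma=gamma)
    return [{nodes[i] for i in community} for community in clustering]


def spinglass_modules(
    network: nx.Graph,
    gamma: float = SPINGLASS_GAMMA,
    min_size: int = MODULE_MIN_SIZE,
    max_size: int = MODULE_MAX_SIZE,
    seed: int | None = None,
) -> list[Module]:
    """Spin-glass community detection with score-uplifted edge weights.

    Communities outside [min_size, max_size] are handled as follows:
    undersized ones are discarded; oversized ones get one recursive
    spin-glass re-split, after which still-oversized pieces are discarded.
    Disconnected communities (rare) are split into their components first.
    Returns modules with chi-square significance attached, in rank order.
    """
    if network.number_of_nodes() < min_size:
        raise ValueError("network smaller than the minimum module size")
    if not nx.is_connected(network):
        raise ValueError("network must be connected (use build_scored_network)")
    base_seed = 0 if seed is None else int(seed)

    communities = _spinglass_communities(network, gamma, base_seed)
    kept: list[set[str]] = []
    for ci, comm in enumerate(communities):
        parts = [set(c) for c in nx.connected_components(network.subgraph(comm))]
        for part in parts:
            if len(part) < min_size:
                continue
            if len(part) <= max_size:
                kept.append(part)
                continue
            # one recursive re-split of an oversized community
            sub = network.subgraph(part)
            try:
                sub_comms = _spinglass_communities(sub, gamma, base_seed + ci + 1)
            except ig.InternalError:
                logger.warning("re-split failed for oversized community of %d genes", len(part))
                continue
            for sc in sub_comms:
                for piece in nx.connected_components(sub.subgraph(sc)):
                    piece = set(piece)
                    if min_size <= len(piece) <= max_size:
                        kept.append(piece)
                    elif len(piece) > max_size:
                        logger.info("discarded still-oversized community (%d genes)", len(piece))
    if not kept:
        logger.warning("no community within size bounds [%d, %d]", min_size, max_size)

    p_map = {n: network.nodes[n]["combined_p"] for n in network.nodes}
    s_map = {n: network.nodes[n]["fisher_score"] for n in network.nodes}
    modules = []
    for i, genes in enumerate(sorted(kept, key=lambda s: sorted(s))):
        chi2, df, p = module_significance(genes, p_map)
        modules.append(
            Module(
                module_id=f"M{i + 1:03d}",
                genes=frozenset(genes),
                chi2_stat=chi2,
                df=df,
                p_value=p,
                mean_score=float(np.mean([s_map[g] for g in genes])),
            )
        )
    return rank_modules(modules)


def greedy_mwcs(network: nx.Graph, score_offset: float) -> Module:
    """Greedy maximum-weight connected subgraph on offset node scores.

    Node weights are ``fisher_score - score_offset`` (the offset is typically
    the bootstrap background quantile, making background genes negative).
    Starting from the maximum-weight node, the subgraph repeatedly absorbs
    the positive-weight node reachable along the cheapest path of
    intermediate nodes — so a negative "bridge" gene is crossed when the gain
    at the far end pays for it — while the total weight increases. When every
    weight is negative the single best node is returned.
    """
    w = {n: network.nodes[n].get("fisher_score", 0.0) - score_offset for n in network.nodes}
    start = max(w, key=lambda n: (w[n], n))
    selected = {start}
    total = w[start]

    while True:
        best_gain, best_path = 0.0, None
        # Dijkstra from the selected set with node cost max(0, -w)
        dist: dict[str, float] = {}
        parent: dict[str, str | None] = {}
        heap: list[tuple[float, str]] = []
        for s in selected:
            for nb in network.neighbors(s):
                if nb in selected:
                    continue
                c = max(0.0, -w[nb])
                if nb not in dist or c < dist[nb]:
                    dist[nb] = c
                    parent[nb] = None
                    heapq.heappush(heap, (c, nb))
        done: set[str] = set()
        while heap:
            c, v = heapq.heappop(heap)
            if v in done or c > dist.get(v, np.inf):
                continue
            done.add(v)
            if w[v] > 0:
                # gain of absorbing v along its cheapest path
                path = [v]
                u = parent[v]
                while u is not None:
                    path.append(u)
                    u = parent[u]
                gain = sum(w[x] for x in path)
                if gain > best_gain + 1e-12:
                    best_gain, best_path = gain, path
            for nb in network.neighbors(v):
                if nb in selected or nb in done:
                    continue
                nc = c + max(0.0, -w[nb])
                if nc < dist.get(nb, np.inf):
                    dist[nb] = nc
                    parent[nb] = v
                    heapq.heappush(heap, (nc, nb))
        if best_path is None:
            break
        selected.update(best_path)
        total += best_gain

    p_map = {n: network.nodes[n]["combined_p"] for n in network.nodes}
    s_map = {n: network.nodes[n]["fisher_score"] for n in network.nodes}
    chi2, df, p = module_significance(selected, p_map)
    return Module(
        module_id="MWCS",
        genes=frozenset(selected),
        chi2_stat=chi2,
        df=df,
        p_value=p,
        mean_score=float(np.mean([s_map[g] for g in selected])),
        modularity_contribution=total,
    )


def module_significance(genes, combined_p: dict[str, float]) -> tuple[float, int, float]:
    """Fisher aggregate significance of a module: -2 sum(ln p) vs chi-square(2k)."""
    ps = np.asarray([combined_p[g] for g in genes], dtype=float)
    chi2 = float(-2.0 * np.sum(np.log(ps)))
    df = 2 * len(ps)
    return chi2, df, float(stats.chi2.sf(chi2, df))


def rank_modules(modules: list[Module]) -> list[Module]:
    """Ascending p-value; ties broken by descending mean score then module id."""
    return sorted(modules, key=lambda m: (m.p_value, -m.mean_score, m.module_id))


def modules_to_frames(modules: list[Module]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(per-gene table, per-module summary table) for TSV export."""
    gene_rows, summary_rows = [], []
    for m in modules:
        summary_rows.append(
            {"module_id": m.module_id, "k": len(m.genes), "chi2": m.chi2_stat,
             "df": m.df, "p_value": m.p_value, "mean_score": m.mean_score}
        )
        for g in sorted(m.genes):
            gene_rows.append({"module_id": m.module_id, "gene": g})
    return pd.DataFrame(gene_rows), pd.DataFrame(summary_rows)
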