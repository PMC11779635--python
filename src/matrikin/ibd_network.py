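"""Weighted inter-site IBD graphs and consensus community detection.

Sites are nodes; the edge weight between two sites is the average total IBD
(cM) over all cross-site individual pairs, with pairs below a pruning
threshold contributing zero. Community structure is found by running the
Leiden algorithm many times with different seeds, averaging the resulting
partitions into a co-assignment matrix, taking the connected components of
the matrix thresholded at 0.5 as the consensus partition (refined
hierarchically at increasing thresholds), and summarising the runs as a
maximum-clade-credibility tree whose clade supports are the frequencies of
each cluster across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import igraph as ig
import leidenalg
import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigError


def build_site_graph(
    pairs: pd.DataFrame,
    metadata: pd.DataFrame,
    min_pair_cm: float = 12.0,
    min_site_n: int = 2,
) -> nx.Graph:
    """Weighted graph of average between-site IBD sharing.

    Edge weight = sum over cross-site pairs of total_ibd_cm (pairs below
    ``min_pair_cm`` contribute 0) divided by the number of cross-site
    individual pairs. The within-site average is stored as the node
    attribute ``within_avg_cm`` (None for single-individual sites, which are
    flagged ``small=True`` along with any site below ``min_site_n``).
    """
    graph = nx.Graph()
    site_sizes = metadata.groupby("site")["id"].count()
    site_of = metadata.set_index("id")["site"]
    for site, n in site_sizes.items():
        graph.add_node(str(site), n=int(n), small=bool(n < min_site_n),
                       within_avg_cm=None)

    totals: dict[tuple[str, str], float] = {}
    if len(pairs):
        kept = pairs[pairs["total_ibd_cm"] >= min_pair_cm]
        for row in kept.itertuples():
            s1 = site_of.get(row.id1)
            s2 = site_of.get(row.id2)
            if s1 is None or s2 is None:
                continue
            key = tuple(sorted((str(s1), str(s2))))
            totals[key] = totals.get(key, 0.0) + float(row.total_ibd_cm)

    for (s1, s2), total in totals.items():
        n1, n2 = int(site_sizes[s1]), int(site_sizes[s2])
        if s1 == s2:
            n_pairs = n1 * (n1 - 1) // 2
            if n_pairs:
                graph.nodes[s1]["within_avg_cm"] = total / n_pairs
        else:
            graph.add_edge(s1, s2, weight=total / (n1 * n2))
    return graph


def _to_igraph(graph: nx.Graph) -> tuple[ig.Graph, list[str]]:
    nodes = sorted(graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in graph.edges]
    weights = [graph.edges[u, v].get("weight", 1.0) for u, v in graph.edges]
    g = ig.Graph(n=len(nodes), edges=edges)
    g.es["weight"] = weights
    return g, nodes


def choose_resolution(
    graph: nx.Graph,
    candidates: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8, 1.0, 1.2, 1.5, 2.0),
    seed: int = 0,
) -> float:
    """Plateau heuristic: the resolution in the middle of the longest run of
    candidates yielding the same number of clusters."""
    g, _ = _to_igraph(graph)
    counts = [
        len(leidenalg.find_partition(
            g, leidenalg.RBConfigurationVertexPartition,
            weights="weight" if g.ecount() else None,
            resolution_parameter=res, seed=seed,
        ))
        for res in candidates
    ]
    best_start, best_len = 0, 1
    start = 0
    for i in range(1, len(counts) + 1):
        if i == len(counts) or counts[i] != counts[start]:
            if i - start > best_len:
                best_start, best_len = start, i - start
            start = i
    return candidates[best_start + best_len // 2]


@dataclass
class ConsensusClustering:
    """Output of repeated Leiden runs plus their consensus."""

    nodes: list[str]
    memberships: list[list[int]]  # one membership vector per run
    seeds: list[int]
    coassignment: np.ndarray  # fraction of runs placing i and j together
    clusters: list[list[str]]  # consensus partition, size-ordered
    hierarchy: list  # nested [threshold, [subtrees-or-leaves]] refinement
    resolution: float
    clade_support: dict[frozenset, float]
    mcc_run: int

    def membership_of(self, run: int) -> dict[str, int]:
        return dict(zip(self.nodes, self.memberships[run]))


def _components_at(coassign: np.ndarray, idx: list[int], threshold: float) -> list[list[int]]:
    sub = nx.Graph()
    sub.add_nodes_from(idx)
    for ii, i in enumerate(idx):
        for j in idx[ii + 1:]:
            if coassign[i, j] >= threshold:
                sub.add_edge(i, j)
    return [sorted(c) for c in nx.connected_components(sub)]


def _refine(coassign: np.ndarray, idx: list[int], thresholds: list[float], level: int):
    """Nested splits of one consensus component at increasing thresholds."""
    if len(idx) == 1 or level >= len(thresholds):
        return idx
    parts = _components_at(coassign, idx, thresholds[level])
    if len(parts) == 1:
        return _refine(coassign, idx, thresholds, level + 1)
    return [_refine(coassign, p, thresholds, level + 1) for p in parts]


def consensus_leiden(
    graph: nx.Graph,
    n_runs: int = 100,
    resolution: float | None = None,
    seeds: list[int] | None = None,
) -> ConsensusClustering:
    """Run Leiden ``n_runs`` times and build the consensus partition and
    maximum-clade-credibility summary.

    Consensus clusters are the connected components of the co-assignment
    matrix thresholded at 0.5, refined hierarchically at 0.75 and 1.0. The
    MCC run is the one whose clusters maximise the summed log frequency of
    occurrence across all runs (clade support); ties break on the
    lexicographically smallest serialised partition.
    """
    if n_runs < 2:
        raise ConfigError("consensus needs at least two runs")
    g, nodes = _to_igraph(graph)
    n = len(nodes)
    if seeds is None:
        seeds = list(range(n_runs))
    elif len(seeds) != n_runs:
        raise ConfigError("need one seed per run")
    if resolution is None:
        resolution = choose_resolution(graph)

    memberships = []
    coassign = np.zeros((n, n))
    for seed in seeds:
        part = leidenalg.find_partition(
            g, leidenalg.RBConfigurationVertexPartition,
            weights="weight" if g.ecount() else None,
            resolution_parameter=resolution, seed=int(seed),
        )
        mem = list(part.membership)
        memberships.append(mem)
        mem_arr = np.array(mem)
        coassign += (mem_arr[:, None] == mem_arr[None, :]).astype(float)
    coassign /= n_runs
    np.fill_diagonal(coassign, 1.0)

    comp = _components_at(coassign, list(range(n)), 0.5)
    clusters = [[nodes[i] for i in c] for c in comp]
    clusters.sort(key=lambda c: (-len(c), min(c)))
    hierarchy = [_refine(coassign, c, [0.75, 1.0], 0) for c in comp]

    # clade support: frequency of each leaf-set across runs
    support: dict[frozenset, float] = {}
    run_clades = []
    for mem in memberships:
        clades = {}
        for i, m in enumerate(mem):
            clades.setdefault(m, set()).add(nodes[i])
        fs = [frozenset(c) for c in clades.values()]
        run_clades.append(fs)
        for c in fs:
            support[c] = support.get(c, 0.0) + 1.0 / n_runs

    def run_score(fs: list[frozenset]) -> float:
        return sum(math.log(support[c]) for c in fs)

    def run_key(fs: list[frozenset]) -> str:
        return ";".join(sorted(",".join(sorted(c)) for c in fs))

    mcc_run = min(
        range(n_runs),
        key=lambda r: (-run_score(run_clades[r]), run_key(run_clades[r])),
    )
    return ConsensusClustering(
        nodes=nodes, memberships=memberships, seeds=list(seeds),
        coassignment=coassign, clusters=clusters, hierarchy=hierarchy,
        resolution=resolution, clade_support=support, mcc_run=mcc_run,
    )


def consensus_newick(consensus: ConsensusClustering) -> str:
    """Newick string of the MCC run's partition, clades annotated with
    support (fraction of runs containing the identical cluster)."""
    mem = consensus.memberships[consensus.mcc_run]
    clades: dict[int, list[str]] = {}
    for node, m in zip(consensus.nodes, mem):
        clades.setdefault(m, []).append(node)
    parts = []
    for leaves in sorted(clades.values(), key=lambda c: (-len(c), min(c))):
        sup = consensus.clade_support[frozenset(leaves)]
        inner = ",".join(sorted(leaves))
        if len(leaves) == 1:
            parts.append(inner)
        else:
            parts.append(f"({inner}){sup:.2f}")
    return f"({','.join(parts)});"


def export_clusters(
    consensus: ConsensusClustering,
    geo: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, str]:
    """Cluster table (stable ids, size-ordered) and annotated newick tree.

    ``geo`` may carry per-site ``latitude``/``longitude`` columns keyed by
    ``site``; they are joined onto the table when present.
    """
    rows = []
    for k, members in enumerate(consensus.clusters, start=1):
        for site in sorted(members):
            rows.append({"site": site, "cluster": f"C{k}", "cluster_size": len(members)})
    table = pd.DataFrame(rows)
    if geo is not None and {"site", "latitude", "longitude"} <= set(geo.columns):
        table = table.merge(geo[["site", "latitude", "longitude"]], on="site", how="left")
    return table, consensus_newick(consensus)
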