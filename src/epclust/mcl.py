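"""Markov clustering of similarity graphs into protein families.

Implements the flow-simulation clustering used to cut reciprocal-best-hit
graphs into families: build a column-stochastic transition matrix with
self-loops, then iterate expansion (matrix squaring) and inflation
(entrywise power followed by column renormalization), pruning tiny entries,
until the matrix converges.  Clusters are read off the attractor structure.
Connected components are clustered independently (flow cannot cross a gap),
which keeps the dense linear algebra limited to component size.

Family-level filters mirror the survey conventions: prokaryotic families need
at least five sequences, eukaryotic families must span at least two species.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import networkx as nx
import numpy as np

__all__ = ["ProteinFamily", "mcl_cluster", "filter_families", "split_join_distance"]


@dataclass
class ProteinFamily:
    family_id: str
    domain: str
    members: List[str]
    genomes: List[str]

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def n_species(self) -> int:
        return len(set(self.genomes))


def _mcl_component(
    nodes: List[str],
    graph: nx.Graph,
    inflation: float,
    prune_threshold: float,
    max_iter: int,
    tol: float,
) -> List[Set[str]]:
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    M = np.zeros((n, n))
    for u, v, data in graph.edges(nodes, data=True):
        if u in index and v in index:
            w = float(data.get("weight", 1.0))
            M[index[u], index[v]] = w
            M[index[v], index[u]] = w
    # self-loop regularization: loop weight = max incident edge weight
    for i in range(n):
        inc = M[:, i]
        M[i, i] = inc.max() if inc.max() > 0 else 1.0
    M /= M.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        prev = M
        M = M @ M  # expansion
        M = np.power(M, inflation)  # inflation
        M[M < prune_threshold] = 0.0
        colsum = M.sum(axis=0, keepdims=True)
        colsum[colsum == 0.0] = 1.0
        M /= colsum
        if np.abs(M - prev).max() < tol:
            break
    # attractors: nodes with appreciable return flow
    attractors = [i for i in range(n) if M[i, i] > tol]
    if not attractors:
        attractors = [int(np.argmax(M.diagonal()))]
    # each node joins the attractor receiving most of its flow; ties -> the
    # attractor containing the lexicographically smallest node
    clusters: Dict[int, Set[str]] = {a: set() for a in attractors}
    # merge attractor systems that share flow (rows of attractors overlap)
    parent = {a: a for a in attractors}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a in attractors:
        for b in attractors:
            if a < b and (M[a, b] > tol or M[b, a] > tol):
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra
    systems: Dict[int, List[int]] = {}
    for a in attractors:
        systems.setdefault(find(a), []).append(a)
    sys_roots = sorted(systems)
    for j, v in enumerate(nodes):
        flows = np.array([sum(M[a, j] for a in systems[r]) for r in sys_roots])
        if flows.max() <= 0.0:
            # no flow retained (heavy pruning): keep the node as a singleton
            clusters.setdefault(-(j + 1), set()).add(v)
            continue
        top = np.nonzero(flows == flows.max())[0]
        chosen = min(
            (min(nodes[a] for a in systems[sys_roots[t]]), sys_roots[t]) for t in top
        )[1]
        clusters.setdefault(chosen, set()).add(v)
    return [c for c in clusters.values() if c]


def mcl_cluster(
    graph: nx.Graph,
    inflation: float = 2.0,
    prune_threshold: float = 1e-5,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> List[Set[str]]:
    """Partition the nodes of a weighted similarity graph by Markov clustering.

    Every node lands in exactly one cluster; singletons are allowed (isolated
    nodes always become singletons).  Raises on an empty graph, non-finite
    edge weights, or inflation <= 1.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if inflation <= 1.0:
        raise ValueError("inflation must exceed 1")
    for _, _, data in graph.edges(data=True):
        w = data.get("weight", 1.0)
        if not np.isfinite(w) or w <= 0:
            raise ValueError("edge weights must be finite and positive")
    clusters: List[Set[str]] = []
    for comp in nx.connected_components(graph):
        nodes = sorted(comp)
        if len(nodes) == 1:
            clusters.append(set(nodes))
            continue
        clusters.extend(
            _mcl_component(nodes, graph, inflation, prune_threshold, max_iter, tol)
        )
    # deterministic output order, independent of input ordering
    clusters.sort(key=lambda c: min(c))
    assigned = [v for c in clusters for v in c]
    if len(assigned) != graph.number_of_nodes() or len(set(assigned)) != len(assigned):
        raise AssertionError("clustering did not produce a partition")
    return clusters


def filter_families(
    partition: Iterable[Set[str]],
    domain: str,
    genome_map: Mapping[str, str],
    min_prok_family_size: int = 5,
    min_euk_species: int = 2,
    prefix: str = "",
) -> Tuple[List[ProteinFamily], List[Set[str]]]:
    """Apply the survey's family-retention filters to an MCL partition.

    Prokaryotic (bacteria/archaea) clusters below ``min_prok_family_size``
    sequences and eukaryotic clusters spanning fewer than ``min_euk_species``
    species are dropped; dropped clusters are returned for the exclusion log.
    """
    if domain not in ("bacteria", "archaea", "eukaryote"):
        raise ValueError(f"unknown domain label: {domain}")
    kept: List[ProteinFamily] = []
    dropped: List[Set[str]] = []
    fid = 0
    for cluster in sorted((sorted(c) for c in partition), key=lambda c: c[0]):
        missing = [m for m in cluster if m not in genome_map]
        if missing:
            raise KeyError(f"members without genome mapping: {missing[:5]}")
        genomes = [genome_map[m] for m in cluster]
        if domain == "eukaryote":
            ok = len(set(genomes)) >= min_euk_species
        else:
            ok = len(cluster) >= min_prok_family_size
        if ok:
            fid += 1
            tag = {"bacteria": "B", "archaea": "A", "eukaryote": "E"}[domain]
            kept.append(
                ProteinFamily(f"{prefix}{tag}{fid:05d}", domain, list(cluster), genomes)
            )
        else:
            dropped.append(set(cluster))
    return kept, dropped


def write_abc(graph: nx.Graph, path) -> None:
    """Write a weighted edge list in the whitespace-separated ABC format."""
    with open(path, "w") as fh:
        for u, v, data in sorted(graph.edges(data=True)):
            fh.write(f"{u}\t{v}\t{data.get('weight', 1.0):g}\n")


def read_abc(path) -> nx.Graph:
    """Read an ABC-format edge list (node node weight per line)."""
    g = nx.Graph()
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            u, v = parts[0], parts[1]
            w = float(parts[2]) if len(parts) > 2 else 1.0
            g.add_edge(u, v, weight=w)
    return g


def split_join_distance(
    partition_a: Iterable[Set[str]], partition_b: Iterable[Set[str]]
) -> int:
    """van Dongen's split/join distance between two partitions of one node set.

    d(A,B) = 2n - sum_max_overlap(A->B) - sum_max_overlap(B->A); 0 iff the
    partitions are identical.  Provided as the comparison utility used when
    tuning large-scale clusterings for stability.
    """
    a = [set(c) for c in partition_a]
    b = [set(c) for c in partition_b]
    na = {v for c in a for v in c}
    nb = {v for c in b for v in c}
    if na != nb:
        raise ValueError("partitions cover different node sets")
    n = len(na)

    def proj(p, q):
        return sum(max((len(c & d) for d in q), default=0) for c in p)

    return 2 * n - proj(a, b) - proj(b, a)
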