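"""Markov Cluster (MCL) algorithm on the ORF similarity graph.

Canonical MCL: the weighted adjacency matrix (with self-loops) is made
column-stochastic and iterated through expansion (matrix power), inflation
(element-wise power followed by column renormalisation) and pruning of tiny
entries until the flow matrix converges.  Attractors (nodes with positive
return flow) define the clusters; nodes attracted to more than one attractor
system are assigned to the one receiving the most flow.

Clusters of size 1, and nodes isolated in the input graph, are reported as
singletons: a protein cluster proper has at least two members.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse

from .datamodel import GenomeSet

log = logging.getLogger(__name__)


@dataclass
class ClusterSet:
    """A partition of the ORF universe into protein clusters (size >= 2) and
    singletons."""

    clusters: dict[str, frozenset[str]]
    singletons: frozenset[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        seen: set[str] = set()
        for cid, members in self.clusters.items():
            if len(members) < 2:
                raise ValueError(f"cluster {cid} has fewer than 2 members")
            if seen & members:
                raise ValueError("clusters are not disjoint")
            seen |= members
        if seen & self.singletons:
            raise ValueError("singleton listed inside a cluster")

    @property
    def all_orfs(self) -> frozenset[str]:
        out: set[str] = set(self.singletons)
        for m in self.clusters.values():
            out |= m
        return frozenset(out)

    @property
    def n_clustered(self) -> int:
        return sum(len(m) for m in self.clusters.values())

    def cluster_of(self) -> dict[str, str]:
        """orf_id -> cluster_id map (singletons absent)."""
        return {o: cid for cid, mem in self.clusters.items() for o in mem}

    def assert_partition_of(self, universe: set[str] | frozenset[str]) -> None:
        if self.all_orfs != frozenset(universe):
            missing = set(universe) - self.all_orfs
            extra = self.all_orfs - set(universe)
            raise AssertionError(
                f"cluster partition broken: missing={sorted(missing)[:5]} extra={sorted(extra)[:5]}"
            )


def _stochastic(M: sparse.csr_matrix) -> sparse.csr_matrix:
    colsum = np.asarray(M.sum(axis=0)).ravel()
    colsum[colsum == 0] = 1.0
    D = sparse.diags(1.0 / colsum)
    return (M @ D).tocsr()


def _inflate(M: sparse.csr_matrix, r: float) -> sparse.csr_matrix:
    M = M.copy()
    M.data = np.power(M.data, r)
    return _stochastic(M)


def _prune(M: sparse.csr_matrix, threshold: float) -> sparse.csr_matrix:
    M = M.copy()
    M.data[M.data < threshold] = 0.0
    M.eliminate_zeros()
    return _stochastic(M)


def mcl(
    graph: nx.Graph,
    inflation: float = 1.5,
    expansion: int = 2,
    tol: float = 1e-6,
    max_iter: int = 200,
    prune_threshold: float = 1e-5,
) -> ClusterSet:
    """Run MCL on a weighted similarity graph and return the partition.

    Self-loops are added with weight equal to the node's maximum incident
    edge weight (1.0 for isolated nodes) before normalisation.  The node
    ordering is the sorted node-id order, so the result is deterministic and
    invariant to input-graph construction order.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    nodes = sorted(graph.nodes())
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    rows, cols, vals = [], [], []
    for a, b, w in graph.edges(data="weight", default=1.0):
        if a == b:
            continue
        rows += [idx[a], idx[b]]
        cols += [idx[b], idx[a]]
        vals += [float(w), float(w)]
    A = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
    maxw = np.asarray(A.max(axis=0).todense()).ravel() if A.nnz else np.zeros(n)
    maxw[maxw == 0] = 1.0
    A = (A + sparse.diags(maxw)).tocsr()
    M = _stochastic(A)
    converged = False
    for _ in range(max_iter):
        prev = M.copy()
        M = M ** expansion
        M = _inflate(M, inflation)
        M = _prune(M, prune_threshold)
        delta = abs(M - prev)
        if delta.nnz == 0 or delta.max() < tol:
            converged = True
            break
    if not converged:
        log.warning("MCL did not converge within %d iterations; returning current partition", max_iter)
    clusters, singleton_nodes = _interpret(M, nodes)
    cs = ClusterSet(
        clusters,
        frozenset(singleton_nodes),
        provenance={
            "method": "mcl",
            "inflation": inflation,
            "expansion": expansion,
            "tol": tol,
            "max_iter": max_iter,
            "prune_threshold": prune_threshold,
            "converged": converged,
            "merge_history": [],
        },
    )
    cs.assert_partition_of(set(nodes))
    return cs


def _interpret(M: sparse.csr_matrix, nodes: list[str]) -> tuple[dict[str, frozenset[str]], list[str]]:
    """Clusters from a converged flow matrix.

    Attractors are nodes with positive diagonal flow; attractors flowing into
    each other form an attractor system; every other node joins the system of
    the attractor from which it receives the most flow (ties: lexicographic).
    """
    n = len(nodes)
    M = M.tocsr()
    diag = M.diagonal()
    attractors = np.flatnonzero(diag > 1e-8)
    if attractors.size == 0:  # pathological; treat every node as its own
        attractors = np.arange(n)
    # union attractor systems: i ~ j if flow in either direction
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    aset = set(attractors.tolist())
    Mcoo = M.tocoo()
    for i, j, v in zip(Mcoo.row, Mcoo.col, Mcoo.data):
        if v > 1e-8 and i in aset and j in aset and i != j:
            union(int(i), int(j))
    # assign non-attractors to the attractor system with the largest inflow
    Mcsc = M.tocsc()
    assign: dict[int, int] = {int(a): find(int(a)) for a in attractors}
    for j in range(n):
        if j in assign:
            continue
        col = Mcsc.getcol(j)
        best_sys, best_flow = None, 0.0
        for i, v in zip(col.indices, col.data):
            if int(i) in aset and v > best_flow + 1e-15:
                best_flow = v
                best_sys = find(int(i))
            elif int(i) in aset and abs(v - best_flow) <= 1e-15 and best_sys is not None:
                best_sys = min(best_sys, find(int(i)))
        assign[j] = best_sys if best_sys is not None else j
    groups: dict[int, set[str]] = {}
    for node_i, sys_i in assign.items():
        groups.setdefault(sys_i, set()).add(nodes[node_i])
    clusters: dict[str, frozenset[str]] = {}
    singletons: list[str] = []
    # deterministic ids: order groups by their lexicographically first member
    for k, members in enumerate(sorted(groups.values(), key=lambda s: min(s))):
        if len(members) >= 2:
            clusters[f"C{k + 1:05d}"] = frozenset(members)
        else:
            singletons.extend(members)
    # renumber so ids are consecutive over actual clusters
    ordered = sorted(clusters.values(), key=lambda s: min(s))
    clusters = {f"C{i + 1:05d}": m for i, m in enumerate(ordered)}
    return clusters, singletons


def cluster_copy_numbers(cs: ClusterSet, gs: GenomeSet, k: int = 5) -> pd.DataFrame:
    """Per-(cluster, genome) member counts, in long form, plus a per-cluster
    summary column ``n_genomes_gt_k``: the number of genomes holding more
    than ``k`` members (high-copy profiling)."""
    rows = []
    gmap = {o.orf_id: o.genome_id for o in gs.orfs.values()}
    for cid in sorted(cs.clusters):
        counts: dict[str, int] = {}
        for oid in cs.clusters[cid]:
            counts[gmap[oid]] = counts.get(gmap[oid], 0) + 1
        n_gt = sum(1 for c in counts.values() if c > k)
        for gid in sorted(counts):
            rows.append(
                {
                    "cluster_id": cid,
                    "genome_id": gid,
                    "copy_number": counts[gid],
                    "n_genomes_gt_k": n_gt,
                }
            )
    return pd.DataFrame(rows, columns=["cluster_id", "genome_id", "copy_number", "n_genomes_gt_k"])


def write_cluster_table(cs: ClusterSet, gs: GenomeSet, path: str | Path) -> None:
    """TSV linking each clustered ORF to its cluster: cluster_id, orf_id, genome_id."""
    gmap = {o.orf_id: o.genome_id for o in gs.orfs.values()}
    with open(path, "w") as fh:
        fh.write("cluster_id\torf_id\tgenome_id\n")
        for cid in sorted(cs.clusters):
            for oid in sorted(cs.clusters[cid]):
                fh.write(f"{cid}\t{oid}\t{gmap[oid]}\n")
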