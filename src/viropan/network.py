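"""Bipartite genome-cluster sharing network and Jaccard profiles.

One node class holds protein clusters, the other holds entities: viral
genomes and external taxon collections.  A cluster is included when it is
shared — present in at least two genomes, or present in one genome but
linked to at least one external taxon by homology.  The Jaccard index
|A ∩ B| / |A ∪ B| over cluster-presence sets measures how similar two
genomes' (or a genome's and a taxon's) gene-content repertoires are.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .datamodel import GenomeSet
from .mcl import ClusterSet


def jaccard(a: set | frozenset, b: set | frozenset) -> float:
    """|a ∩ b| / |a ∪ b|; both sets empty is undefined."""
    if not a and not b:
        raise ValueError("Jaccard undefined for two empty sets")
    return len(set(a) & set(b)) / len(set(a) | set(b))


def _presence_sets(cs: ClusterSet, gs: GenomeSet) -> dict[str, set[str]]:
    gmap = {o.orf_id: o.genome_id for o in gs.orfs.values()}
    out: dict[str, set[str]] = {g.genome_id: set() for g in gs.genomes}
    for cid, members in cs.clusters.items():
        for oid in members:
            out[gmap[oid]].add(cid)
    return out


def _taxon_sets(cs: ClusterSet, hits: pd.DataFrame) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    if hits is None or not len(hits):
        return out
    orf_taxa: dict[str, set[str]] = {}
    for oid, tx in zip(hits["orf_id"], hits["taxon_label"]):
        orf_taxa.setdefault(oid, set()).add(tx)
    for cid, members in cs.clusters.items():
        for oid in members:
            for tx in orf_taxa.get(oid, ()):
                out.setdefault(tx, set()).add(cid)
    return out


def build_network(cs: ClusterSet, gs: GenomeSet, hits: pd.DataFrame | None = None) -> nx.Graph:
    """Bipartite cluster / entity network under the sharing inclusion rule.

    A cluster node is kept iff it occurs in >= 2 genomes, or in >= 1 genome
    and hits >= 1 external taxon.  Edges: genome-cluster when the genome has
    a member; taxon-cluster when any member hits the taxon.
    """
    genome_sets = _presence_sets(cs, gs)
    taxon_sets = _taxon_sets(cs, hits if hits is not None else pd.DataFrame())
    fam = {g.genome_id: g.family_label for g in gs.genomes}
    g = nx.Graph()
    cluster_genomes: dict[str, set[str]] = {cid: set() for cid in cs.clusters}
    for gid, cids in genome_sets.items():
        for cid in cids:
            cluster_genomes[cid].add(gid)
    cluster_taxa: dict[str, set[str]] = {cid: set() for cid in cs.clusters}
    for tx, cids in taxon_sets.items():
        for cid in cids:
            cluster_taxa[cid].add(tx)
    for cid in sorted(cs.clusters):
        if len(cluster_genomes[cid]) >= 2 or cluster_taxa[cid]:
            g.add_node(cid, type="cluster", bipartite=0)
            for gid in sorted(cluster_genomes[cid]):
                if gid not in g:
                    g.add_node(gid, type="genome", bipartite=1, family_label=fam[gid])
                g.add_edge(cid, gid)
            for tx in sorted(cluster_taxa[cid]):
                if tx not in g:
                    g.add_node(tx, type="taxon", bipartite=1)
                g.add_edge(cid, tx)
    return g


def assert_bipartite(g: nx.Graph) -> None:
    for a, b in g.edges():
        if g.nodes[a]["bipartite"] == g.nodes[b]["bipartite"]:
            raise AssertionError(f"edge within one node class: {a} -- {b}")


def jaccard_profiles(
    cs: ClusterSet, gs: GenomeSet, hits: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genome x genome and genome x taxon Jaccard matrices over
    cluster-presence sets.

    A genome with no clustered ORF gets a zero row (with a warning); the
    genome x genome diagonal is 1 by convention even then.
    """
    import logging

    genome_sets = _presence_sets(cs, gs)
    taxon_sets = _taxon_sets(cs, hits if hits is not None else pd.DataFrame())
    gids = gs.genome_ids
    for gid in gids:
        if not genome_sets[gid]:
            logging.getLogger(__name__).warning(
                "genome %s has no clustered ORFs; Jaccard row is zero", gid
            )
    gg = np.zeros((len(gids), len(gids)))
    for i, a in enumerate(gids):
        gg[i, i] = 1.0
        for j in range(i + 1, len(gids)):
            b = gids[j]
            sa, sb = genome_sets[a], genome_sets[b]
            v = jaccard(sa, sb) if (sa or sb) else 0.0
            gg[i, j] = gg[j, i] = v
    taxa = sorted(taxon_sets)
    gt = np.zeros((len(gids), len(taxa)))
    for i, a in enumerate(gids):
        for j, tx in enumerate(taxa):
            sa, st = genome_sets[a], taxon_sets[tx]
            gt[i, j] = jaccard(sa, st) if (sa or st) else 0.0
    return (
        pd.DataFrame(gg, index=gids, columns=gids),
        pd.DataFrame(gt, index=gids, columns=taxa),
    )


def write_network(g: nx.Graph, graphml_path: str | Path, edgelist_path: str | Path) -> None:
    nx.write_graphml(g, graphml_path)
    with open(edgelist_path, "w") as fh:
        fh.write("node_a\tnode_b\n")
        for a, b in sorted(g.edges()):
            fh.write(f"{a}\t{b}\n")
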