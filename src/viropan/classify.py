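"""Exhaustive ORF classification and cluster sharing statistics.

Every ORF falls in exactly one of four categories, crossing cluster
membership with external homology:

* ``clustered_internal_only``   — in a cluster, no member of the cluster has
  a qualifying hit to any external reference collection;
* ``clustered_with_external``   — in a cluster, at least one member hits;
* ``singleton_internal_only``   — unclustered, no external hit itself;
* ``singleton_with_external``   — unclustered, with an external hit.

Cluster-level sharing statistics count genomes and virus family/groups per
cluster, flag the core gene set (clusters in strictly more than
``core_family_min`` families), the universal clusters (present in every
genome), and the family-restricted clusters (shared by two or more virus
families but without similarity to anything outside the genome set).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .datamodel import GenomeSet, PipelineConfig
from .mcl import ClusterSet

CATEGORIES = [
    "clustered_internal_only",
    "clustered_with_external",
    "singleton_internal_only",
    "singleton_with_external",
]


@dataclass(frozen=True)
class OrfCategory:
    orf_id: str
    genome_id: str
    in_cluster: bool
    external_homologue: bool

    @property
    def category(self) -> str:
        if self.in_cluster:
            return "clustered_with_external" if self.external_homologue else "clustered_internal_only"
        return "singleton_with_external" if self.external_homologue else "singleton_internal_only"


def classify_orfs(
    cs: ClusterSet, gs: GenomeSet, hits: pd.DataFrame
) -> tuple[list[OrfCategory], pd.DataFrame]:
    """Assign every ORF its single category; also return the per-genome
    proportion table (one row per genome, one column per category, rows
    summing to 1).

    For a clustered ORF, external homology is decided at cluster level: any
    member with a qualifying best hit makes the whole cluster externally
    linked.  Singletons are judged on their own hits.
    """
    universe = set(gs.orfs)
    cs.assert_partition_of(universe)
    orfs_with_hits = set(hits["orf_id"]) if len(hits) else set()
    cluster_external = {
        cid: bool(members & orfs_with_hits) for cid, members in cs.clusters.items()
    }
    cluster_of = cs.cluster_of()
    cats: list[OrfCategory] = []
    for g in gs.genomes:
        for oid in g.orf_ids:
            cid = cluster_of.get(oid)
            if cid is not None:
                cats.append(OrfCategory(oid, g.genome_id, True, cluster_external[cid]))
            else:
                cats.append(OrfCategory(oid, g.genome_id, False, oid in orfs_with_hits))
    df = pd.DataFrame(
        [{"genome_id": c.genome_id, "category": c.category} for c in cats]
    )
    counts = (
        df.groupby(["genome_id", "category"]).size().unstack(fill_value=0)
        .reindex(columns=CATEGORIES, fill_value=0)
        .reindex(index=[g.genome_id for g in gs.genomes])
    )
    props = counts.div(counts.sum(axis=1), axis=0)
    return cats, props


@dataclass(frozen=True)
class ClusterSharingRecord:
    cluster_id: str
    n_genomes: int
    n_families: int
    taxa_with_hits: frozenset[str]
    is_core: bool
    is_universal: bool


def sharing_records(
    cs: ClusterSet,
    gs: GenomeSet,
    hits: pd.DataFrame,
    cfg: PipelineConfig | None = None,
) -> list[ClusterSharingRecord]:
    """Per-cluster genome/family spread, external-taxon links, core and
    universal flags."""
    cfg = cfg or PipelineConfig()
    fam = {g.genome_id: g.family_label for g in gs.genomes}
    gmap = {o.orf_id: o.genome_id for o in gs.orfs.values()}
    n_genomes_total = len(gs.genomes)
    taxa_by_orf: dict[str, set[str]] = {}
    if len(hits):
        for oid, tx in zip(hits["orf_id"], hits["taxon_label"]):
            taxa_by_orf.setdefault(oid, set()).add(tx)
    records = []
    for cid in sorted(cs.clusters):
        members = cs.clusters[cid]
        genomes = {gmap[o] for o in members}
        families = {fam[g] for g in genomes}
        taxa: set[str] = set()
        for o in members:
            taxa |= taxa_by_orf.get(o, set())
        records.append(
            ClusterSharingRecord(
                cid,
                len(genomes),
                len(families),
                frozenset(taxa),
                is_core=len(families) > cfg.core_family_min,
                is_universal=len(genomes) == n_genomes_total,
            )
        )
    return records


def family_restricted_clusters(records: list[ClusterSharingRecord]) -> list[ClusterSharingRecord]:
    """Clusters shared by >= 2 virus families with no external-taxon hits:
    candidate virus-specific families."""
    return [r for r in records if r.n_families >= 2 and not r.taxa_with_hits]


def genome_count_histogram(records: list[ClusterSharingRecord]) -> pd.DataFrame:
    """How many clusters are present in exactly k genomes, for each k."""
    s = pd.Series([r.n_genomes for r in records], dtype=int)
    h = s.value_counts().sort_index()
    return pd.DataFrame({"n_genomes": h.index, "n_clusters": h.to_numpy()})


def sharing_table(records: list[ClusterSharingRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cluster_id": r.cluster_id,
                "n_genomes": r.n_genomes,
                "n_families": r.n_families,
                "taxa_with_hits": ",".join(sorted(r.taxa_with_hits)),
                "is_core": r.is_core,
                "is_universal": r.is_universal,
            }
            for r in records
        ]
    )


def category_table(cats: list[OrfCategory]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "orf_id": c.orf_id,
                "genome_id": c.genome_id,
                "in_cluster": c.in_cluster,
                "external_homologue": c.external_homologue,
                "category": c.category,
            }
            for c in cats
        ]
    )
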