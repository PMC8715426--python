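"""ORF category partition and cluster sharing statistics."""

import pandas as pd
import pytest

from viropan.classify import (
    classify_orfs,
    family_restricted_clusters,
    genome_count_histogram,
    sharing_records,
)
from viropan.datamodel import Genome, GenomeSet, ORF, PipelineConfig
from viropan.mcl import ClusterSet


def build_gs(n_families=8):
    """8 genomes in 4 family labels, one clustered family pair per genome
    plus one unique singleton ORF each."""
    orfs, genomes = {}, []
    for i in range(8):
        gid = f"g{i}"
        oids = [f"{gid}_a", f"{gid}_b"]
        for oid in oids:
            orfs[oid] = ORF(oid, gid, "MKLVVT")
        genomes.append(Genome(gid, f"fam{i % 4}", oids))
    return GenomeSet(genomes, orfs)


def hits_df(rows):
    return pd.DataFrame(rows, columns=["orf_id", "taxon_label", "subject_id", "evalue", "bit_score"])


def test_every_orf_gets_exactly_one_category():
    gs = build_gs()
    clusters = {"C1": frozenset(f"g{i}_a" for i in range(8))}
    cs = ClusterSet(clusters, frozenset(f"g{i}_b" for i in range(8)))
    hits = hits_df([("g0_b", "Eukaryota", "s", 1e-6, 40.0)])
    cats, props = classify_orfs(cs, gs, hits)
    assert len(cats) == gs.n_orfs
    by_id = {c.orf_id: c.category for c in cats}
    assert by_id["g0_a"] == "clustered_internal_only"
    assert by_id["g0_b"] == "singleton_with_external"
    assert by_id["g1_b"] == "singleton_internal_only"
    assert (abs(props.sum(axis=1) - 1.0) < 1e-9).all()


def test_cluster_level_external_homology_is_any_member():
    gs = build_gs()
    cs = ClusterSet({"C1": frozenset(f"g{i}_a" for i in range(8))},
                    frozenset(f"g{i}_b" for i in range(8)))
    hits = hits_df([("g3_a", "Bacteria", "s", 1e-8, 50.0)])
    cats, _ = classify_orfs(cs, gs, hits)
    for c in cats:
        if c.orf_id.endswith("_a"):
            assert c.category == "clustered_with_external"


def test_classification_errors_on_broken_partition():
    gs = build_gs()
    cs = ClusterSet({"C1": frozenset(["g0_a", "g1_a"])}, frozenset(["g0_b"]))
    with pytest.raises(AssertionError):
        classify_orfs(cs, gs, hits_df([]))


def test_sharing_core_universal_and_histogram():
    gs = build_gs()
    universal = frozenset(f"g{i}_a" for i in range(8))      # all 8 genomes, 4 families
    narrow = frozenset(["g0_b", "g4_b"])                     # 2 genomes, 1 family (fam0)
    cs = ClusterSet({"C1": universal, "C2": narrow},
                    frozenset(o for o in gs.orfs if o not in universal | narrow))
    cfg = PipelineConfig(core_family_min=3)
    recs = sharing_records(cs, gs, hits_df([]), cfg)
    r = {x.cluster_id: x for x in recs}
    assert r["C1"].n_genomes == 8 and r["C1"].n_families == 4
    assert r["C1"].is_core and r["C1"].is_universal
    assert r["C2"].n_families == 1 and not r["C2"].is_core and not r["C2"].is_universal
    hist = genome_count_histogram(recs)
    assert dict(zip(hist.n_genomes, hist.n_clusters)) == {2: 1, 8: 1}


def test_core_threshold_is_strict_and_monotone():
    gs = build_gs()
    members = frozenset(f"g{i}_a" for i in range(8))  # 4 distinct family labels
    cs = ClusterSet({"C1": members}, frozenset(o for o in gs.orfs if o not in members))
    sizes = []
    for k in (3, 4, 5):
        recs = sharing_records(cs, gs, hits_df([]), PipelineConfig(core_family_min=k))
        sizes.append(sum(r.is_core for r in recs))
    assert sizes[0] == 1      # 4 > 3
    assert sizes[1] == 0      # 4 > 4 is false: strict
    assert sizes == sorted(sizes, reverse=True)


def test_family_restricted_requires_two_families_and_no_hits():
    gs = build_gs()
    shared = frozenset(["g0_a", "g1_a", "g2_a"])   # 3 families
    local = frozenset(["g0_b", "g4_b"])            # 1 family
    cs = ClusterSet({"C1": shared, "C2": local},
                    frozenset(o for o in gs.orfs if o not in shared | local))
    recs = sharing_records(cs, gs, hits_df([]), PipelineConfig())
    assert [r.cluster_id for r in family_restricted_clusters(recs)] == ["C1"]
    # one external hit on any member disqualifies
    recs2 = sharing_records(cs, gs, hits_df([("g1_a", "Bacteria", "s", 1e-9, 60.0)]), PipelineConfig())
    assert family_restricted_clusters(recs2) == []


def test_no_references_forces_internal_only_categories():
    gs = build_gs()
    cs = ClusterSet({"C1": frozenset(f"g{i}_a" for i in range(8))},
                    frozenset(f"g{i}_b" for i in range(8)))
    cats, _ = classify_orfs(cs, gs, hits_df([]))
    assert {c.category for c in cats} <= {"clustered_internal_only", "singleton_internal_only"}
    recs = sharing_records(cs, gs, hits_df([]), PipelineConfig())
    assert all(not r.taxa_with_hits for r in recs)


def test_planted_family_restricted_clusters_recovered(small_fixture):
    """In the simulated fixture, clusters built from true families shared by
    both family-groups and not planted in any reference collection are
    exactly the family-restricted set."""
    truth, gs = small_fixture
    fam_members: dict[str, set] = {}
    for oid in gs.orfs:
        fam_members.setdefault(oid.split("|")[1], set()).add(oid)
    clusters = {f: frozenset(m) for f, m in fam_members.items() if len(m) >= 2}
    singles = frozenset(o for f, m in fam_members.items() if len(m) == 1 for o in m)
    cs = ClusterSet(clusters, singles)
    # planted external homologues: reference collections hold ancestors of
    # the first 12 root families
    planted = {f for refs in gs.taxon_refs.values() for r in refs for f in [r.split("_", 1)[1]]}
    from viropan.align import best_hits

    bh = best_hits(gs, PipelineConfig())
    recs = sharing_records(cs, gs, bh, PipelineConfig())
    groups = truth.family_groups
    expected = set()
    for fam, members in clusters.items():
        fams = {groups[o.split("|")[0]] for o in members}
        if len(fams) >= 2 and fam not in planted:
            expected.add(fam)
    got = {r.cluster_id for r in family_restricted_clusters(recs)}
    assert got == expected
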