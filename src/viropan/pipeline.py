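"""End-to-end orchestration: read -> similarity -> cluster -> merge ->
classify -> phylogeny -> network, with a provenance manifest.

Every stage writes its outputs before the next starts, so a failed run
leaves the completed stages on disk; the manifest records the full config,
seeds, input checksums and a checksum for every output file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import align, classify, network, phylo, profiles
from .mcl import cluster_copy_numbers, mcl as run_mcl, write_cluster_table
from .datamodel import GenomeSet, PipelineConfig, read_genome_set, summarize_genome_set

log = logging.getLogger("viropan.pipeline")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_config(path: str | Path) -> tuple[PipelineConfig, dict]:
    """Load a YAML config; keys matching PipelineConfig fields configure the
    pipeline, the rest (fasta_paths, metadata_path, taxon_refs, outdir,
    bootstrap on/off) describe inputs."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    fields = set(PipelineConfig.__dataclass_fields__)
    cfg = PipelineConfig(**{k: v for k, v in raw.items() if k in fields})
    extra = {k: v for k, v in raw.items() if k not in fields}
    return cfg, extra


def run_pipeline(
    gs: GenomeSet,
    cfg: PipelineConfig,
    outdir: str | Path,
    run_tree: bool = True,
    run_bootstrap: bool = True,
) -> dict:
    """Run every stage on a genome set; returns the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": cfg.to_dict(),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": [],
        "outputs": {},
        "complete": False,
    }
    mpath = outdir / "manifest.json"

    def checkpoint(stage: str, files: list[Path], counts: dict | None = None):
        entry = {"stage": stage, "counts": counts or {}}
        manifest["stages"].append(entry)
        for f in files:
            manifest["outputs"][f.name] = _sha256(f)
        mpath.write_text(json.dumps(manifest, indent=2, default=str))
        log.info("[%s] %s", stage, counts or "done")

    try:
        # stage: input summary
        summary = summarize_genome_set(gs)
        f = outdir / "genome_summary.tsv"
        summary.to_csv(f, sep="\t", index=False)
        checkpoint("read", [f], {"genomes": len(gs.genomes), "orfs": gs.n_orfs})

        # stage: all-vs-all similarity
        graph = align.all_vs_all(gs, cfg)
        f = outdir / "similarity_edges.tsv"
        align.write_edge_list(graph, f)
        checkpoint("all_vs_all", [f], {"nodes": graph.number_of_nodes(), "edges": graph.number_of_edges()})

        # stage: MCL clustering
        cs = run_mcl(graph, inflation=cfg.mcl_inflation, expansion=cfg.mcl_expansion,
                     tol=cfg.mcl_tol, max_iter=cfg.mcl_max_iter, prune_threshold=cfg.mcl_prune)
        cs.assert_partition_of(set(gs.orfs))
        f = outdir / "clusters_initial.tsv"
        write_cluster_table(cs, gs, f)
        checkpoint("mcl", [f], {"clusters": len(cs.clusters), "singletons": len(cs.singletons)})

        # stage: profile merge
        n_before = len(cs.clusters)
        hits_pp: list[profiles.ProfileHit] = []
        for _ in range(max(cfg.merge_rounds, 1)):
            cs2, hp = profiles.profile_merge_pass(cs, gs, cfg)
            hits_pp = hp
            if len(cs2.clusters) == len(cs.clusters):
                cs = cs2
                break
            cs = cs2
        cs.assert_partition_of(set(gs.orfs))
        f1 = outdir / "clusters.tsv"
        write_cluster_table(cs, gs, f1)
        f2 = outdir / "profile_hits.tsv"
        profiles.write_profile_hits(hits_pp, cfg, f2)
        f3 = outdir / "copy_numbers.tsv"
        cluster_copy_numbers(cs, gs, cfg.copy_number_k).to_csv(f3, sep="\t", index=False)
        checkpoint("profile_merge", [f1, f2, f3],
                   {"clusters_before": n_before, "clusters_after": len(cs.clusters)})

        # stage: external best hits + classification
        bh = align.best_hits(gs, cfg) if gs.taxon_refs else None
        bh = bh if bh is not None else pd.DataFrame(
            columns=["orf_id", "taxon_label", "subject_id", "evalue", "bit_score"]
        )
        f0 = outdir / "best_hits.tsv"
        bh.to_csv(f0, sep="\t", index=False)
        cats, props = classify.classify_orfs(cs, gs, bh)
        f1 = outdir / "orf_categories.tsv"
        classify.category_table(cats).to_csv(f1, sep="\t", index=False)
        f2 = outdir / "category_proportions.tsv"
        props.to_csv(f2, sep="\t")
        recs = classify.sharing_records(cs, gs, bh, cfg)
        f3 = outdir / "cluster_sharing.tsv"
        classify.sharing_table(recs).to_csv(f3, sep="\t", index=False)
        f4 = outdir / "genome_count_histogram.tsv"
        classify.genome_count_histogram(recs).to_csv(f4, sep="\t", index=False)
        checkpoint("classify", [f0, f1, f2, f3, f4], {
            "external_hits": int(len(bh)),
            "core_clusters": sum(r.is_core for r in recs),
            "universal_clusters": sum(r.is_universal for r in recs),
        })

        # stage: presence/absence matrix + tree
        tree_counts = {}
        files = []
        if cs.clusters:
            M = phylo.build_matrix(cs, gs)
            f1 = outdir / "presence_absence.tsv"
            M.to_tsv(f1)
            f2 = outdir / "presence_absence.phy"
            M.to_phylip(f2)
            files = [f1, f2]
            tree_counts = {"matrix": f"{M.n_genomes}x{M.n_clusters}",
                           "constant_columns": int(M.constant_columns().sum())}
            if run_tree and M.n_genomes >= 4:
                tree, model, ll = phylo.infer_tree(M, cfg=cfg)
                f3 = outdir / "tree.nwk"
                f3.write_text(tree.to_newick() + "\n")
                files.append(f3)
                tree_counts.update({"loglik": round(ll, 4), "pi1": round(model.pi1, 6)})
                if run_bootstrap and cfg.bootstrap_reps >= 10:
                    bt = phylo.bootstrap_support(M, tree, B=cfg.bootstrap_reps,
                                                 seed=cfg.rng_seed, model=model)
                    f4 = outdir / "tree_support.nwk"
                    f4.write_text(bt.to_newick(with_supports=True) + "\n")
                    files.append(f4)
                    tree_counts["branches_above_mark"] = len(
                        phylo.marked_branches(bt, cfg.support_mark_threshold)
                    )
        checkpoint("phylogeny", files, tree_counts)

        # stage: network + Jaccard
        net = network.build_network(cs, gs, bh)
        network.assert_bipartite(net)
        f1 = outdir / "network.graphml"
        f2 = outdir / "network_edges.tsv"
        network.write_network(net, f1, f2)
        gg, gt = network.jaccard_profiles(cs, gs, bh)
        f3 = outdir / "jaccard_genomes.tsv"
        gg.to_csv(f3, sep="\t")
        f4 = outdir / "jaccard_taxa.tsv"
        gt.to_csv(f4, sep="\t")
        checkpoint("network", [f1, f2, f3, f4],
                   {"nodes": net.number_of_nodes(), "edges": net.number_of_edges()})

        manifest["complete"] = True
        mpath.write_text(json.dumps(manifest, indent=2, default=str))
        return manifest
    except Exception:
        mpath.write_text(json.dumps(manifest, indent=2, default=str))
        raise


def run_from_config(config_path: str | Path) -> dict:
    cfg, extra = load_config(config_path)
    gs = read_genome_set(
        extra["fasta_paths"], extra["metadata_path"], extra.get("taxon_refs")
    )
    return run_pipeline(
        gs, cfg, extra.get("outdir", "results"),
        run_tree=extra.get("run_tree", True),
        run_bootstrap=extra.get("run_bootstrap", True),
    )
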