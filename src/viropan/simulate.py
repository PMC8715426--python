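"""Forward simulator of genome-content and sequence evolution.

Generates ground-truth datasets for every pipeline stage: a birth-death
taxon tree, protein-family content evolved along it by per-branch loss,
duplication, de-novo gain and lateral gene transfer (LGT), and amino-acid
sequences for every family copy.  The event log is complete: replaying it
reproduces the leaf incidence and copy-number tables exactly.

Per branch of length t, in documented draw order (all randomness from one
seeded generator):

1. each family present at the parent survives with probability exp(-mu t)
   (families iterated in sorted name order);
2. each surviving family gains Poisson(delta t) extra copies;
3. Poisson(nu t) brand-new families arise de novo;
4. Poisson(lambda_L t) LGT events each copy one family, chosen uniformly
   from families present anywhere else in the already-simulated state (an
   extant-pool approximation of contemporaneous donors), into the branch.

Sequences evolve by per-site Poisson substitution with uniform residue
frequencies: each site accumulates Poisson(rate * t) substitutions, each
replacing the residue with one of the other 19 uniformly.  The probability
that a site is unchanged over total path length T is therefore
1/20 + (19/20) exp(-(20/19) rate T), which the calibration tests exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import CANONICAL, Genome, GenomeSet, ORF
from .phylo import Node, PhyloTree, from_newick

PRESETS = ("small", "plasticity", "reduction")


@dataclass
class SimConfig:
    seed: int
    n_taxa: int = 10
    birth_rate: float = 1.0
    death_rate: float = 0.0
    tree_newick: str | None = None
    tree_height: float | None = None  # rescale the tree to this root-to-tip height
    min_internal_frac: float | None = None  # resimulate until every internal edge >= this fraction of the height
    n_root_families: int = 60
    loss_rate: float = 0.3         # mu, per family per unit branch length
    dup_rate: float = 0.15         # delta
    denovo_rate: float = 2.0       # nu
    lgt_rate: float = 0.5          # lambda_L
    subst_rate: float = 0.15       # substitutions per site per unit branch length
    seq_len_range: tuple[int, int] = (80, 140)
    n_family_groups: int = 2
    reduction_leaf: str | None = None
    reduction_fraction: float = 0.0

    def __post_init__(self):
        if self.n_taxa < 4:
            raise ValueError("n_taxa must be >= 4")
        for r in (self.loss_rate, self.dup_rate, self.denovo_rate, self.lgt_rate,
                  self.subst_rate, self.birth_rate, self.death_rate):
            if r < 0:
                raise ValueError("rates must be >= 0")


@dataclass
class SimTruth:
    tree: PhyloTree
    newick: str
    root_families: list[str]
    incidence: pd.DataFrame     # leaves x families, 0/1
    copy_number: pd.DataFrame   # leaves x families, int
    events: pd.DataFrame        # branch, type, family
    family_groups: dict[str, str]          # leaf -> group label
    ancestral_sequences: dict[str, str] = field(default_factory=dict)
    leaf_sequences: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    config: SimConfig | None = None


# ---------------------------------------------------------------------------
# tree simulation

def simulate_tree(cfg: SimConfig, rng: np.random.Generator | None = None) -> PhyloTree:
    """Birth-death tree conditioned on ``n_taxa`` extant tips (crown start
    with two lineages; the process stops the moment the tip count reaches
    ``n_taxa``, so the tree is ultrametric).  A user newick in
    ``cfg.tree_newick`` is passed through instead."""
    if cfg.tree_newick is not None:
        return from_newick(cfg.tree_newick)
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    b, d = cfg.birth_rate, cfg.death_rate
    if b <= 0:
        raise ValueError("birth rate must be > 0 to reach the target tip count")
    for _attempt in range(1000):
        root = Node()
        c1, c2 = Node(), Node()
        c1.parent = c2.parent = root
        root.children = [c1, c2]
        active = [c1, c2]
        depth = {id(c1): 0.0, id(c2): 0.0}
        t = 0.0
        failed = False
        while len(active) < cfg.n_taxa:
            n = len(active)
            if n == 0:
                failed = True
                break
            t += rng.exponential(1.0 / ((b + d) * n))
            i = int(rng.integers(0, n))
            node = active[i]
            if rng.random() < b / (b + d):
                node.blen = t - depth[id(node)]
                k1, k2 = Node(), Node()
                k1.parent = k2.parent = node
                node.children = [k1, k2]
                depth[id(k1)] = depth[id(k2)] = t
                active.pop(i)
                active.extend([k1, k2])
            else:
                active.pop(i)
                _prune_dead(node)
        if failed:
            continue
        for node in active:
            node.blen = t - depth[id(node)]
        tree = PhyloTree(root)
        _cleanup(tree)
        if len(tree.tips()) == cfg.n_taxa:
            if cfg.min_internal_frac is not None:
                height = max(sum(x.blen for x in _path_to_root(n)) for n in tree.tips())
                internal = [n.blen for n in tree.postorder() if n.parent is not None and n.children]
                if internal and min(internal) < cfg.min_internal_frac * height:
                    continue  # reject trees with unidentifiably short splits
            _label_tips(tree)
            tree.tip_names = sorted(n.label for n in tree.tips())
            if cfg.tree_height is not None:
                _rescale(tree, cfg.tree_height)
            return tree
    raise RuntimeError("birth-death simulation failed to reach the target tip count")


def _path_to_root(n: Node) -> list[Node]:
    out = []
    while n.parent is not None:
        out.append(n)
        n = n.parent
    return out


def _prune_dead(node: Node) -> None:
    """Remove an extinct lineage, suppressing the resulting unary node."""
    p = node.parent
    if p is None:
        return
    p.children.remove(node)
    if len(p.children) == 1 and p.parent is not None:
        only = p.children[0]
        gp = p.parent
        only.blen += p.blen
        only.parent = gp
        gp.children[gp.children.index(p)] = only


def _cleanup(tree: PhyloTree) -> None:
    # suppress any remaining unary nodes below the root
    changed = True
    while changed:
        changed = False
        for n in tree.postorder():
            if n.parent is not None and len(n.children) == 1:
                only = n.children[0]
                only.blen += n.blen
                only.parent = n.parent
                n.parent.children[n.parent.children.index(n)] = only
                changed = True
                break
    while len(tree.root.children) == 1:
        tree.root = tree.root.children[0]
        tree.root.parent = None
        tree.root.blen = 0.0


def _label_tips(tree: PhyloTree) -> None:
    k = 0
    stack = [tree.root]
    while stack:
        n = stack.pop()
        if not n.children:
            k += 1
            n.label = f"G{k:02d}"
        else:
            stack.extend(reversed(n.children))
    j = 0
    for n in tree.postorder():
        if n.children:
            j += 1
            if n.label is None:
                n.label = f"N{j}"


def _rescale(tree: PhyloTree, height: float) -> None:
    depths = []
    def rec(n, d):
        if not n.children:
            depths.append(d)
        for c in n.children:
            rec(c, d + c.blen)
    rec(tree.root, 0.0)
    f = height / max(depths)
    for n in tree.postorder():
        n.blen *= f


def tree_is_ultrametric(tree: PhyloTree, tol: float = 1e-9) -> bool:
    depths = []
    def rec(n, d):
        if not n.children:
            depths.append(d)
        for c in n.children:
            rec(c, d + c.blen)
    rec(tree.root, 0.0)
    return max(depths) - min(depths) < tol


# ---------------------------------------------------------------------------
# content simulation

def simulate_content(tree: PhyloTree, cfg: SimConfig,
                     rng: np.random.Generator | None = None) -> SimTruth:
    """Evolve family content along the tree; returns the full ground truth
    (without sequences)."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    _label_tips(tree)
    root_families = [f"F{i + 1:04d}" for i in range(cfg.n_root_families)]
    state: dict[int, dict[str, int]] = {id(tree.root): {f: 1 for f in root_families}}
    pool: set[str] = set(root_families)
    events: list[dict] = []
    denovo_counter = 0
    order = []
    stack = [tree.root]
    while stack:  # preorder, children in creation order
        n = stack.pop(0)
        order.append(n)
        stack = n.children + stack
    for n in order:
        if n.parent is None:
            continue
        t = n.blen
        parent_state = state[id(n.parent)]
        here: dict[str, int] = {}
        for fam in sorted(parent_state):
            if rng.random() < np.exp(-cfg.loss_rate * t):
                here[fam] = parent_state[fam]
            else:
                events.append({"branch": n.label, "type": "loss", "family": fam, "count": parent_state[fam]})
        for fam in sorted(here):
            k = int(rng.poisson(cfg.dup_rate * t))
            if k:
                here[fam] += k
                events.append({"branch": n.label, "type": "dup", "family": fam, "count": k})
        k_new = int(rng.poisson(cfg.denovo_rate * t))
        for _ in range(k_new):
            denovo_counter += 1
            fam = f"FN{denovo_counter:04d}"
            here[fam] = 1
            pool.add(fam)
            events.append({"branch": n.label, "type": "denovo", "family": fam, "count": 1})
        k_lgt = int(rng.poisson(cfg.lgt_rate * t))
        for _ in range(k_lgt):
            donors = sorted(pool - set(here))
            if not donors:
                continue
            fam = donors[int(rng.integers(0, len(donors)))]
            here[fam] = here.get(fam, 0) + 1
            events.append({"branch": n.label, "type": "lgt", "family": fam, "count": 1})
        state[id(n)] = here
        pool |= set(here)
    truth = _truth_from_state(tree, state, root_families, events, cfg)
    if cfg.reduction_fraction > 0:
        _apply_reduction(truth, state, cfg, rng)
    return truth


def _truth_from_state(tree, state, root_families, events, cfg) -> SimTruth:
    leaves = sorted(n.label for n in tree.tips())
    leaf_nodes = {n.label: n for n in tree.tips()}
    families = sorted({f for n in tree.tips() for f in state[id(n)]} | set(root_families))
    copy = pd.DataFrame(0, index=leaves, columns=families, dtype=int)
    for lf in leaves:
        for fam, c in state[id(leaf_nodes[lf])].items():
            copy.loc[lf, fam] = c
    ev = pd.DataFrame(events, columns=["branch", "type", "family", "count"])
    return SimTruth(
        tree=tree,
        newick=tree.to_newick(),
        root_families=root_families,
        incidence=(copy > 0).astype(int),
        copy_number=copy,
        events=ev,
        family_groups=assign_family_groups(tree, cfg.n_family_groups),
        config=cfg,
    )


def _apply_reduction(truth: SimTruth, state, cfg: SimConfig, rng: np.random.Generator) -> None:
    """Loss burst on one leaf: remove a fixed fraction of its families."""
    leaf = cfg.reduction_leaf or sorted(truth.incidence.index)[0]
    present = sorted(truth.incidence.columns[truth.incidence.loc[leaf] > 0])
    n_remove = int(np.floor(cfg.reduction_fraction * len(present)))
    removed = sorted(rng.choice(present, size=n_remove, replace=False).tolist())
    events = truth.events.to_dict("records")
    for fam in removed:
        events.append({"branch": leaf, "type": "loss", "family": fam,
                       "count": int(truth.copy_number.loc[leaf, fam])})
        truth.copy_number.loc[leaf, fam] = 0
        node = next(n for n in truth.tree.tips() if n.label == leaf)
        state[id(node)].pop(fam, None)
    truth.incidence = (truth.copy_number > 0).astype(int)
    truth.events = pd.DataFrame(events, columns=["branch", "type", "family", "count"])


def replay_events(truth: SimTruth) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reconstruct leaf incidence and copy numbers from the event log alone;
    must equal the recorded tables exactly."""
    tree = truth.tree
    by_branch: dict[str, list[dict]] = {}
    for rec in truth.events.to_dict("records"):
        by_branch.setdefault(rec["branch"], []).append(rec)
    state: dict[int, dict[str, int]] = {id(tree.root): {f: 1 for f in truth.root_families}}
    order = []
    stack = [tree.root]
    while stack:
        n = stack.pop(0)
        order.append(n)
        stack = n.children + stack
    for n in order:
        if n.parent is None:
            continue
        here = dict(state[id(n.parent)])
        for rec in by_branch.get(n.label, []):
            if rec["type"] == "loss":
                here.pop(rec["family"], None)
            elif rec["type"] == "dup":
                here[rec["family"]] += rec["count"]
            else:  # denovo or lgt
                here[rec["family"]] = here.get(rec["family"], 0) + rec["count"]
        state[id(n)] = here
    leaves = sorted(n.label for n in tree.tips())
    leaf_nodes = {n.label: n for n in tree.tips()}
    copy = pd.DataFrame(0, index=leaves, columns=truth.copy_number.columns, dtype=int)
    for lf in leaves:
        for fam, c in state[id(leaf_nodes[lf])].items():
            copy.loc[lf, fam] = c
    return (copy > 0).astype(int), copy


def assign_family_groups(tree: PhyloTree, k: int) -> dict[str, str]:
    """Split the tips into k clade-based virus family/group labels by
    repeatedly subdividing the largest clade."""
    clades: list[list[str]] = [sorted(n.label for n in PhyloTree(c).tips()) for c in tree.root.children]
    nodes: list[Node] = list(tree.root.children)
    while len(clades) < k:
        sizes = [len(c) for c in clades]
        i = max(range(len(clades)), key=lambda j: (sizes[j], clades[j][0]))
        node = nodes[i]
        if not node.children:
            break
        clades.pop(i)
        nodes.pop(i)
        for c in node.children:
            clades.append(sorted(n.label for n in PhyloTree(c).tips()))
            nodes.append(c)
    clades.sort(key=lambda c: c[0])
    out = {}
    for gi, clade in enumerate(clades, 1):
        for tip in clade:
            out[tip] = f"FG{gi}"
    return out


# ---------------------------------------------------------------------------
# sequence simulation

_RES = np.array(list(CANONICAL))


def _mutate(seq: np.ndarray, t: float, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Per-site Poisson substitution; replacement uniform over the 19 other
    residues."""
    out = seq.copy()
    nsub = rng.poisson(rate * t, size=seq.shape[0])
    for i in np.flatnonzero(nsub):
        r = out[i]
        for _ in range(nsub[i]):
            r = (r + 1 + int(rng.integers(0, 19))) % 20
        out[i] = r
    return out


def simulate_sequences(truth: SimTruth, cfg: SimConfig,
                       rng: np.random.Generator | None = None) -> SimTruth:
    """Attach sequences: one random ancestral sequence per family (uniform
    residue frequencies), evolved down the tree; duplicate copies diverge
    independently from their branch of origin; an LGT copy restarts from the
    donor family's ancestral sequence."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 2)
    tree = truth.tree
    families = list(truth.copy_number.columns)
    lo, hi = cfg.seq_len_range
    anc: dict[str, np.ndarray] = {}
    for fam in families:
        L = int(rng.integers(lo, hi + 1))
        anc[fam] = rng.integers(0, 20, size=L)
    # per-branch events for gains
    by_branch: dict[str, list[dict]] = {}
    for rec in truth.events.to_dict("records"):
        by_branch.setdefault(rec["branch"], []).append(rec)
    seqs: dict[int, dict[str, list[np.ndarray]]] = {
        id(tree.root): {f: [anc[f]] for f in truth.root_families}
    }
    order = []
    stack = [tree.root]
    while stack:
        n = stack.pop(0)
        order.append(n)
        stack = n.children + stack
    for n in order:
        if n.parent is None:
            continue
        t = n.blen
        parent_seqs = seqs[id(n.parent)]
        here: dict[str, list[np.ndarray]] = {}
        evs = by_branch.get(n.label, [])
        lost = {e["family"] for e in evs if e["type"] == "loss"}
        for fam in sorted(parent_seqs):
            if fam in lost:
                continue
            here[fam] = [_mutate(s, t, cfg.subst_rate, rng) for s in parent_seqs[fam]]
        for e in evs:
            fam = e["family"]
            if e["type"] == "dup" and fam in here:
                for _ in range(e["count"]):
                    here[fam].append(_mutate(here[fam][0], t / 2.0, cfg.subst_rate, rng))
            elif e["type"] == "denovo":
                here[fam] = [_mutate(anc[fam], t / 2.0, cfg.subst_rate, rng)]
            elif e["type"] == "lgt":
                here.setdefault(fam, []).append(_mutate(anc[fam], t / 2.0, cfg.subst_rate, rng))
        seqs[id(n)] = here
    truth.ancestral_sequences = {f: "".join(_RES[s]) for f, s in anc.items()}
    truth.leaf_sequences = {}
    for n in tree.tips():
        truth.leaf_sequences[n.label] = {
            fam: ["".join(_RES[s]) for s in copies] for fam, copies in seqs[id(n)].items()
        }
    return truth


def make_star_family(n_members: int, divergence: float, length: int, seed: int
                     ) -> tuple[str, dict[str, str]]:
    """One family whose members diverged independently from a common
    ancestor (star phylogeny) by ``divergence`` expected substitutions per
    site.  Returns (ancestral sequence, member sequences)."""
    rng = np.random.default_rng(seed)
    anc = rng.integers(0, 20, size=length)
    members = {
        f"m{i:02d}": "".join(_RES[_mutate(anc, divergence, 1.0, rng)])
        for i in range(n_members)
    }
    return "".join(_RES[anc]), members


# ---------------------------------------------------------------------------
# fixtures

def genome_set_from_truth(truth: SimTruth, taxon_refs: dict[str, dict[str, str]] | None = None) -> GenomeSet:
    genomes = []
    orfs: dict[str, ORF] = {}
    for gid in sorted(truth.leaf_sequences):
        oids = []
        for fam in sorted(truth.leaf_sequences[gid]):
            for i, s in enumerate(truth.leaf_sequences[gid][fam], 1):
                oid = f"{gid}|{fam}|{i}"
                orfs[oid] = ORF(oid, gid, s)
                oids.append(oid)
        genomes.append(Genome(gid, truth.family_groups[gid], oids))
    return GenomeSet(genomes, orfs, taxon_refs or {})


def _preset_config(preset: str, seed: int) -> SimConfig:
    if preset == "small":
        return SimConfig(seed=seed, tree_height=1.0)
    if preset == "plasticity":
        return SimConfig(seed=seed, tree_height=1.0, dup_rate=1.5, lgt_rate=2.0)
    if preset == "reduction":
        return SimConfig(seed=seed, tree_height=1.0, reduction_fraction=0.16,
                         reduction_leaf="G01")
    raise ValueError(f"unknown preset {preset!r}; choose one of {PRESETS}")


def tree_recovery_config(seed: int) -> SimConfig:
    """Study condition for gene-content tree recovery: 10 taxa, unit tree
    height with every internal edge at least 5 % of the height (so all
    splits are identifiable at the simulated character count), and >= 400
    families: 250 root families under moderate loss plus de-novo gains that
    provide clade-marking characters throughout the tree.  Content only."""
    return SimConfig(seed=seed, n_taxa=10, tree_height=1.0, n_root_families=250,
                     loss_rate=0.2, dup_rate=0.0, denovo_rate=60.0, lgt_rate=0.0,
                     min_internal_frac=0.05)


N_REF_FAMILIES = {"Eukaryota": 8, "Bacteria": 4}


def make_fixture(preset: str, seed: int, outdir: str | Path | None = None
                 ) -> tuple[SimTruth, GenomeSet, dict[str, Path]]:
    """Simulate a complete dataset for a named preset and (optionally) write
    it to disk: per-genome FASTA, metadata TSV, truth tables, tree newick,
    event log, and taxon reference FASTAs built from a known subset of
    family ancestral sequences (planted external homologues)."""
    cfg = _preset_config(preset, seed)
    rng = np.random.default_rng(cfg.seed)
    tree = simulate_tree(cfg, rng)
    truth = simulate_content(tree, cfg, rng)
    truth = simulate_sequences(truth, cfg, rng)
    refs: dict[str, dict[str, str]] = {}
    i = 0
    for taxon, n in N_REF_FAMILIES.items():
        fams = truth.root_families[i:i + n]
        i += n
        refs[taxon] = {f"{taxon}_{f}": truth.ancestral_sequences[f] for f in fams}
    gs = genome_set_from_truth(truth, refs)
    files: dict[str, Path] = {}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for g in gs.genomes:
            p = outdir / f"{g.genome_id}.faa"
            with open(p, "w") as fh:
                for oid in g.orf_ids:
                    fh.write(f">{oid}\n{gs.orfs[oid].sequence}\n")
            files[g.genome_id] = p
        meta = outdir / "metadata.tsv"
        with open(meta, "w") as fh:
            fh.write("genome_id\tfamily_label\tgenome_size_kb\n")
            for g in gs.genomes:
                fh.write(f"{g.genome_id}\t{g.family_label}\t\n")
        files["metadata"] = meta
        for taxon, seqs in refs.items():
            p = outdir / f"ref_{taxon}.faa"
            with open(p, "w") as fh:
                for sid in sorted(seqs):
                    fh.write(f">{sid}\n{seqs[sid]}\n")
            files[f"ref_{taxon}"] = p
        truth.incidence.to_csv(outdir / "truth_incidence.tsv", sep="\t")
        truth.copy_number.to_csv(outdir / "truth_copy_number.tsv", sep="\t")
        truth.events.to_csv(outdir / "truth_events.tsv", sep="\t", index=False)
        (outdir / "truth_tree.nwk").write_text(truth.newick + "\n")
        for name in ("truth_incidence.tsv", "truth_copy_number.tsv",
                     "truth_events.tsv", "truth_tree.nwk"):
            files[name] = outdir / name
    return truth, gs, files
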