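"""Gene-content phylogeny from protein-cluster presence/absence.

The genomes x clusters incidence matrix is treated as a binary character
alignment and analysed under a two-state general time-reversible model
("GTR2": free stationary frequencies pi0, pi1 with pi0 + pi1 = 1) with the
rate normalised so one unit of branch length is one expected event:

    beta = 1 / (2 * pi0 * pi1)
    P00(t) = pi0 + pi1 * exp(-beta t)    P01(t) = pi1 * (1 - exp(-beta t))
    P10(t) = pi0 * (1 - exp(-beta t))    P11(t) = pi1 + pi0 * exp(-beta t)

Because a cluster absent from every genome can never be observed (and a
cluster present everywhere carries no split information either way), the
likelihood is conditioned on characters being variable (Lewis-type
ascertainment-bias correction): each pattern likelihood is divided by
(1 - P(all absent) - P(all present)).

Tree search is neighbour joining on Jaccard distances followed by
nearest-neighbour-interchange hill climbing with per-branch Brent
branch-length optimisation and maximum-likelihood estimation of pi1.
Support values come from a standard nonparametric bootstrap over matrix
columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .datamodel import GenomeSet, PipelineConfig
from .mcl import ClusterSet

log = logging.getLogger(__name__)

MIN_BLEN = 1e-8
MAX_BLEN = 50.0


# ---------------------------------------------------------------------------
# presence/absence matrix

@dataclass
class PresenceAbsenceMatrix:
    genome_ids: list[str]
    cluster_ids: list[str]
    binary: np.ndarray       # (n_genomes, n_clusters) in {0,1}
    copy_number: np.ndarray  # same shape, integer counts

    def __post_init__(self):
        self.binary = np.asarray(self.binary, dtype=np.int8)
        if set(np.unique(self.binary)) - {0, 1}:
            raise ValueError("binary matrix entries must be 0/1")
        if (self.binary.sum(axis=0) == 0).any():
            raise ValueError("all-absent cluster column")

    @property
    def n_genomes(self) -> int:
        return len(self.genome_ids)

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_ids)

    def constant_columns(self) -> np.ndarray:
        """Boolean mask of all-present columns (all-absent cannot occur)."""
        return self.binary.sum(axis=0) == self.n_genomes

    def patterns(self) -> tuple[np.ndarray, np.ndarray]:
        """Unique site patterns (P, n_genomes) and their weights; weights sum
        to the number of clusters."""
        cols = np.ascontiguousarray(self.binary.T)
        pats, counts = np.unique(cols, axis=0, return_counts=True)
        return pats, counts.astype(float)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.binary, index=self.genome_ids, columns=self.cluster_ids).to_csv(
            path, sep="\t", index_label="genome_id"
        )

    def to_phylip(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{self.n_genomes} {self.n_clusters}\n")
            for gid, row in zip(self.genome_ids, self.binary):
                fh.write(f"{gid}  {''.join(str(int(v)) for v in row)}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PresenceAbsenceMatrix":
        df = pd.read_csv(path, sep="\t", index_col="genome_id")
        b = df.to_numpy(dtype=np.int8)
        return cls(list(df.index), list(df.columns), b, b.astype(int))


def build_matrix(cs: ClusterSet, gs: GenomeSet) -> PresenceAbsenceMatrix:
    """Genomes x clusters incidence: 1 iff the genome holds >= 1 member of
    the cluster; the copy-number matrix keeps the member counts."""
    gids = gs.genome_ids
    cids = sorted(cs.clusters)
    gidx = {g: i for i, g in enumerate(gids)}
    gmap = {o.orf_id: o.genome_id for o in gs.orfs.values()}
    copy = np.zeros((len(gids), len(cids)), dtype=int)
    for j, cid in enumerate(cids):
        for oid in cs.clusters[cid]:
            copy[gidx[gmap[oid]], j] += 1
    return PresenceAbsenceMatrix(gids, cids, (copy > 0).astype(np.int8), copy)


# ---------------------------------------------------------------------------
# model

@dataclass
class BinaryModel:
    pi1: float = 0.5
    asc_correction: bool = True

    def __post_init__(self):
        if not (0.0 < self.pi1 < 1.0):
            raise ValueError("pi1 must be in (0, 1)")

    @property
    def pi0(self) -> float:
        return 1.0 - self.pi1

    @property
    def beta(self) -> float:
        return 1.0 / (2.0 * self.pi0 * self.pi1)

    def transition(self, t: float) -> np.ndarray:
        """2x2 transition-probability matrix over branch length t >= 0."""
        if t < 0:
            raise ValueError("branch length must be >= 0")
        e = np.exp(-self.beta * t)
        p0, p1 = self.pi0, self.pi1
        return np.array([[p0 + p1 * e, p1 * (1 - e)], [p0 * (1 - e), p1 + p0 * e]])


# ---------------------------------------------------------------------------
# tree structure (unrooted binary tree stored rooted at a trifurcating node)

class Node:
    __slots__ = ("children", "parent", "blen", "label")

    def __init__(self, label: str | None = None):
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.blen: float = 0.0
        self.label = label


@dataclass
class PhyloTree:
    root: Node
    tip_names: list[str] = field(default_factory=list)
    supports: dict = field(default_factory=dict)  # frozenset(tip names) -> support

    def postorder(self) -> list[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return out[::-1]

    def tips(self) -> list[Node]:
        return [n for n in self.postorder() if not n.children]

    def edges(self) -> list[Node]:
        """Every non-root node identifies the edge to its parent."""
        return [n for n in self.postorder() if n.parent is not None]

    def internal_edges(self) -> list[Node]:
        return [n for n in self.edges() if n.children]

    def copy(self) -> "PhyloTree":
        def rec(n: Node, parent: Node | None) -> Node:
            m = Node(n.label)
            m.blen = n.blen
            m.parent = parent
            m.children = [rec(c, m) for c in n.children]
            return m

        return PhyloTree(rec(self.root, None), list(self.tip_names), dict(self.supports))

    # -- bipartitions ------------------------------------------------------
    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions of the unrooted tree, each canonicalised
        as the side not containing the lexicographically smallest tip."""
        all_tips = frozenset(self.tip_names)
        anchor = min(all_tips)
        out: set[frozenset[str]] = set()
        below: dict[int, frozenset[str]] = {}
        for n in self.postorder():
            if not n.children:
                below[id(n)] = frozenset([n.label])
            else:
                s = frozenset().union(*(below[id(c)] for c in n.children))
                below[id(n)] = s
                if n.parent is not None and 1 < len(s) < len(all_tips) - 1:
                    out.add(s if anchor not in s else all_tips - s)
        return out

    # -- newick ------------------------------------------------------------
    def to_newick(self, with_supports: bool = False) -> str:
        # canonical child order (smallest descendant tip first) so equal
        # trees always serialise identically
        mins: dict[int, str] = {}
        for n in self.postorder():
            mins[id(n)] = n.label if not n.children else min(mins[id(c)] for c in n.children)
        for n in self.postorder():
            n.children.sort(key=lambda c: mins[id(c)])

        def rec(n: Node) -> str:
            if not n.children:
                return f"{n.label}:{n.blen:.10g}"
            inner = ",".join(rec(c) for c in n.children)
            lab = ""
            if with_supports and n.parent is not None:
                side = self._clade(n)
                sup = self.supports.get(side)
                if sup is not None:
                    lab = f"{sup:.3f}"
            if n.parent is None:
                return f"({inner}){lab}"
            return f"({inner}){lab}:{n.blen:.10g}"

        return rec(self.root) + ";"

    def _clade(self, n: Node) -> frozenset[str]:
        tips = []
        stack = [n]
        while stack:
            m = stack.pop()
            if m.children:
                stack.extend(m.children)
            else:
                tips.append(m.label)
        all_tips = frozenset(self.tip_names)
        s = frozenset(tips)
        return s if min(all_tips) not in s else all_tips - s


def from_newick(newick: str) -> PhyloTree:
    """Parse a newick string into a :class:`PhyloTree`; a bifurcating root is
    suppressed so the stored tree is the standard unrooted representation."""
    dt = dendropy.Tree.get(data=newick, schema="newick")
    dt.suppress_unifurcations()

    def rec(dn, parent):
        n = Node(dn.taxon.label if dn.taxon else None)
        n.parent = parent
        n.blen = max(dn.edge.length or 0.0, 0.0)
        n.children = [rec(c, n) for c in dn.child_nodes()]
        return n

    root = rec(dt.seed_node, None)
    if len(root.children) == 2:  # rooted representation: merge the root edge
        a, b = root.children
        keep, absorb = (a, b) if a.children else (b, a)
        if keep.children:
            keep.parent = None
            absorb.parent = keep
            absorb.blen = a.blen + b.blen
            keep.children = list(keep.children) + [absorb]
            keep.blen = 0.0
            root = keep
        # two-tip tree: leave as is
    tips = sorted(n.label for n in PhyloTree(root).tips())
    return PhyloTree(root, tips)


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> int:
    """Robinson-Foulds distance: size of the symmetric difference of the two
    trees' non-trivial bipartition sets."""
    if set(t1.tip_names) != set(t2.tip_names):
        raise ValueError("trees have different tip sets")
    return len(t1.bipartitions() ^ t2.bipartitions())


# ---------------------------------------------------------------------------
# likelihood

class LikelihoodEngine:
    """Felsenstein pruning over compressed site patterns for one matrix."""

    def __init__(self, M: PresenceAbsenceMatrix, patterns: np.ndarray | None = None,
                 weights: np.ndarray | None = None):
        if patterns is None:
            patterns, weights = M.patterns()
        self.patterns = patterns  # (P, n_genomes)
        self.weights = weights
        self.genome_index = {g: i for i, g in enumerate(M.genome_ids)}
        self.n_sites = float(weights.sum())
        P = patterns.shape[0]
        # tip conditional likelihoods, per genome: (P, 2)
        self._tip_partials: dict[str, np.ndarray] = {}
        for g, i in self.genome_index.items():
            arr = np.zeros((P, 2))
            arr[np.arange(P), patterns[:, i]] = 1.0
            self._tip_partials[g] = arr
        # constant-pattern partials for the ASC term
        self._const = {
            g: np.array([[1.0, 0.0], [0.0, 1.0]]) for g in self.genome_index
        }

    def _prune(self, tree: PhyloTree, model: BinaryModel, tip_partials) -> np.ndarray:
        partial: dict[int, np.ndarray] = {}
        for n in tree.postorder():
            if not n.children:
                partial[id(n)] = tip_partials[n.label]
            else:
                acc = None
                for c in n.children:
                    T = model.transition(c.blen)
                    contrib = partial[id(c)] @ T.T  # (P,2): rows index parent state
                    acc = contrib if acc is None else acc * contrib
                partial[id(n)] = acc
        pi = np.array([model.pi0, model.pi1])
        return partial[id(tree.root)] @ pi

    def site_likelihoods(self, tree: PhyloTree, model: BinaryModel) -> np.ndarray:
        return self._prune(tree, model, self._tip_partials)

    def constant_pattern_prob(self, tree: PhyloTree, model: BinaryModel) -> float:
        """P(all absent) + P(all present) on the tree."""
        lk = self._prune(tree, model, self._const)
        return float(lk[0] + lk[1])

    def loglik(self, tree: PhyloTree, model: BinaryModel) -> float:
        lk = self.site_likelihoods(tree, model)
        if np.any(lk <= 0) or not np.all(np.isfinite(lk)):
            bad = int(np.argmin(lk))
            raise FloatingPointError(f"non-finite site likelihood at pattern {bad}")
        ll = float(self.weights @ np.log(lk))
        if model.asc_correction:
            pconst = self.constant_pattern_prob(tree, model)
            ll -= self.n_sites * np.log1p(-pconst)
        return ll


def log_likelihood(tree: PhyloTree, M: PresenceAbsenceMatrix, model: BinaryModel) -> float:
    """Log-likelihood of the presence/absence matrix on the tree."""
    if set(tree.tip_names) != set(M.genome_ids):
        raise ValueError("tree tips do not match matrix rows")
    return LikelihoodEngine(M).loglik(tree, model)


# ---------------------------------------------------------------------------
# optimisation and search

_BLEN_GRID = np.array([MIN_BLEN, 0.002, 0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0])


def _optimize_one_edge(engine: LikelihoodEngine, tree: PhyloTree,
                       model: BinaryModel, n: Node, current_ll: float) -> float:
    """Optimise a single branch length: coarse log-grid scan (the per-branch
    likelihood can be multimodal under the ascertainment correction) followed
    by a bounded Brent refinement around the best bracket."""
    t0 = n.blen

    def neg(t):
        n.blen = t
        return -engine.loglik(tree, model)

    grid = np.unique(np.append(_BLEN_GRID, t0))
    vals = np.array([neg(t) for t in grid])
    k = int(np.argmin(vals))
    lo = grid[k - 1] if k > 0 else MIN_BLEN
    hi = grid[k + 1] if k + 1 < len(grid) else MAX_BLEN
    res = minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-7})
    cands = [(-res.fun, float(res.x)), (-vals[k], float(grid[k])), (current_ll, t0)]
    ll, t = max(cands)
    n.blen = t
    return ll


def _optimize_branch_lengths(engine: LikelihoodEngine, tree: PhyloTree,
                             model: BinaryModel, passes: int = 2) -> float:
    best = engine.loglik(tree, model)
    for _ in range(passes):
        improved = False
        for n in tree.edges():
            ll = _optimize_one_edge(engine, tree, model, n, best)
            if ll > best + 1e-10:
                best = ll
                improved = True
        if not improved:
            break
    return best


def _optimize_single_branch(engine: LikelihoodEngine, tree: PhyloTree,
                            model: BinaryModel, n: Node) -> float:
    return _optimize_one_edge(engine, tree, model, n, engine.loglik(tree, model))


def _optimize_pi(engine: LikelihoodEngine, tree: PhyloTree, model: BinaryModel) -> float:
    def neg(p):
        m = BinaryModel(pi1=p, asc_correction=model.asc_correction)
        return -engine.loglik(tree, m)

    res = minimize_scalar(neg, bounds=(1e-3, 1 - 1e-3), method="bounded",
                          options={"xatol": 1e-5})
    if -res.fun > engine.loglik(tree, model):
        model.pi1 = float(res.x)
    return engine.loglik(tree, model)


def _nni_candidates(tree: PhyloTree):
    """Yield (v, child_of_v, child_of_parent) swap triples covering both NNI
    alternatives of every internal edge, in deterministic order."""
    for v in tree.internal_edges():
        u = v.parent
        others = [c for c in u.children if c is not v]
        c = others[0]
        for a in list(v.children):
            yield v, a, c


def _apply_swap(v: Node, a: Node, c: Node) -> None:
    u = v.parent
    v.children[v.children.index(a)] = c
    u.children[u.children.index(c)] = a
    a.parent, c.parent = u, v


def jaccard_distance_matrix(M: PresenceAbsenceMatrix) -> np.ndarray:
    """Pairwise 1 - Jaccard over genome cluster-presence rows."""
    B = M.binary.astype(bool)
    n = M.n_genomes
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            inter = np.count_nonzero(B[i] & B[j])
            union = np.count_nonzero(B[i] | B[j])
            D[i, j] = D[j, i] = 1.0 - (inter / union if union else 1.0)
    return D


def neighbor_joining(D: np.ndarray, labels: list[str]) -> PhyloTree:
    """Canonical neighbour joining with deterministic tie-breaking (smallest
    Q value, then lexicographic pair of subtree labels)."""
    nodes = [Node(lb) for lb in labels]
    names = list(labels)
    D = D.astype(float).copy()
    while len(nodes) > 3:
        n = len(nodes)
        total = D.sum(axis=1)
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * D[i, j] - total[i] - total[j]
                key = (round(q, 12), min(names[i], names[j]), max(names[i], names[j]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        di = 0.5 * D[i, j] + (total[i] - total[j]) / (2 * (n - 2))
        dj = D[i, j] - di
        parent = Node()
        for child, bl in ((nodes[i], di), (nodes[j], dj)):
            child.parent = parent
            child.blen = max(float(bl), 0.0)
            parent.children.append(child)
        newrow = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        D2 = np.zeros((n - 1, n - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = newrow[keep]
        D = D2
        nodes = [nodes[k] for k in keep] + [parent]
        names = [names[k] for k in keep] + [min(names[i], names[j])]
    root = Node()
    if len(nodes) == 3:
        for k, node in enumerate(nodes):
            j, l = (k + 1) % 3, (k + 2) % 3
            node.parent = root
            node.blen = max(0.5 * (D[k, j] + D[k, l] - D[j, l]), 0.0)
            root.children.append(node)
    else:  # 2 remaining subtrees
        a, b = nodes
        a.parent = b.parent = root
        a.blen = b.blen = max(D[0, 1] / 2, 0.0)
        root.children = [a, b]
    tree = PhyloTree(root)
    tree.tip_names = sorted(n.label for n in tree.tips())
    return tree


def nj_start_tree(M: PresenceAbsenceMatrix) -> PhyloTree:
    """Neighbour-joining start tree on Jaccard distances (tips in sorted
    genome order for determinism)."""
    order = sorted(M.genome_ids)
    idx = [M.genome_ids.index(g) for g in order]
    D = jaccard_distance_matrix(M)[np.ix_(idx, idx)]
    if np.allclose(D, 0):
        log.warning("all pairwise Jaccard distances are zero; NJ ties broken lexicographically")
    tree = neighbor_joining(D, order)
    for n in tree.postorder():
        if n.parent is not None:
            n.blen = min(max(n.blen, MIN_BLEN), MAX_BLEN)
    return tree


def infer_tree(
    M: PresenceAbsenceMatrix,
    model: BinaryModel | None = None,
    cfg: PipelineConfig | None = None,
    max_nni_rounds: int = 20,
    opt_passes: int = 2,
    start: PhyloTree | None = None,
    n_starts: int = 3,
) -> tuple[PhyloTree, BinaryModel, float]:
    """ML tree by NNI hill climbing from an NJ start tree plus seeded
    NNI-perturbed restarts (the ASC likelihood surface has local optima);
    returns (tree, model, loglik) for the best start.

    With an explicit ``start`` tree, a single search is run from it.
    ``model.pi1`` is re-estimated by maximum likelihood.
    """
    if M.n_genomes < 4:
        raise ValueError("tree inference needs >= 4 genomes")
    model = model or BinaryModel(pi1=0.5, asc_correction=True)
    base = start if start is not None else nj_start_tree(M)
    if start is not None or n_starts <= 1:
        return _search_from(M, base, model, max_nni_rounds, opt_passes)
    rng = np.random.default_rng((cfg.rng_seed if cfg else 0) + 7919)
    best = None
    for k in range(n_starts):
        t0 = base.copy()
        if k > 0:
            _perturb(t0, rng, n_moves=2)
        m0 = BinaryModel(pi1=model.pi1, asc_correction=model.asc_correction)
        cand = _search_from(M, t0, m0, max_nni_rounds, opt_passes)
        if best is None or cand[2] > best[2] + 1e-9:
            best = cand
    return best


def _perturb(tree: PhyloTree, rng: np.random.Generator, n_moves: int = 2) -> None:
    """Apply random NNI moves in place (search restart diversification)."""
    for _ in range(n_moves):
        cands = list(_nni_candidates(tree))
        if not cands:
            return
        v, a, c = cands[int(rng.integers(0, len(cands)))]
        _apply_swap(v, a, c)


def _search_from(
    M: PresenceAbsenceMatrix,
    start: PhyloTree,
    model: BinaryModel,
    max_nni_rounds: int,
    opt_passes: int,
) -> tuple[PhyloTree, BinaryModel, float]:
    engine = LikelihoodEngine(M)
    tree = start.copy()
    _optimize_branch_lengths(engine, tree, model, passes=opt_passes)
    best = _optimize_pi(engine, tree, model)
    for _ in range(max_nni_rounds):
        best_gain, best_state = 0.0, None
        for v, a, c in _nni_candidates(tree):
            # score the candidate by re-optimising the edges at the junction
            local = [v, a, c] + [x for x in v.children if x is not a]
            if v.parent.parent is not None:
                local.append(v.parent)
            saved = [(e, e.blen) for e in local]
            _apply_swap(v, a, c)
            ll = engine.loglik(tree, model)
            for e in local:
                ll = _optimize_one_edge(engine, tree, model, e, ll)
            if ll - best > best_gain + 1e-9:
                best_gain = ll - best
                best_state = (v, a, c)
            _apply_swap(v, c, a)  # undo
            for e, t in saved:
                e.blen = t
        if best_state is None:
            break
        v, a, c = best_state
        _apply_swap(v, a, c)
        _optimize_branch_lengths(engine, tree, model, passes=opt_passes)
        best = _optimize_pi(engine, tree, model)
    best = _optimize_branch_lengths(engine, tree, model, passes=opt_passes)
    return tree, model, best


def bootstrap_support(
    M: PresenceAbsenceMatrix,
    tree: PhyloTree,
    B: int = 100,
    seed: int = 0,
    model: BinaryModel | None = None,
    cfg: PipelineConfig | None = None,
) -> PhyloTree:
    """Standard nonparametric bootstrap over matrix columns.

    Each replicate resamples columns with replacement, re-infers a tree by
    NNI starting from the ML topology, and the support of each internal edge
    of ``tree`` is the fraction of replicate trees containing its
    bipartition.  Returns a copy of ``tree`` with supports attached.
    """
    if B < 10:
        raise ValueError("bootstrap needs B >= 10 replicates")
    model = model or BinaryModel()
    rng = np.random.default_rng(seed)
    target = tree.bipartitions()
    counts = {bp: 0 for bp in target}
    for _ in range(B):
        cols = rng.integers(0, M.n_clusters, size=M.n_clusters)
        binary = M.binary[:, cols]
        keep = binary.sum(axis=0) > 0
        binary = binary[:, keep]
        Mb = PresenceAbsenceMatrix(
            M.genome_ids, [f"c{i}" for i in range(binary.shape[1])], binary, binary.astype(int)
        )
        bt, _, _ = infer_tree(
            Mb,
            BinaryModel(pi1=model.pi1, asc_correction=model.asc_correction),
            start=tree,
            max_nni_rounds=5,
            opt_passes=1,
        )
        bps = bt.bipartitions()
        for bp in target:
            if bp in bps:
                counts[bp] += 1
    out = tree.copy()
    out.supports = {bp: counts[bp] / B for bp in target}
    return out


def marked_branches(tree: PhyloTree, threshold: float = 0.95) -> list[frozenset[str]]:
    """Bipartitions whose support strictly exceeds the marking threshold."""
    return [bp for bp, s in tree.supports.items() if s > threshold]
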