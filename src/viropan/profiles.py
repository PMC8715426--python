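"""Per-cluster sequence profiles and profile-profile cluster merging.

Clusters produced by graph clustering can still split one divergent protein
family across several clusters.  This stage builds a position-specific
residue-frequency profile for every cluster from a star multiple alignment,
aligns profiles pairwise (local alignment over columns), calibrates a match
probability against a column-shuffled empirical null, and merges clusters
whose profiles overlap over more than half of the shorter profile's length
with probability above 0.95 (both inequalities strict).

The match probability is a seeded empirical quantity (1 minus the empirical
p-value of the raw profile-alignment score under column shuffling), a
semantic stand-in for the calibrated probabilities of HMM-HMM search tools,
not a reimplementation of them.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .align import BLOSUM62, _sw_full, _sw_score, _nw_trace, encode, sw_score
from .datamodel import CANONICAL, GenomeSet, PipelineConfig
from .mcl import ClusterSet

# Robinson & Robinson background amino-acid frequencies, in CANONICAL order
_BG = np.array(
    [0.07805, 0.01925, 0.05364, 0.06295, 0.03856, 0.07377, 0.02199, 0.05142,
     0.05744, 0.09019, 0.02243, 0.04487, 0.05203, 0.04264, 0.05129, 0.07120,
     0.05841, 0.06441, 0.01330, 0.03216]
)
BACKGROUND = _BG / _BG.sum()

PSEUDOCOUNT = 0.05
MIN_OCCUPANCY = 0.5


@dataclass
class Profile:
    """Column-wise residue frequencies of a cluster's star alignment.

    ``freqs`` is (length, 20) with rows summing to 1; ``occupancy`` is the
    fraction of members contributing a residue to each column; ``log_odds``
    is log(freqs / background).
    """

    cluster_id: str
    freqs: np.ndarray
    occupancy: np.ndarray
    center_id: str

    @property
    def length(self) -> int:
        return self.freqs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log(self.freqs / BACKGROUND)

    def consensus(self) -> str:
        return "".join(CANONICAL[i] for i in self.freqs.argmax(axis=1))


def build_profile(members: dict[str, str], cluster_id: str = "cluster") -> Profile:
    """Star multiple alignment of cluster member sequences -> Profile.

    The centre is the member with the highest summed pairwise local-alignment
    score (ties: longest sequence, then lexicographically smallest id); every
    other member is globally aligned to the centre and contributes counts to
    the centre's columns (insertions relative to the centre are discarded).
    Columns with occupancy below 0.5 are dropped; counts receive a uniform
    pseudocount of 0.05 per residue.
    """
    if len(members) < 2:
        raise ValueError("a profile needs at least 2 member sequences")
    ids = sorted(members)
    sums = {i: 0.0 for i in ids}
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            s = sw_score(members[a], members[b])
            sums[a] += s
            sums[b] += s
    center = min(ids, key=lambda i: (-sums[i], -len(members[i]), i))
    cseq = encode(members[center])
    L = len(cseq)
    counts = np.zeros((L, 20))
    occ = np.zeros(L)
    n = len(ids)
    for oid in ids:
        if oid == center:
            _add_residues(counts, occ, np.arange(L), cseq)
            continue
        mseq = encode(members[oid])
        ops = _nw_trace(mseq, cseq, BLOSUM62, 11.0, 1.0)
        mi = ci = 0
        cols, res = [], []
        for op in ops:
            if op == 0:
                cols.append(ci)
                res.append(mseq[mi])
                mi += 1
                ci += 1
            elif op == 1:  # insertion relative to centre: residue discarded
                mi += 1
            else:
                ci += 1
        _add_residues(counts, occ, np.array(cols, dtype=int), np.array(res, dtype=int))
    keep = (occ / n) >= MIN_OCCUPANCY
    if not keep.any():
        keep = occ == occ.max()
    counts, occ = counts[keep], occ[keep]
    freqs = (counts + PSEUDOCOUNT) / (occ[:, None] + 20 * PSEUDOCOUNT)
    return Profile(cluster_id, freqs, occ / n, center)


def _add_residues(counts: np.ndarray, occ: np.ndarray, cols: np.ndarray, residues: np.ndarray) -> None:
    for c, r in zip(cols, residues):
        if r == 20:  # X: spread uniformly
            counts[c] += 1.0 / 20.0
        else:
            counts[c, r] += 1.0
        occ[c] += 1.0


@dataclass(frozen=True)
class ProfileHit:
    cluster_a: str
    cluster_b: str
    aligned_columns: int
    overlap_fraction: float
    raw_score: float
    probability: float


def _column_score_matrix(p: Profile, q: Profile) -> np.ndarray:
    """Symmetrised column-column scores: mean of frequency-vs-log-odds dot
    products in both orientations."""
    return 0.5 * (p.freqs @ q.log_odds.T + p.log_odds @ q.freqs.T)


def _dp_on_matrix(S: np.ndarray, gap_open: float, gap_extend: float):
    """Local affine DP treating S as a position-position score lookup."""
    n, m = S.shape
    a = np.arange(n, dtype=np.int64)
    b = np.arange(m, dtype=np.int64)
    return _sw_full(a, b, S, gap_open, gap_extend)


def compare_profiles(
    p: Profile,
    q: Profile,
    null_reps: int = 1000,
    seed: int = 0,
    cfg: PipelineConfig | None = None,
) -> ProfileHit:
    """Local profile-profile alignment with an empirical match probability.

    The raw score is the optimal local alignment of profile columns under
    affine column-gap penalties; the probability is 1 minus the empirical
    p-value of that score against ``null_reps`` column-shuffled profile
    pairs, with the shuffles drawn from a generator seeded by ``seed`` and
    the (order-independent) pair of cluster ids.  Exactly symmetric in its
    arguments.
    """
    if null_reps < 100:
        raise ValueError("null_reps < 100: probability calibration too coarse")
    cfg = cfg or PipelineConfig()
    if q.cluster_id < p.cluster_id:  # canonical orientation => exact symmetry
        p, q = q, p
    S = _column_score_matrix(p, q)
    go, ge = cfg.profile_gap_open, cfg.profile_gap_extend
    raw, *_span, npairs, _ = _dp_on_matrix(S, go, ge)
    pair_seed = zlib.crc32(f"{p.cluster_id}|{q.cluster_id}".encode()) ^ (seed & 0x7FFFFFFF)
    rng = np.random.default_rng(pair_seed)
    n, m = S.shape
    ge_count = 0
    for _ in range(null_reps):
        ra = rng.permutation(n).astype(np.int64)
        rb = rng.permutation(m).astype(np.int64)
        if _sw_score(ra, rb, S, go, ge) >= raw:
            ge_count += 1
    pval = (1 + ge_count) / (null_reps + 1)
    return ProfileHit(
        p.cluster_id,
        q.cluster_id,
        int(npairs),
        npairs / min(p.length, q.length),
        float(raw),
        1.0 - pval,
    )


def raw_profile_alignment(p: Profile, q: Profile, cfg: PipelineConfig | None = None) -> tuple[float, int, float]:
    """Raw score, aligned columns and overlap fraction only (no null)."""
    cfg = cfg or PipelineConfig()
    if q.cluster_id < p.cluster_id:
        p, q = q, p
    S = _column_score_matrix(p, q)
    raw, *_s, npairs, _ = _dp_on_matrix(S, cfg.profile_gap_open, cfg.profile_gap_extend)
    return float(raw), int(npairs), npairs / min(p.length, q.length)


def merge_clusters(cs: ClusterSet, hits: list[ProfileHit], cfg: PipelineConfig | None = None) -> ClusterSet:
    """Union-find merge of clusters joined by qualifying profile hits.

    A hit qualifies when overlap_fraction > cfg.merge_overlap_min AND
    probability > cfg.merge_probability_min, both strictly; qualifying hits
    close transitively.  The merged cluster keeps the lexicographically
    smallest constituent id; singletons are untouched.
    """
    cfg = cfg or PipelineConfig()
    ids = sorted(cs.clusters)
    parent = {c: c for c in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    merged_pairs = []
    for h in hits:
        for c in (h.cluster_a, h.cluster_b):
            if c not in parent:
                raise ValueError(f"profile hit references unknown cluster {c!r}")
        if h.overlap_fraction > cfg.merge_overlap_min and h.probability > cfg.merge_probability_min:
            ra, rb = find(h.cluster_a), find(h.cluster_b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
            merged_pairs.append((h.cluster_a, h.cluster_b))
    groups: dict[str, set[str]] = {}
    for c in ids:
        groups.setdefault(find(c), set()).add(c)
    new_clusters = {
        root: frozenset().union(*(cs.clusters[c] for c in members))
        for root, members in groups.items()
    }
    prov = dict(cs.provenance)
    history = list(prov.get("merge_history", []))
    history.append(
        {
            "merged_pairs": merged_pairs,
            "groups": {r: sorted(m) for r, m in groups.items() if len(m) > 1},
            "overlap_min": cfg.merge_overlap_min,
            "probability_min": cfg.merge_probability_min,
        }
    )
    prov["merge_history"] = history
    out = ClusterSet(new_clusters, cs.singletons, provenance=prov)
    out.assert_partition_of(cs.all_orfs)
    assert len(out.clusters) <= len(cs.clusters)
    return out


def build_all_profiles(cs: ClusterSet, gs: GenomeSet) -> dict[str, Profile]:
    return {
        cid: build_profile({o: gs.orfs[o].sequence for o in cs.clusters[cid]}, cid)
        for cid in sorted(cs.clusters)
    }


def profile_merge_pass(
    cs: ClusterSet,
    gs: GenomeSet,
    cfg: PipelineConfig | None = None,
) -> tuple[ClusterSet, list[ProfileHit]]:
    """One full merge round: profiles, all-pairs comparison, merge.

    Pairs whose raw alignment already fails the overlap threshold are not
    null-calibrated (the probability cannot rescue them); their hits are
    reported with probability 0.
    """
    cfg = cfg or PipelineConfig()
    profiles = build_all_profiles(cs, gs)
    ids = sorted(profiles)
    hits: list[ProfileHit] = []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            raw, ncols, overlap = raw_profile_alignment(profiles[a], profiles[b], cfg)
            if overlap > cfg.merge_overlap_min:
                hits.append(compare_profiles(profiles[a], profiles[b], cfg.null_reps, cfg.rng_seed, cfg))
            else:
                hits.append(ProfileHit(a, b, ncols, overlap, raw, 0.0))
    return merge_clusters(cs, hits, cfg), hits


def write_profile_hits(hits: list[ProfileHit], cfg: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_a\tcluster_b\taligned_cols\toverlap_fraction\traw_score\tprobability\tmerged\n")
        for h in sorted(hits, key=lambda h: (h.cluster_a, h.cluster_b)):
            merged = h.overlap_fraction > cfg.merge_overlap_min and h.probability > cfg.merge_probability_min
            fh.write(
                f"{h.cluster_a}\t{h.cluster_b}\t{h.aligned_columns}\t"
                f"{h.overlap_fraction:.4f}\t{h.raw_score:.4f}\t{h.probability:.4f}\t{merged}\n"
            )
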