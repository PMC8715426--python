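"""All-vs-all protein similarity search: exact local alignment + E-values.

Self-contained replacement for an external BLAST search at desk scale:
optimal Smith-Waterman alignment under affine gap costs (a gap of length k
costs ``open + k * extend``), with BLAST-convention Karlin-Altschul E-values
``E = K * m * n * exp(-lambda * S)``.  The dynamic programming kernels are
JIT-compiled; scores are exact, with a deterministic traceback (ties prefer
diagonal, then up, then left).

The gapped Karlin-Altschul parameters are fixed (lambda = 0.267, K = 0.041,
the standard BLOSUM62/11/1 gapped values) rather than estimated per query;
E-values are therefore comparable across a run but not identical to BLAST's
composition-adjusted statistics.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from numba import njit

from .datamodel import CANONICAL, GenomeSet, PipelineConfig

ALPHABET = CANONICAL + "X"  # 21 letters; X carries the matrix's ambiguity scores
_RES_INDEX = {c: i for i, c in enumerate(ALPHABET)}

KARLIN_LAMBDA = 0.267
KARLIN_K = 0.041


def load_matrix(name: str = "BLOSUM62") -> np.ndarray:
    """A 21x21 integer substitution matrix over :data:`ALPHABET`."""
    m = substitution_matrices.load(name)
    out = np.zeros((21, 21), dtype=np.float64)
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            out[i, j] = m[a][b]
    return out


BLOSUM62 = load_matrix("BLOSUM62")


def encode(seq: str) -> np.ndarray:
    try:
        return np.array([_RES_INDEX[c] for c in seq], dtype=np.int8)
    except KeyError as e:
        raise ValueError(f"unknown residue {e.args[0]!r} after sanitation") from None


@njit(cache=True)
def _sw_score(a, b, S, gap_open, gap_extend):
    """Best local alignment score only (rolling rows)."""
    n, m = a.shape[0], b.shape[0]
    NEG = -1e30
    Hprev = np.zeros(m + 1)
    Fprev = np.full(m + 1, NEG)
    best = 0.0
    for i in range(1, n + 1):
        Hcur = np.zeros(m + 1)
        Fcur = np.empty(m + 1)
        Fcur[0] = NEG
        e = NEG
        for j in range(1, m + 1):
            e = max(e - gap_extend, Hcur[j - 1] - gap_open - gap_extend)
            f = max(Fprev[j] - gap_extend, Hprev[j] - gap_open - gap_extend)
            Fcur[j] = f
            h = Hprev[j - 1] + S[a[i - 1], b[j - 1]]
            v = h
            if e > v:
                v = e
            if f > v:
                v = f
            if v < 0.0:
                v = 0.0
            Hcur[j] = v
            if v > best:
                best = v
        Hprev = Hcur
        Fprev = Fcur
    return best


@njit(cache=True)
def _sw_full(a, b, S, gap_open, gap_extend):
    """Full DP with traceback.

    Returns (score, q_start, q_end, s_start, s_end, n_aligned_pairs,
    n_identical) with 1-based inclusive spans; zeros if the best score is 0
    (empty alignment).  Tie-break on the end cell: smallest i, then j;
    traceback prefers diagonal, then up (gap in subject), then left.
    """
    n, m = a.shape[0], b.shape[0]
    NEG = -1e30
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    best = 0.0
    bi, bj = 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(E[i, j - 1] - gap_extend, H[i, j - 1] - gap_open - gap_extend)
            F[i, j] = max(F[i - 1, j] - gap_extend, H[i - 1, j] - gap_open - gap_extend)
            h = H[i - 1, j - 1] + S[a[i - 1], b[j - 1]]
            v = h
            if E[i, j] > v:
                v = E[i, j]
            if F[i, j] > v:
                v = F[i, j]
            if v < 0.0:
                v = 0.0
            H[i, j] = v
            if v > best:
                best = v
                bi, bj = i, j
    if best <= 0.0:
        return 0.0, 0, 0, 0, 0, 0, 0
    # traceback from (bi, bj) in state H
    i, j = bi, bj
    state = 0  # 0=H, 1=F(up), 2=E(left)
    npairs = 0
    nid = 0
    while True:
        if state == 0:
            if H[i, j] == 0.0:
                break
            diag = H[i - 1, j - 1] + S[a[i - 1], b[j - 1]]
            if H[i, j] == diag:
                npairs += 1
                if a[i - 1] == b[j - 1]:
                    nid += 1
                i -= 1
                j -= 1
            elif H[i, j] == F[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            # gap consuming query residue i
            if F[i, j] == H[i - 1, j] - gap_open - gap_extend:
                state = 0
            i -= 1
        else:
            if E[i, j] == H[i, j - 1] - gap_open - gap_extend:
                state = 0
            j -= 1
    return best, i + 1, bi, j + 1, bj, npairs, nid


@njit(cache=True)
def _nw_trace(a, b, S, gap_open, gap_extend):
    """Global (Needleman-Wunsch, affine) alignment; returns the operation
    string encoded as int8 array: 0 = match/mismatch, 1 = gap in b (consume
    a), 2 = gap in a (consume b), in alignment order."""
    n, m = a.shape[0], b.shape[0]
    NEG = -1e30
    H = np.full((n + 1, m + 1), NEG)
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    H[0, 0] = 0.0
    for j in range(1, m + 1):
        E[0, j] = -gap_open - j * gap_extend
        H[0, j] = E[0, j]
    for i in range(1, n + 1):
        F[i, 0] = -gap_open - i * gap_extend
        H[i, 0] = F[i, 0]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(E[i, j - 1] - gap_extend, H[i, j - 1] - gap_open - gap_extend)
            F[i, j] = max(F[i - 1, j] - gap_extend, H[i - 1, j] - gap_open - gap_extend)
            h = H[i - 1, j - 1] + S[a[i - 1], b[j - 1]]
            v = h
            if E[i, j] > v:
                v = E[i, j]
            if F[i, j] > v:
                v = F[i, j]
            H[i, j] = v
    ops = np.empty(n + m, dtype=np.int8)
    k = 0
    i, j = n, m
    state = 0
    while i > 0 or j > 0:
        if state == 0:
            if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + S[a[i - 1], b[j - 1]]:
                ops[k] = 0
                i -= 1
                j -= 1
                k += 1
                continue
            if i > 0 and H[i, j] == F[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            ops[k] = 1
            if F[i, j] == H[i - 1, j] - gap_open - gap_extend:
                state = 0
            i -= 1
            k += 1
        else:
            ops[k] = 2
            if j > 0 and E[i, j] == H[i, j - 1] - gap_open - gap_extend:
                state = 0
            j -= 1
            k += 1
    return ops[:k][::-1].copy()


@dataclass(frozen=True)
class AlignmentResult:
    query_id: str
    subject_id: str
    score: float
    bit_score: float
    evalue: float
    query_span: tuple[int, int]   # 1-based inclusive; (0, 0) for empty alignment
    subject_span: tuple[int, int]
    identity: float


def bit_score(score: float, lam: float = KARLIN_LAMBDA, K: float = KARLIN_K) -> float:
    return (lam * score - math.log(K)) / math.log(2.0)


def estimate_evalue(
    score: float, m: int, n: int, lam: float = KARLIN_LAMBDA, K: float = KARLIN_K
) -> float:
    """Karlin-Altschul expectation value E = K * m * n * exp(-lambda * S)."""
    if m < 1 or n < 1:
        raise ValueError("sequence/database lengths must be >= 1")
    if lam <= 0 or K <= 0:
        raise ValueError("Karlin-Altschul parameters must be positive")
    return K * m * n * math.exp(-lam * score)


def local_align(
    a: str,
    b: str,
    matrix: np.ndarray | None = None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    query_id: str = "query",
    subject_id: str = "subject",
    db_length: int | None = None,
) -> AlignmentResult:
    """Optimal Smith-Waterman local alignment of two protein sequences.

    ``db_length`` is the effective database length for the E-value (defaults
    to ``len(b)`` for a single pairwise comparison).
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    S = BLOSUM62 if matrix is None else matrix
    ea, eb = encode(a), encode(b)
    score, qs, qe, ss, se, npairs, nid = _sw_full(ea, eb, S, float(gap_open), float(gap_extend))
    ident = nid / npairs if npairs else 0.0
    n = db_length if db_length is not None else len(b)
    return AlignmentResult(
        query_id,
        subject_id,
        float(score),
        bit_score(score),
        estimate_evalue(score, len(a), n),
        (qs, qe),
        (ss, se),
        ident,
    )


def sw_score(a: str, b: str, matrix: np.ndarray | None = None,
             gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Score-only Smith-Waterman (fast path)."""
    S = BLOSUM62 if matrix is None else matrix
    return float(_sw_score(encode(a), encode(b), S, float(gap_open), float(gap_extend)))


WEIGHT_CAP = 200.0


def _edge_weight(evalue: float) -> float:
    if evalue <= 0.0:
        return WEIGHT_CAP
    return min(-math.log10(evalue), WEIGHT_CAP)


def all_vs_all(gs: GenomeSet, cfg: PipelineConfig | None = None) -> nx.Graph:
    """All-vs-all similarity graph over the ORFs of a genome set.

    Nodes are all ORF ids; an undirected edge joins two ORFs when their
    pairwise E-value is at or below ``cfg.evalue_cutoff`` in both search
    directions (reciprocal criterion; the database length is the total
    residue count of the ORF collection).  Edge weight is
    ``min(-log10 E, 200)``.
    """
    cfg = cfg or PipelineConfig()
    orf_ids = gs.orf_ids_in_order()
    if len(orf_ids) < 2:
        raise ValueError("all_vs_all needs at least 2 ORFs")
    enc = {oid: encode(gs.orfs[oid].sequence) for oid in orf_ids}
    n_db = sum(gs.orfs[oid].length for oid in orf_ids)
    g = nx.Graph()
    g.add_nodes_from(sorted(orf_ids))
    g.graph["provenance"] = {
        "matrix": "BLOSUM62",
        "gap_open": cfg.gap_open,
        "gap_extend": cfg.gap_extend,
        "karlin_lambda": cfg.karlin_lambda,
        "karlin_k": cfg.karlin_k,
        "evalue_cutoff": cfg.evalue_cutoff,
        "db_length": n_db,
    }
    for x, y in itertools.combinations(sorted(orf_ids), 2):
        s = _sw_score(enc[x], enc[y], BLOSUM62, cfg.gap_open, cfg.gap_extend)
        # reciprocal E-value: the worse of the two query directions
        m = max(len(enc[x]), len(enc[y]))
        e = estimate_evalue(s, m, n_db, cfg.karlin_lambda, cfg.karlin_k)
        if e <= cfg.evalue_cutoff:
            g.add_edge(x, y, weight=_edge_weight(e), evalue=e, score=float(s))
    return g


def best_hits(gs: GenomeSet, cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """Best hit of every ORF against each taxon-labelled reference collection.

    For each (ORF, taxon) the single subject with the highest bit score is
    kept (ties: lower E-value, then lexicographically smaller subject_id);
    hits with E-value above the cutoff are discarded.  Returns a DataFrame
    with columns orf_id, taxon_label, subject_id, evalue, bit_score.
    """
    cfg = cfg or PipelineConfig()
    rows = []
    for taxon in sorted(gs.taxon_refs):
        refs = gs.taxon_refs[taxon]
        if not refs:
            raise ValueError(f"reference collection {taxon!r} is empty")
        enc_refs = {sid: encode(s) for sid, s in refs.items()}
        n_db = sum(len(s) for s in refs.values())
        for oid in gs.orf_ids_in_order():
            q = encode(gs.orfs[oid].sequence)
            best = None  # (-bit, evalue, subject_id)
            for sid in sorted(enc_refs):
                s = _sw_score(q, enc_refs[sid], BLOSUM62, cfg.gap_open, cfg.gap_extend)
                e = estimate_evalue(s, len(q), n_db, cfg.karlin_lambda, cfg.karlin_k)
                if e > cfg.evalue_cutoff:
                    continue
                key = (-bit_score(s, cfg.karlin_lambda, cfg.karlin_k), e, sid)
                if best is None or key < best:
                    best = key
            if best is not None:
                rows.append(
                    {
                        "orf_id": oid,
                        "taxon_label": taxon,
                        "subject_id": best[2],
                        "evalue": best[1],
                        "bit_score": -best[0],
                    }
                )
    return pd.DataFrame(rows, columns=["orf_id", "taxon_label", "subject_id", "evalue", "bit_score"])


OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_hits_table(path: str | Path, taxon_label: str,
                    cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """Ingest a 12-column tabular hit file (BLAST outfmt-6-like) as a
    best-hit table for one taxon collection, applying the E-value cutoff and
    best-hit rule."""
    cfg = cfg or PipelineConfig()
    df = pd.read_csv(path, sep="\t", header=None, names=OUTFMT6_COLUMNS)
    df = df[df["evalue"] <= cfg.evalue_cutoff]
    df = df.sort_values(
        ["qseqid", "bitscore", "evalue", "sseqid"],
        ascending=[True, False, True, True],
        kind="mergesort",
    ).drop_duplicates("qseqid", keep="first")
    return pd.DataFrame(
        {
            "orf_id": df["qseqid"].to_numpy(),
            "taxon_label": taxon_label,
            "subject_id": df["sseqid"].to_numpy(),
            "evalue": df["evalue"].to_numpy(),
            "bit_score": df["bitscore"].to_numpy(),
        }
    )


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("orf_a\torf_b\tweight\n")
        for a, b, w in sorted(graph.edges(data="weight")):
            fh.write(f"{a}\t{b}\t{w:.6g}\n")
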