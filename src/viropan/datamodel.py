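"""Core data model: ORFs, genomes, genome sets and the pipeline configuration.

A :class:`GenomeSet` is the universe every downstream stage operates on: a
collection of viral proteomes (one per genome), each ORF a plain amino-acid
sequence, plus per-genome metadata (the virus family/group label used for
core-gene-set statistics) and optional taxon-labelled reference protein
collections (stand-ins for cellular / other-virus databases used for
external-homology annotation).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

#: canonical amino-acid alphabet; X is the ambiguity residue
CANONICAL = "ACDEFGHIKLMNPQRSTVWY"
AMBIGUOUS_MAP = str.maketrans({c: "X" for c in "BZUJO"})
VALID = set(CANONICAL) | {"X"}


def sanitize_sequence(seq: str, orf_id: str = "?") -> str:
    """Upper-case, strip a single trailing stop ('*'), map rare non-canonical
    residues (B, Z, U, J, O) to X.  Any other character is an error."""
    s = seq.upper().rstrip("*")
    if "*" in s:
        raise ValueError(f"internal stop '*' in sequence of {orf_id}")
    t = s.translate(AMBIGUOUS_MAP)
    if t != s:
        log.warning("non-canonical residues in %s mapped to X", orf_id)
    bad = set(t) - VALID
    if bad:
        raise ValueError(f"invalid residues {sorted(bad)} in {orf_id}")
    if not t:
        raise ValueError(f"empty sequence for {orf_id}")
    return t


@dataclass(frozen=True)
class ORF:
    orf_id: str
    genome_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Genome:
    genome_id: str
    family_label: str
    orf_ids: list[str]
    genome_size_kb: float | None = None

    def __post_init__(self):
        if not self.family_label:
            raise ValueError(f"genome {self.genome_id} has empty family label")
        if not self.orf_ids:
            raise ValueError(f"genome {self.genome_id} has an empty proteome")


@dataclass
class GenomeSet:
    """Proteomes plus metadata; the universe of ORFs and family labels.

    ``taxon_refs`` maps a taxon label (e.g. "Eukaryota", "Bacteria") to a
    reference protein collection ``{subject_id: sequence}``.
    """

    genomes: list[Genome]
    orfs: dict[str, ORF]
    taxon_refs: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self):
        gids = [g.genome_id for g in self.genomes]
        if len(gids) != len(set(gids)):
            raise ValueError("duplicate genome_id in GenomeSet")
        for g in self.genomes:
            for oid in g.orf_ids:
                if oid not in self.orfs:
                    raise ValueError(f"genome {g.genome_id} references unknown ORF {oid}")

    @property
    def genome_ids(self) -> list[str]:
        return [g.genome_id for g in self.genomes]

    @property
    def n_orfs(self) -> int:
        return len(self.orfs)

    def genome(self, genome_id: str) -> Genome:
        for g in self.genomes:
            if g.genome_id == genome_id:
                return g
        raise KeyError(genome_id)

    def orf_ids_in_order(self) -> list[str]:
        """All ORF ids in deterministic (genome, record) order."""
        return [oid for g in self.genomes for oid in g.orf_ids]


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline, with their defaults.

    The defaults encode the analysis conventions: BLAST-style E-value cutoff
    of 1e-5 for homology calls, profile-merge rule of strictly more than 50 %
    length overlap at strictly more than 95 % match probability, core gene
    set defined by presence in strictly more than six virus family/groups,
    and branch supports marked above 95 %.
    """

    evalue_cutoff: float = 1e-5
    merge_overlap_min: float = 0.5     # strict >
    merge_probability_min: float = 0.95  # strict >
    core_family_min: int = 6           # strict >
    mcl_inflation: float = 1.5
    mcl_expansion: int = 2
    mcl_prune: float = 1e-5
    mcl_tol: float = 1e-6
    mcl_max_iter: int = 200
    gap_open: float = 11.0
    gap_extend: float = 1.0
    karlin_lambda: float = 0.267
    karlin_k: float = 0.041
    null_reps: int = 1000
    profile_gap_open: float = 3.0
    profile_gap_extend: float = 0.3
    merge_rounds: int = 1
    bootstrap_reps: int = 100
    support_mark_threshold: float = 0.95
    copy_number_k: int = 5
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("merge_overlap_min", "merge_probability_min", "support_mark_threshold"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue_cutoff must be > 0")
        if self.mcl_inflation <= 1:
            raise ValueError("mcl_inflation must be > 1")

    def to_dict(self) -> dict:
        return asdict(self)


def _read_fasta_records(path: Path) -> list[tuple[str, str]]:
    recs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        recs.append((rec.id, str(rec.seq)))
    return recs


def read_genome_set(
    fasta_paths: Iterable[str | Path],
    metadata_path: str | Path,
    taxon_ref_paths: Mapping[str, str | Path] | None = None,
) -> GenomeSet:
    """Read one protein FASTA per genome plus a metadata TSV.

    The metadata TSV must have columns ``genome_id`` and ``family_label``
    (``genome_size_kb`` optional).  Each FASTA file is matched to a metadata
    row by its filename stem.  ORF ids are the FASTA description up to the
    first whitespace and must be globally unique.  Genome order follows the
    metadata file; record order within a genome follows the FASTA file.
    """
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    for col in ("genome_id", "family_label"):
        if col not in meta.columns:
            raise ValueError(f"metadata lacks required column {col!r}")
    paths = {Path(p).stem: Path(p) for p in fasta_paths}
    known = set(meta["genome_id"])
    unmatched = sorted(set(paths) - known)
    if unmatched:
        raise ValueError(
            "FASTA file(s) without a metadata row: "
            + ", ".join(str(paths[u]) for u in unmatched)
        )
    orfs: dict[str, ORF] = {}
    genomes: list[Genome] = []
    for row in meta.itertuples(index=False):
        gid = row.genome_id
        if gid not in paths:
            raise ValueError(f"metadata row {gid!r} has no FASTA file")
        size = None
        if "genome_size_kb" in meta.columns:
            raw = getattr(row, "genome_size_kb", None)
            if raw not in (None, "") and not pd.isna(raw):
                size = float(raw)
        oids = []
        for rid, seq in _read_fasta_records(paths[gid]):
            if rid in orfs:
                raise ValueError(f"duplicate orf_id {rid!r} (genome {gid})")
            orfs[rid] = ORF(rid, gid, sanitize_sequence(seq, rid))
            oids.append(rid)
        genomes.append(Genome(gid, row.family_label, oids, genome_size_kb=size))
    return GenomeSet(genomes, orfs, dict(_read_taxon_refs(taxon_ref_paths or {})))


def _read_taxon_refs(paths: Mapping[str, str | Path]) -> dict[str, dict[str, str]]:
    refs: dict[str, dict[str, str]] = {}
    for label, p in paths.items():
        refs[label] = {
            rid: sanitize_sequence(seq, rid) for rid, seq in _read_fasta_records(Path(p))
        }
        if not refs[label]:
            raise ValueError(f"reference collection {label!r} is empty")
    return refs


def write_genome_set(gs: GenomeSet, outdir: str | Path) -> dict[str, Path]:
    """Write one FASTA per genome plus metadata.tsv; inverse of
    :func:`read_genome_set` (round-trips exactly)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    rows = []
    for g in gs.genomes:
        p = outdir / f"{g.genome_id}.faa"
        with open(p, "w") as fh:
            for oid in g.orf_ids:
                fh.write(f">{oid}\n{gs.orfs[oid].sequence}\n")
        files[g.genome_id] = p
        rows.append(
            {
                "genome_id": g.genome_id,
                "family_label": g.family_label,
                "genome_size_kb": "" if g.genome_size_kb is None else g.genome_size_kb,
            }
        )
    mpath = outdir / "metadata.tsv"
    pd.DataFrame(rows).to_csv(mpath, sep="\t", index=False)
    files["__metadata__"] = mpath
    return files


def summarize_genome_set(gs: GenomeSet) -> pd.DataFrame:
    """Per-genome summary table (ORF count, family label) with a totals row."""
    rows = [
        {
            "genome_id": g.genome_id,
            "family_label": g.family_label,
            "n_orfs": len(g.orf_ids),
            "genome_size_kb": g.genome_size_kb,
        }
        for g in gs.genomes
    ]
    df = pd.DataFrame(rows)
    total = {
        "genome_id": "TOTAL",
        "family_label": "",
        "n_orfs": int(df["n_orfs"].sum()),
        "genome_size_kb": None,
    }
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)
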