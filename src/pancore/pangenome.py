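"""Pangenome construction: clustering stand-in, matrices, modal variants.

Production pangenomes are built by clustering protein sequences with CD-HIT
(identity >= 80%, alignment covering >= 80% of the shorter sequence) and
treating clusters as genes.  This module provides a behavior-compatible
desk-scale greedy clusterer with an exactly specified contract, an adapter
for ingesting CD-HIT ``.clstr`` output verbatim, the presence/absence matrix
builder, and modal sequence-variant selection.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from Bio import Align, SeqIO

from .matrix import PresenceAbsenceMatrix

__all__ = [
    "GeneCluster",
    "greedy_cluster",
    "build_matrix",
    "modal_variant",
    "read_cdhit_clstr",
    "read_protein_fastas",
]

_AA_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWYXBZJUO*]+$", re.IGNORECASE)


@dataclass
class GeneCluster:
    """A cluster of homologous protein sequences, treated as one gene.

    Members are (genome_id, sequence_id, sequence) triples; the representative
    is the sequence the greedy pass founded the cluster with.
    """

    cluster_id: str
    members: list[tuple[str, str, str]] = field(repr=False)
    representative: str

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("cluster must be non-empty")
        if self.representative not in {m[1] for m in self.members}:
            raise ValueError("representative must be a member sequence ID")

    @property
    def genomes(self) -> set:
        return {m[0] for m in self.members}


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    return aligner


def _identity_coverage(aligner: Align.PairwiseAligner, a: str, b: str) -> tuple[float, float]:
    """Global-alignment identity (matches / alignment columns) and coverage
    of the shorter sequence (aligned residue columns / shorter length)."""
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    identity = counts.identities / columns if columns else 0.0
    coverage = (counts.identities + counts.mismatches) / min(len(a), len(b))
    return identity, coverage


def greedy_cluster(
    sequences: list[tuple[str, str, str]],
    min_identity: float = 0.8,
    min_coverage: float = 0.8,
) -> list[GeneCluster]:
    """Greedy representative-first clustering of protein sequences.

    Sequences are processed by decreasing length (ties by sequence ID); each
    joins the first existing cluster whose representative aligns with identity
    >= `min_identity` over >= `min_coverage` of the shorter sequence, else it
    founds a new cluster.
    """
    if not sequences:
        raise ValueError("no sequences given")
    for genome_id, seq_id, seq in sequences:
        if not seq:
            raise ValueError(f"empty sequence: {seq_id}")
        if not _AA_RE.match(seq):
            raise ValueError(f"non-amino-acid characters in sequence {seq_id}")
    aligner = _make_aligner()
    ordered = sorted(sequences, key=lambda r: (-len(r[2]), r[1]))
    clusters: list[GeneCluster] = []
    reps: list[str] = []
    for genome_id, seq_id, seq in ordered:
        placed = False
        for k, rep_seq in enumerate(reps):
            identity, coverage = _identity_coverage(aligner, rep_seq, seq)
            if identity >= min_identity and coverage >= min_coverage:
                clusters[k].members.append((genome_id, seq_id, seq))
                placed = True
                break
        if not placed:
            cid = f"C{len(clusters):05d}"
            clusters.append(GeneCluster(cid, [(genome_id, seq_id, seq)], seq_id))
            reps.append(seq)
    return clusters


def build_matrix(clusters: list[GeneCluster], genomes: list[str]) -> PresenceAbsenceMatrix:
    """Presence/absence matrix: entry (i, j) = 1 iff cluster i has a member
    from genome j.  Paralogs (multiple members from one genome) collapse to a
    single 1."""
    roster = {g: j for j, g in enumerate(genomes)}
    entries = np.zeros((len(clusters), len(genomes)), dtype=np.int8)
    for i, cluster in enumerate(clusters):
        for genome_id, _, _ in cluster.members:
            if genome_id not in roster:
                raise ValueError(f"member genome {genome_id!r} not in roster")
            entries[i, roster[genome_id]] = 1
    return PresenceAbsenceMatrix([c.cluster_id for c in clusters], list(genomes), entries)


def modal_variant(cluster: GeneCluster) -> str:
    """Most frequent exact sequence string; ties broken by the
    lexicographically smallest sequence."""
    counts: dict[str, int] = {}
    for _, _, seq in cluster.members:
        counts[seq] = counts.get(seq, 0) + 1
    return min(counts, key=lambda s: (-counts[s], s))


# ---------------------------------------------------------------------------
# adapters

_CLSTR_ENTRY = re.compile(r"^\d+\s+\d+(?:aa|nt),\s+>(\S+?)\.\.\.\s+(.*)$")


def read_cdhit_clstr(
    path,
    sequence_lookup: dict[str, tuple[str, str]] | None = None,
) -> list[GeneCluster]:
    """Parse CD-HIT ``.clstr`` output into GeneCluster objects.

    ``sequence_lookup`` maps sequence ID -> (genome_id, sequence); when not
    given, genome IDs are taken as the prefix of the sequence ID before the
    first '|' and sequences are left empty.
    """
    clusters: list[GeneCluster] = []
    current: list[tuple[str, str, str]] = []
    current_rep: str | None = None
    current_id: str | None = None

    def _resolve(seq_id: str) -> tuple[str, str, str]:
        if sequence_lookup is not None:
            genome_id, seq = sequence_lookup[seq_id]
        else:
            genome_id, seq = seq_id.split("|", 1)[0], ""
        return (genome_id, seq_id, seq)

    def _flush():
        nonlocal current, current_rep, current_id
        if current_id is not None:
            if current_rep is None:
                current_rep = current[0][1]
            clusters.append(GeneCluster(current_id, current, current_rep))
        current, current_rep, current_id = [], None, None

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                _flush()
                current_id = "C" + line[1:].strip().replace("Cluster ", "").strip()
            else:
                mobj = _CLSTR_ENTRY.match(line)
                if mobj is None:
                    raise ValueError(f"unparseable .clstr line: {line!r}")
                seq_id, tail = mobj.groups()
                current.append(_resolve(seq_id))
                if tail.strip() == "*":
                    current_rep = seq_id
    _flush()
    return clusters


def read_protein_fastas(paths: dict[str, str]) -> list[tuple[str, str, str]]:
    """Read per-genome protein FASTA files: {genome_id: path} -> records."""
    records = []
    for genome_id, path in sorted(paths.items()):
        for rec in SeqIO.parse(path, "fasta"):
            records.append((genome_id, rec.id, str(rec.seq)))
    return records
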