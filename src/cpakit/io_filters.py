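"""Sequence I/O and pre-processing filters.

Implements the screens applied to the CPA sequence pool before alignment and
tree building: a minimum-length screen (short entries cannot span the full
NhaA fold), greedy identity clustering (a CD-HIT surrogate: representatives by
decreasing length, membership by global-alignment identity), and the
essential-region coverage screen that drops queries whose profile alignment
misses functionally indispensable match columns (notably the TM-5 ion-binding
aspartate anchoring motif position 7).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

log = logging.getLogger(__name__)

VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWYX")


class FastaParseError(ValueError):
    """Malformed FASTA input (duplicate ids, empty file, illegal characters)."""


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence: unique id, free-text description, residues."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise FastaParseError("sequence record with empty id")
        if not self.residues:
            raise FastaParseError(f"record {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the pre-processing screens (defaults as used for CPAs)."""

    min_length: int = 300
    seed_cluster_identity: float = 0.90
    pool_cluster_identity: float = 0.70
    essential_coverage: float = 0.70

    def __post_init__(self):
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        for ident in (self.seed_cluster_identity, self.pool_cluster_identity):
            if not 0 < ident <= 1:
                raise ValueError("cluster identities must lie in (0, 1]")


def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file into validated records.

    Residues are uppercased (lowercase input is accepted and logged); duplicate
    ids, an empty file, or characters outside the amino-acid alphabet (+X)
    raise :class:`FastaParseError` naming the offending record.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaParseError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        raw = str(rec.seq)
        if raw != raw.upper():
            log.info("record %s: lowercase residues uppercased", rec.id)
        residues = raw.upper().replace(".", "-")
        bad = set(residues) - VALID_RESIDUES - {"-"}
        if bad:
            raise FastaParseError(
                f"record {rec.id!r} contains illegal characters {sorted(bad)}"
            )
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(SequenceRecord(rec.id, residues, desc))
    if not records:
        raise FastaParseError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def length_filter(
    records: Sequence[SequenceRecord], min_length: int = 300
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Partition records into (kept, dropped); kept iff length >= min_length."""
    kept = [r for r in records if len(r) >= min_length]
    dropped = [r for r in records if len(r) < min_length]
    return kept, dropped


@dataclass
class Cluster:
    representative: SequenceRecord
    members: list[SequenceRecord] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.members)


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    return aligner


def global_identity(a: str, b: str, aligner: PairwiseAligner | None = None) -> float:
    """Identity = matches / alignment length under global alignment."""
    aligner = aligner or _make_aligner()
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    return counts.identities / aln.length


def greedy_identity_cluster(
    records: Sequence[SequenceRecord], identity_threshold: float
) -> list[Cluster]:
    """Greedy length-sorted clustering: each record joins the first existing
    representative at >= threshold identity, else founds a new cluster.

    Sorting by decreasing length is stable, so equal-length records keep input
    order (deterministic representatives).
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity threshold must lie in (0, 1]")
    if not records:
        raise ValueError("cannot cluster an empty record set")
    aligner = _make_aligner()
    ordered = sorted(records, key=len, reverse=True)
    clusters: list[Cluster] = []
    for rec in ordered:
        for cluster in clusters:
            if rec.residues == cluster.representative.residues or global_identity(
                rec.residues, cluster.representative.residues, aligner
            ) >= identity_threshold:
                cluster.members.append(rec)
                break
        else:
            clusters.append(Cluster(representative=rec, members=[rec]))
    return clusters


def write_cluster_table(clusters: Sequence[Cluster], path) -> None:
    with open(path, "w") as fh:
        fh.write("record_id\tcluster_id\trepresentative\n")
        for i, cluster in enumerate(clusters):
            for rec in cluster.members:
                flag = int(rec.id == cluster.representative.id)
                fh.write(f"{rec.id}\t{i}\t{flag}\n")


def essential_coverage_filter(
    alignment_maps: Mapping[str, "AlignmentMap"],
    records: Sequence[SequenceRecord],
    essential_columns: Sequence[int],
    anchor_column: int,
    min_coverage: float = 0.70,
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Keep records whose alignment covers the essential match columns.

    A record is kept iff the fraction of ``essential_columns`` (1-based match
    states) aligned to query residues is >= ``min_coverage`` (inclusive) and
    ``anchor_column`` — the match state carrying motif position 7, the TM-5
    ion-binding aspartate — is not deleted.

    ``alignment_maps`` maps record id -> :class:`cpakit.hmm.AlignmentMap`.
    """
    if not essential_columns:
        raise ValueError("essential_columns must be non-empty")
    kept, dropped = [], []
    for rec in records:
        amap = alignment_maps[rec.id]
        M = amap.n_match_columns
        for col in list(essential_columns) + [anchor_column]:
            if not 1 <= col <= M:
                raise ValueError(
                    f"essential column {col} outside profile range 1..{M}"
                )
        aligned = sum(
            1 for col in essential_columns if amap.query_index_of_column(col) is not None
        )
        coverage = aligned / len(essential_columns)
        if coverage >= min_coverage and amap.query_index_of_column(anchor_column) is not None:
            kept.append(rec)
        else:
            dropped.append(rec)
    return kept, dropped
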