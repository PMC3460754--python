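"""Readers and writers for the formats the pipeline touches.

FASTA holds transcripts and reads (qualities are irrelevant to
zero-mismatch matching, so FASTQ is not consumed); newick holds gene trees
with RAxML-style bootstrap node labels; tab-delimited tables with a header
row map cluster members and tips to genomes.  Readers reject malformed
records rather than repairing them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

from .errors import FormatError, ValidationError
from .taxa import PANEL_GENOMES
from .tree import SupportTree, parse_newick_with_support

__all__ = [
    "SequenceRecord",
    "GeneCluster",
    "read_fasta",
    "write_fasta",
    "read_cluster_table",
    "write_cluster_table",
    "read_tip_genome_table",
    "write_tip_genome_table",
]

_ALPHABET = re.compile(r"^[ACGTN]+$")


@dataclass(frozen=True)
class SequenceRecord:
    """A DNA sequence (uppercase, alphabet ACGTN) with a unique id."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValidationError("empty sequence id")
        if not self.seq:
            raise ValidationError(f"record {self.id!r} has an empty sequence")
        if not _ALPHABET.match(self.seq):
            bad = sorted(set(self.seq) - set("ACGTN"))
            raise ValidationError(
                f"record {self.id!r} contains non-ACGTN characters: {bad}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class GeneCluster:
    """A homolog cluster: member sequences, genome map, and (optionally)
    its gene tree."""

    cluster_id: str
    members: list[SequenceRecord] = field(default_factory=list)
    genome_of: dict[str, str] = field(default_factory=dict)
    tree: SupportTree | None = None

    def __post_init__(self):
        for rec in self.members:
            if rec.id not in self.genome_of:
                raise ValidationError(
                    f"cluster {self.cluster_id}: member {rec.id!r} missing "
                    "from genome map"
                )
        if self.tree is not None:
            members = {r.id for r in self.members} | set(self.genome_of)
            extra = set(self.tree.tip_labels()) - members
            if extra:
                raise ValidationError(
                    f"cluster {self.cluster_id}: tree tips not in members: "
                    f"{sorted(extra)}"
                )

    def genomes(self) -> set[str]:
        return set(self.genome_of.values())


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (possibly wrapped) multi-FASTA file; sequences are uppercased
    and validated against the ACGTN alphabet; ids must be unique."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: FASTA record with empty id")
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has empty sequence")
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        try:
            records.append(SequenceRecord(rec.id, seq, desc))
        except ValidationError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    return records


def write_fasta(
    records: Iterable[SequenceRecord], path: str | Path, width: int = 70
) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# TSV tables


def _read_tsv(path: str | Path, columns: tuple[str, ...]) -> list[list[str]]:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: missing header row")
    header = lines[0].split("\t")
    if header[: len(columns)] != list(columns):
        raise FormatError(
            f"{path}: expected columns {columns}, found {tuple(header)}"
        )
    rows = []
    for ln in lines[1:]:
        parts = ln.split("\t")
        if len(parts) < len(columns):
            raise FormatError(f"{path}: short row {ln!r}")
        rows.append(parts)
    return rows


def read_cluster_table(
    path: str | Path, panel: frozenset[str] | set[str] = PANEL_GENOMES
) -> dict[str, list[tuple[str, str]]]:
    """Read the cluster membership table (cluster_id, member_id, genome).

    Returns ``cluster_id -> [(member_id, genome), ...]`` with genomes
    validated against the taxon panel and member ids unique per cluster.
    """
    out: dict[str, list[tuple[str, str]]] = {}
    for cluster_id, member_id, genome, *_ in _read_tsv(
        path, ("cluster_id", "member_id", "genome")
    ):
        if genome not in panel:
            raise ValidationError(
                f"{path}: unknown genome {genome!r} for member {member_id!r}"
            )
        members = out.setdefault(cluster_id, [])
        if any(m == member_id for m, _ in members):
            raise ValidationError(
                f"{path}: duplicate member {member_id!r} in cluster {cluster_id}"
            )
        members.append((member_id, genome))
    return out


def write_cluster_table(
    clusters: Mapping[str, Iterable[tuple[str, str]]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tmember_id\tgenome\n")
        for cid in clusters:
            for member_id, genome in clusters[cid]:
                fh.write(f"{cid}\t{member_id}\t{genome}\n")


def read_tip_genome_table(
    path: str | Path, panel: frozenset[str] | set[str] = PANEL_GENOMES
) -> dict[str, str]:
    """Read a (tip, genome) map; genomes validated against the panel."""
    out: dict[str, str] = {}
    for tip, genome, *_ in _read_tsv(path, ("tip", "genome")):
        if genome not in panel:
            raise ValidationError(f"{path}: unknown genome {genome!r}")
        if tip in out:
            raise ValidationError(f"{path}: duplicate tip {tip!r}")
        out[tip] = genome
    return out


def write_tip_genome_table(tip_genome: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("tip\tgenome\n")
        for tip, genome in tip_genome.items():
            fh.write(f"{tip}\t{genome}\n")


def read_tree_file(path: str | Path, tip_genome: Mapping[str, str]) -> SupportTree:
    """Read one newick tree (RAxML support dialect) from a file."""
    text = Path(path).read_text().strip()
    return parse_newick_with_support(text, tip_genome)
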