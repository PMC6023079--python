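"""Amplicon read cleanup and dereplication (forward reads only).

The cleanup mirrors a strict quality workflow for single-end 16S reads:

1. remove the 4-nt degenerate heterogeneity spacer from the 5' end,
   unconditionally (the spacer is degenerate by design, so its letters
   are never inspected);
2. reject reads containing any ambiguity code (anything outside A/C/G/T)
   after spacer removal;
3. reject reads with any base below the Phred quality floor (default 20)
   — a per-base hard filter, not sliding-window trimming;
4. reject reads shorter than the minimum length (default 240 nt) after
   trimming.

Surviving reads are dereplicated by exact string identity, keeping
per-site abundances, and sorted by total abundance (descending, ties
broken lexicographically by sequence) — the ordering the greedy OTU
clusterer requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

__all__ = [
    "Read",
    "UniqueSequence",
    "RejectedRead",
    "read_fastq",
    "clean_reads",
    "dereplicate",
    "write_derep_fasta",
    "write_rejection_log",
]

_DNA = frozenset("ACGT")


@dataclass
class Read:
    """A single amplicon read with per-base Phred qualities."""

    read_id: str
    sequence: str
    qualities: list[int]
    site_id: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id!r}: sequence/quality length mismatch"
            )


@dataclass
class RejectedRead:
    read_id: str
    reason: str  # "ambiguity" | "low_quality" | "too_short"
    site_id: str = ""


@dataclass
class UniqueSequence:
    """A dereplicated sequence with per-site read counts."""

    sequence: str
    size_by_site: dict[str, int] = field(default_factory=dict)

    @property
    def total_size(self) -> int:
        return sum(self.size_by_site.values())


def read_fastq(path: str | Path, site_id: str = "") -> list[Read]:
    """Load a Phred+33 FASTQ file into :class:`Read` records."""
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append(
            Read(
                read_id=rec.id,
                sequence=str(rec.seq).upper(),
                qualities=list(rec.letter_annotations["phred_quality"]),
                site_id=site_id,
            )
        )
    return reads


def clean_reads(
    reads: list[Read],
    min_quality: int = 20,
    spacer_length: int = 4,
    min_length: int = 240,
) -> tuple[list[Read], list[RejectedRead]]:
    """Apply spacer removal, ambiguity, quality and length filters.

    Returns ``(survivors, rejections)``; each rejected read carries the
    first rule it violated, checked in the order ambiguity, quality,
    length. Spacer removal happens first and is never itself a cause of
    rejection (a read shorter than the spacer is rejected as too short).
    With ``spacer_length=0`` the operation is idempotent.
    """
    kept: list[Read] = []
    rejected: list[RejectedRead] = []
    for read in reads:
        seq = read.sequence[spacer_length:]
        quals = read.qualities[spacer_length:]
        if not _DNA.issuperset(seq):
            rejected.append(RejectedRead(read.read_id, "ambiguity", read.site_id))
        elif any(q < min_quality for q in quals):
            rejected.append(RejectedRead(read.read_id, "low_quality", read.site_id))
        elif len(seq) < min_length:
            rejected.append(RejectedRead(read.read_id, "too_short", read.site_id))
        else:
            kept.append(Read(read.read_id, seq, quals, read.site_id))
    return kept, rejected


def dereplicate(reads: list[Read]) -> list[UniqueSequence]:
    """Collapse identical sequences, tracking per-site abundance.

    Output is sorted by total abundance descending, then by sequence
    lexicographically — a deterministic order for greedy clustering.
    The sum of all sizes equals the number of input reads.
    """
    by_seq: dict[str, dict[str, int]] = {}
    for read in reads:
        sites = by_seq.setdefault(read.sequence, {})
        sites[read.site_id] = sites.get(read.site_id, 0) + 1
    uniques = [UniqueSequence(seq, sites) for seq, sites in by_seq.items()]
    uniques.sort(key=lambda u: (-u.total_size, u.sequence))
    return uniques


def write_derep_fasta(uniques: list[UniqueSequence], path: str | Path) -> None:
    """Write uniques as FASTA with USEARCH-style ``;size=N`` annotations.

    Sites are recorded as ``;site=S1+S2`` (sorted) after the size field.
    """
    with open(path, "w") as fh:
        for i, u in enumerate(uniques, 1):
            sites = "+".join(sorted(u.size_by_site))
            fh.write(f">u{i};size={u.total_size};site={sites}\n{u.sequence}\n")


def write_rejection_log(rejections: list[RejectedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tsite_id\treason\n")
        for r in rejections:
            fh.write(f"{r.read_id}\t{r.site_id}\t{r.reason}\n")
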