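"""Cultured-isolate comparison: region extraction and OTU co-clustering.

Full-length 16S sequences from cultured isolates are trimmed to the
amplified hypervariable region by locating the forward primer and the
reverse complement of the reverse primer (IUPAC-aware, minimal-mismatch
placement), then co-clustered with OTU centroids at 97% identity to
answer "which OTUs did we manage to culture?".

OTU centroids are seeded as cluster founders first (in abundance order),
then isolates (lexicographically), so isolates attach to OTUs rather
than founding clusters that would absorb them.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cluster import OTU, pairwise_identity

__all__ = [
    "RegionSpec",
    "RegionExtractionError",
    "extract_region",
    "cocluster",
    "write_clusters_tsv",
    "write_match_report_tsv",
    "write_region_fasta",
]

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RegionSpec:
    """Primer pair delimiting an amplified 16S region.

    The reverse primer is given in primer orientation and matched on the
    template as its reverse complement. ``expected_length`` is advisory
    (the region between primers, primers excluded).
    """

    forward_primer: str
    reverse_primer: str
    max_mismatches: int = 2
    expected_length: int | None = None

    def __post_init__(self) -> None:
        if not self.forward_primer or not self.reverse_primer:
            raise ValueError("primers must be nonempty")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


class RegionExtractionError(ValueError):
    """A primer could not be placed within the mismatch budget."""


def _mismatches(primer: str, window: str) -> int:
    n = 0
    for p, b in zip(primer, window):
        if b not in _IUPAC.get(p, p):
            n += 1
    return n


def _best_match(primer: str, seq: str, start: int = 0) -> tuple[int, int]:
    """(position, mismatches) of the minimal-mismatch placement of
    ``primer`` in ``seq[start:]``; earliest position wins ties."""
    best_pos, best_mm = -1, len(primer) + 1
    for i in range(start, len(seq) - len(primer) + 1):
        mm = _mismatches(primer, seq[i : i + len(primer)])
        if mm < best_mm:
            best_pos, best_mm = i, mm
    return best_pos, best_mm


def extract_region(full_sequence: str, spec: RegionSpec) -> str:
    """Trim a full-length sequence to the inter-primer region.

    IUPAC degeneracy in primers matches any compatible base at zero
    cost. Raises :class:`RegionExtractionError` naming the primer when
    its best placement exceeds ``max_mismatches``.
    """
    seq = full_sequence.upper()
    fwd = spec.forward_primer.upper()
    rev_rc = reverse_complement(spec.reverse_primer.upper())
    fpos, fmm = _best_match(fwd, seq)
    if fpos < 0 or fmm > spec.max_mismatches:
        raise RegionExtractionError(
            f"forward primer not found within {spec.max_mismatches} mismatches"
        )
    rpos, rmm = _best_match(rev_rc, seq, start=fpos + len(fwd))
    if rpos < 0 or rmm > spec.max_mismatches:
        raise RegionExtractionError(
            f"reverse primer not found within {spec.max_mismatches} mismatches"
        )
    return seq[fpos + len(fwd) : rpos]


def cocluster(
    otu_centroids: list[OTU],
    isolate_fragments: dict[str, str],
    threshold: float = 0.97,
):
    """Greedy co-clustering of OTU centroids and isolate fragments.

    Centroids are seeded first in abundance order (ties by OTU id), then
    isolates in lexicographic id order; each sequence joins the first
    existing cluster whose founder is within the identity radius, else
    founds its own. Returns ``(clusters, matches)`` where ``clusters``
    maps cluster id -> list of ``(member_id, role)`` with role
    ``"otu"`` or ``"isolate"``, and ``matches`` maps each isolate id to
    the matched OTU id or ``None`` (unmatched).
    """
    if not otu_centroids and not isolate_fragments:
        raise ValueError("cocluster requires at least one input sequence")
    seeds = sorted(otu_centroids, key=lambda o: (-o.total_count, o.otu_id))
    members: list[tuple[str, str, str]] = [  # (id, role, sequence)
        (o.otu_id, "otu", o.centroid_sequence) for o in seeds
    ] + [(iid, "isolate", isolate_fragments[iid]) for iid in sorted(isolate_fragments)]

    founders: list[tuple[str, str]] = []  # (founder_id, sequence)
    clusters: dict[str, list[tuple[str, str]]] = {}
    assignment: dict[str, str] = {}
    for mid, role, seq in members:
        placed = None
        for fid, fseq in founders:
            if pairwise_identity(seq, fseq) >= threshold:
                placed = fid
                break
        if placed is None:
            founders.append((mid, seq))
            placed = mid
            clusters[mid] = []
        clusters[placed].append((mid, role))
        assignment[mid] = placed

    matches: dict[str, str | None] = {}
    for iid in isolate_fragments:
        cluster = clusters[assignment[iid]]
        otus_here = [m for m, role in cluster if role == "otu"]
        matches[iid] = otus_here[0] if otus_here else None
    return clusters, matches


def write_clusters_tsv(clusters: dict[str, list[tuple[str, str]]], path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence_id\tcluster_id\trole\n")
        for cid, members in clusters.items():
            for mid, role in members:
                fh.write(f"{mid}\t{cid}\t{role}\n")


def write_match_report_tsv(matches: dict[str, str | None], path) -> None:
    with open(path, "w") as fh:
        fh.write("isolate_id\tmatched_otu\n")
        for iid in sorted(matches):
            fh.write(f"{iid}\t{matches[iid] or 'unmatched'}\n")


def write_region_fasta(fragments: dict[str, str], path) -> None:
    """Region-trimmed sequences, ready for external alignment/tree tools."""
    with open(path, "w") as fh:
        for sid in sorted(fragments):
            fh.write(f">{sid}\n{fragments[sid]}\n")
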