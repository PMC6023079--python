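"""Greedy 97%-identity centroid clustering and read-to-OTU mapping.

Operational taxonomic units (OTUs) are formed by a single greedy pass
over abundance-sorted unique sequences: each unique either joins the
first existing centroid within the identity radius or founds a new OTU.
Singleton uniques (below ``min_unique_size``) can neither found nor join
clusters, but their reads are recaptured when all cleaned reads are
mapped back to the accepted centroids.

Identity between two sequences is computed from an edit-distance-optimal
global (Needleman-Wunsch) alignment as matches / alignment columns,
terminal gaps included in the denominator. A ``matched_columns`` dialect
(gap columns excluded from the denominator) is available for
compatibility with tools that report identity over aligned letters only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib
import pandas as pd

from .reads import Read, UniqueSequence

__all__ = ["OTU", "OTUTable", "pairwise_identity", "cluster_otus", "map_reads"]

_CIGAR_RE = re.compile(r"(\d+)([=XID])")


@dataclass
class OTU:
    otu_id: str
    centroid_sequence: str
    counts_by_site: dict[str, int] = field(default_factory=dict)

    @property
    def total_count(self) -> int:
        return sum(self.counts_by_site.values())


class OTUTable:
    """An ordered list of OTUs plus the OTU x site count matrix."""

    def __init__(self, otus: list[OTU], site_ids: list[str],
                 unmapped_by_site: dict[str, int] | None = None) -> None:
        ids = [o.otu_id for o in otus]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate OTU ids")
        self.otus = otus
        self.site_ids = list(site_ids)
        self.unmapped_by_site = dict(unmapped_by_site or {})

    @property
    def counts(self) -> pd.DataFrame:
        """Integer count matrix, rows = OTUs (in order), columns = sites."""
        data = {
            o.otu_id: [o.counts_by_site.get(s, 0) for s in self.site_ids]
            for o in self.otus
        }
        return pd.DataFrame(data, index=self.site_ids).T.astype(int)

    def presence(self) -> pd.DataFrame:
        return self.counts > 0

    def centroids(self) -> dict[str, str]:
        return {o.otu_id: o.centroid_sequence for o in self.otus}

    def to_tsv(self, path) -> None:
        df = self.counts.copy()
        df.index.name = "otu_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_counts(cls, counts: pd.DataFrame,
                    centroids: dict[str, str] | None = None) -> "OTUTable":
        centroids = centroids or {}
        otus = [
            OTU(str(oid), centroids.get(str(oid), ""),
                {s: int(counts.loc[oid, s]) for s in counts.columns})
            for oid in counts.index
        ]
        return cls(otus, [str(s) for s in counts.columns])


def pairwise_identity(a: str, b: str, denominator: str = "all_columns") -> float:
    """Global-alignment identity between two DNA sequences, in [0, 1].

    The alignment minimizes edit distance; identity is the fraction of
    alignment columns that are matches. With ``denominator="all_columns"``
    (default) gap columns, terminal gaps included, count in the
    denominator; with ``"matched_columns"`` only substitution/match
    columns do.
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires nonempty sequences")
    if b < a:  # canonical argument order: exact symmetry even when
        a, b = b, a  # co-optimal alignments differ in gap placement
    res = edlib.align(a, b, mode="NW", task="path")
    matches = 0
    columns = 0
    aligned_letters = 0
    for num, op in _CIGAR_RE.findall(res["cigar"]):
        n = int(num)
        columns += n
        if op == "=":
            matches += n
        if op in "=X":
            aligned_letters += n
    denom = columns if denominator == "all_columns" else aligned_letters
    return matches / denom


def cluster_otus(
    uniques: list[UniqueSequence],
    threshold: float = 0.97,
    min_unique_size: int = 2,
) -> list[OTU]:
    """Greedy abundance-ordered centroid clustering.

    ``uniques`` must already be sorted by total size descending, ties
    lexicographic (the order :func:`otukit.reads.dereplicate` emits).
    Each unique with size >= ``min_unique_size`` joins the first centroid
    at identity >= ``threshold`` or founds a new OTU; every accepted
    centroid is therefore < ``threshold`` identical to all earlier ones.
    OTU ids are assigned in founding order (``OTU1``, ``OTU2``, ...).
    """
    order = [(-u.total_size, u.sequence) for u in uniques]
    if order != sorted(order):
        raise ValueError("uniques must be sorted by size desc, ties lexicographic")
    otus: list[OTU] = []
    for u in uniques:
        if u.total_size < min_unique_size:
            continue
        placed = False
        for otu in otus:
            if pairwise_identity(u.sequence, otu.centroid_sequence) >= threshold:
                for site, n in u.size_by_site.items():
                    otu.counts_by_site[site] = otu.counts_by_site.get(site, 0) + n
                placed = True
                break
        if not placed:
            otus.append(OTU(f"OTU{len(otus) + 1}", u.sequence, dict(u.size_by_site)))
    return otus


def map_reads(
    reads: list[Read],
    otus: list[OTU],
    threshold: float = 0.97,
) -> OTUTable:
    """Assign every cleaned read to its best centroid at >= ``threshold``.

    Ties on identity go to the earliest-founded OTU. Reads below the
    threshold against every centroid are tallied per site in
    ``OTUTable.unmapped_by_site``. Per site, mapped + unmapped equals the
    number of input reads.
    """
    counts: dict[str, dict[str, int]] = {o.otu_id: {} for o in otus}
    unmapped: dict[str, int] = {}
    site_ids: list[str] = []
    cache: dict[str, tuple[str | None, float]] = {}
    for read in reads:
        if read.site_id not in site_ids:
            site_ids.append(read.site_id)
        hit = cache.get(read.sequence)
        if hit is None:
            best_id: str | None = None
            best_ident = -1.0
            for otu in otus:
                ident = pairwise_identity(read.sequence, otu.centroid_sequence)
                if ident > best_ident:
                    best_ident = ident
                    best_id = otu.otu_id
            hit = (best_id, best_ident)
            cache[read.sequence] = hit
        best_id, best_ident = hit
        if best_id is not None and best_ident >= threshold:
            site_counts = counts[best_id]
            site_counts[read.site_id] = site_counts.get(read.site_id, 0) + 1
        else:
            unmapped[read.site_id] = unmapped.get(read.site_id, 0) + 1
    mapped_otus = [
        OTU(o.otu_id, o.centroid_sequence, counts[o.otu_id]) for o in otus
    ]
    return OTUTable(mapped_otus, site_ids, unmapped)
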