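"""Synthetic amplicon-community generation with known ground truth.

Everything the pipeline consumes can be generated here with a recorded
truth sidecar: a ranked taxonomy, a reference amplicon database (with
optional "uncultured"-style entries), per-site genus communities with
long-tailed (log-normal) abundances, error-bearing FASTQ reads carrying
the 4-nt degenerate 5' heterogeneity spacer, BLAST-tabular hit tables,
and OTU x site presence tables realizing an exact 3-set Venn partition.

All generators are pure functions of their parameters and seed.

The error model is substitutions only — i.i.d. per-base replacement by
one of the three other bases — which keeps every read alignable to its
source amplicon at identity 1 - error_rate in expectation. Bit scores in
generated hit tables are the simple monotone score
``max(0, 2*matches - 3*(non-match columns))`` and E-values are
``K * m * n * 2^(-bitscore)`` with fixed K, m, n: the downstream
classifier depends only on hit ordering and threshold behaviour, not on
Karlin-Altschul statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import edlib
import numpy as np

from .cluster import OTU, OTUTable, _CIGAR_RE
from .classify import HitRecord
from .reads import Read
from .stats import VennSpec
from .taxonomy import TaxonomyTree, is_uninformative

__all__ = [
    "CommunityProfile",
    "ReferenceEntry",
    "ReferenceDB",
    "HitScoring",
    "generate_taxonomy",
    "build_reference_db",
    "lognormal_profile",
    "generate_reads",
    "generate_hit_table",
    "presence_table_from_venn",
    "counts_for_inverse_simpson",
    "write_fastq",
    "write_truth_tsv",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class CommunityProfile:
    """Expected relative genus abundances at one site (sums to 1)."""

    site_id: str
    taxon_abundances: dict[str, float]  # genus node_id -> relative abundance

    def __post_init__(self) -> None:
        vals = list(self.taxon_abundances.values())
        if any(v < 0 for v in vals):
            raise ValueError("abundances must be nonnegative")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise ValueError("abundances must sum to 1")


@dataclass(frozen=True)
class ReferenceEntry:
    subject_id: str
    sequence: str
    taxon_id: str  # node id in the companion TaxonomyTree
    taxon_name: str


class ReferenceDB:
    """A labelled reference amplicon database.

    One *primary* entry exists per covered genus (the amplicon reads are
    generated from); additional entries may be near-identical variants
    or "uncultured"-named decoys.
    """

    def __init__(self, entries: list[ReferenceEntry],
                 primary_by_taxon: dict[str, str]) -> None:
        self.entries = list(entries)
        self._by_id = {e.subject_id: e for e in entries}
        self._primary = dict(primary_by_taxon)  # taxon_id -> subject_id

    def __len__(self) -> int:
        return len(self.entries)

    def amplicon_for(self, taxon_id: str) -> str:
        try:
            return self._by_id[self._primary[taxon_id]].sequence
        except KeyError:
            raise ValueError(f"no reference amplicon for taxon {taxon_id!r}") from None

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for e in self.entries:
                fh.write(
                    f">{e.subject_id} taxon_id={e.taxon_id} taxon_name={e.taxon_name}\n"
                    f"{e.sequence}\n"
                )


def generate_taxonomy(
    n_phyla: int,
    n_genera_per_family: int,
    seed: int,
    n_families_per_phylum: int = 2,
    uninformative_genus_fraction: float = 0.0,
) -> TaxonomyTree:
    """Deterministic ranked taxonomy with full domain->genus paths.

    Each phylum holds one class, one order and ``n_families_per_phylum``
    families of ``n_genera_per_family`` genera. A configurable fraction
    of genera receive "uncultured ..."-style names so that downstream
    uninformative-name handling can be exercised.
    """
    if n_phyla <= 0 or n_genera_per_family <= 0 or n_families_per_phylum <= 0:
        raise ValueError("taxonomy sizes must be positive")
    rng = np.random.default_rng(seed)
    tree = TaxonomyTree()
    n_genera = n_phyla * n_families_per_phylum * n_genera_per_family
    n_unnamed = int(round(uninformative_genus_fraction * n_genera))
    unnamed_idx = set(
        rng.choice(n_genera, size=n_unnamed, replace=False).tolist()
    ) if n_unnamed else set()
    k = 0
    for p in range(1, n_phyla + 1):
        for f in range(1, n_families_per_phylum + 1):
            for g in range(1, n_genera_per_family + 1):
                if k in unnamed_idx:
                    genus = f"uncultured bacterium clone S{k + 1:03d}"
                else:
                    genus = f"Genus{p}f{f}g{g}"
                tree.add_lineage(
                    [
                        "Bacteria",
                        f"Phylum{p}",
                        f"Class{p}",
                        f"Order{p}",
                        f"Family{p}f{f}",
                        genus,
                    ]
                )
                k += 1
    tree.validate()
    return tree


def _random_amplicon(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(len(arr)) < rate
    idx = np.nonzero(hit)[0]
    for i in idx:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def build_reference_db(
    tree: TaxonomyTree,
    seed: int,
    amplicon_length: int = 280,
    variants_per_genus: int = 1,
    variant_divergence: float = 0.005,
    decoy_uncultured_fraction: float = 0.0,
) -> ReferenceDB:
    """Reference amplicons for every genus in ``tree``.

    Amplicons are i.i.d. random sequences, so inter-genus divergence is
    far above the 3% OTU radius. Each genus gets one primary entry plus
    ``variants_per_genus - 1`` near-identical variants (same taxon).
    ``decoy_uncultured_fraction`` of genera additionally get an entry
    named "uncultured bacterium" attached to an unranked environmental
    node under the domain — emulating environmental-clone database
    records that shadow informative ones.
    """
    rng = np.random.default_rng(seed)
    genera = sorted(
        (n.node_id for n in tree.nodes() if n.rank == "genus"),
    )
    if not genera:
        raise ValueError("taxonomy contains no genus nodes")
    decoy_node_id: str | None = None
    if decoy_uncultured_fraction > 0:
        decoy_node_id = tree.add_lineage(
            ["Bacteria", "uncultured bacterium"], ranks=("domain", "no_rank")
        )
    n_decoys = int(round(decoy_uncultured_fraction * len(genera)))
    decoy_idx = set(
        rng.choice(len(genera), size=n_decoys, replace=False).tolist()
    ) if n_decoys else set()
    entries: list[ReferenceEntry] = []
    primary: dict[str, str] = {}
    for gi, gid in enumerate(genera):
        name = tree.node(gid).name
        base = _random_amplicon(rng, amplicon_length)
        for v in range(variants_per_genus):
            sid = f"ref{gi + 1:03d}.{v}"
            seq = base if v == 0 else _mutate(rng, base, variant_divergence)
            entries.append(ReferenceEntry(sid, seq, gid, name))
            if v == 0:
                primary[gid] = sid
        if gi in decoy_idx:
            # decoys are byte-identical to the informative amplicon, so
            # they always co-occur with it among top hits and the
            # skip-uninformative rule is what keeps them out of the LCA
            assert decoy_node_id is not None
            entries.append(
                ReferenceEntry(
                    f"ref{gi + 1:03d}.env", base, decoy_node_id,
                    "uncultured bacterium",
                )
            )
    return ReferenceDB(entries, primary)


def counts_for_inverse_simpson(sobs: int, target_inv: float) -> np.ndarray:
    """An integer count vector with ``sobs`` taxa whose finite-sample
    inverse Simpson index is as close as possible to ``target_inv``.

    Uses a one-dominant-taxon profile ``[A, 1, 1, ..., 1]``: with
    N = A + sobs - 1, the index 1/D = N(N-1) / (A(A-1)) is strictly
    decreasing in A, so the best integer A is found by bisection.
    Useful for building fixtures that hit published diversity values.
    """
    if sobs < 2:
        raise ValueError("need sobs >= 2")
    if not 1.0 < target_inv <= sobs * (sobs + 1) / 2:
        raise ValueError("target_inv out of the reachable range")

    def inv(a: int) -> float:
        n = a + sobs - 1
        return n * (n - 1) / (a * (a - 1))

    lo, hi = 2, 2
    while inv(hi) > target_inv:
        hi *= 2
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if inv(mid) > target_inv:
            lo = mid
        else:
            hi = mid
    best = min((lo, hi), key=lambda a: abs(inv(a) - target_inv))
    return np.array([best] + [1] * (sobs - 1), dtype=np.int64)


def lognormal_profile(
    site_id: str,
    genus_ids: list[str],
    seed: int,
    sigma: float = 1.0,
    min_fraction: float = 0.0,
) -> CommunityProfile:
    """Long-tailed genus abundances: log-normal weights, renormalized.

    ``min_fraction`` floors each relative abundance (approximately) so
    that every genus receives a usable number of reads in small
    simulations.
    """
    rng = np.random.default_rng(seed)
    w = rng.lognormal(mean=0.0, sigma=sigma, size=len(genus_ids))
    w = w / w.sum()
    if min_fraction > 0:
        w = np.maximum(w, min_fraction)
        w = w / w.sum()
    return CommunityProfile(site_id, dict(zip(genus_ids, w.tolist())))


def generate_reads(
    profile: CommunityProfile,
    refdb: ReferenceDB,
    n_reads: int,
    error_rate: float,
    seed: int,
    spacer_length: int = 4,
    quality_floor: int = 30,
    low_quality_fraction: float = 0.0,
    ambiguous_fraction: float = 0.0,
) -> tuple[list[Read], list[tuple[str, str, str]]]:
    """Amplicon reads for one site plus a (read_id, site, taxon) truth list.

    Each read is ``spacer_length`` random bases followed by the genus's
    reference amplicon with i.i.d. substitutions at ``error_rate``.
    Per-base qualities are uniform in [quality_floor, 40]; a configurable
    fraction of reads get one injected low-quality base or one ambiguous
    'N' (both after the spacer) to exercise the cleanup filters.
    """
    if not 0 <= error_rate < 0.03:
        raise ValueError("error_rate must lie in [0, 0.03)")
    rng = np.random.default_rng(seed)
    taxa = list(profile.taxon_abundances)
    probs = np.array([profile.taxon_abundances[t] for t in taxa])
    amplicons = {t: refdb.amplicon_for(t) for t in taxa}  # raises if missing
    counts = rng.multinomial(n_reads, probs)
    reads: list[Read] = []
    truth: list[tuple[str, str, str]] = []
    i = 0
    for taxon, count in zip(taxa, counts):
        amp = amplicons[taxon]
        for _ in range(count):
            i += 1
            rid = f"{profile.site_id}_r{i:06d}"
            spacer = _random_amplicon(rng, spacer_length)
            body = _mutate(rng, amp, error_rate) if error_rate > 0 else amp
            seq = spacer + body
            quals = rng.integers(quality_floor, 41, size=len(seq)).tolist()
            if low_quality_fraction and rng.random() < low_quality_fraction:
                pos = int(rng.integers(spacer_length, len(seq)))
                quals[pos] = int(rng.integers(2, 15))
            if ambiguous_fraction and rng.random() < ambiguous_fraction:
                pos = int(rng.integers(spacer_length, len(seq)))
                seq = seq[:pos] + "N" + seq[pos + 1:]
            reads.append(Read(rid, seq, quals, profile.site_id))
            truth.append((rid, profile.site_id, taxon))
    return reads, truth


@dataclass(frozen=True)
class HitScoring:
    """Synthetic alignment scoring for generated hit tables."""

    match: int = 2
    mismatch_penalty: int = 3
    evalue_k: float = 0.1
    evalue_mn: float = 1.0e6
    min_identity_emit: float = 0.50  # fraction; hits below are not emitted


def _alignment_stats(a: str, b: str) -> tuple[int, int]:
    """(matches, alignment columns) of an edit-distance-optimal global
    alignment."""
    res = edlib.align(a, b, mode="NW", task="path")
    matches = columns = 0
    for num, op in _CIGAR_RE.findall(res["cigar"]):
        n = int(num)
        columns += n
        if op == "=":
            matches += n
    return matches, columns


def generate_hit_table(
    otus: dict[str, str] | list[OTU],
    refdb: ReferenceDB,
    scoring: HitScoring = HitScoring(),
) -> list[HitRecord]:
    """BLAST-outfmt-6-style hit records for each OTU against ``refdb``.

    Percent identity is matches / alignment columns; the bit score is
    monotone in (identity, length); E-value decreases in bit score. Per
    query, hits are sorted by bit score descending (ties: E-value, then
    subject id), so equally distant subjects receive equal scores.
    """
    if len(refdb) == 0:
        raise ValueError("empty reference database")
    if isinstance(otus, list):
        otus = {o.otu_id: o.centroid_sequence for o in otus}
    hits: list[HitRecord] = []
    for qid, qseq in otus.items():
        rows = []
        for e in refdb.entries:
            matches, columns = _alignment_stats(qseq, e.sequence)
            identity = matches / columns
            if identity < scoring.min_identity_emit:
                continue
            bit = float(max(
                0, scoring.match * matches
                - scoring.mismatch_penalty * (columns - matches)
            ))
            evalue = scoring.evalue_k * scoring.evalue_mn * 2.0 ** (-bit)
            rows.append(
                HitRecord(
                    query_id=qid,
                    subject_id=e.subject_id,
                    percent_identity=round(100 * identity, 3),
                    alignment_length=columns,
                    bit_score=bit,
                    e_value=evalue,
                    subject_taxon_id=e.taxon_id,
                    subject_name=e.taxon_name,
                )
            )
        rows.sort(key=lambda h: (-h.bit_score, h.e_value, h.subject_id))
        hits.extend(rows)
    return hits


def write_hit_table(hits: list[HitRecord], path: str | Path) -> None:
    """BLAST outfmt-6 layout plus subject_taxon_id and subject_name."""
    with open(path, "w") as fh:
        fh.write("# qid sid pident alen mism gapo qs qe ss se evalue bits taxid name\n")
        for h in hits:
            mism = h.alignment_length - round(h.alignment_length * h.percent_identity / 100)
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.percent_identity}\t"
                f"{h.alignment_length}\t{mism}\t0\t1\t{h.alignment_length}\t1\t"
                f"{h.alignment_length}\t{h.e_value:.3g}\t{h.bit_score}\t"
                f"{h.subject_taxon_id}\t{h.subject_name}\n"
            )


def presence_table_from_venn(
    spec: VennSpec,
    site_ids: tuple[str, str, str] = ("COL1", "COL3", "COL4"),
    seed: int = 0,
) -> OTUTable:
    """An OTU x 3-site abundance table realizing ``spec`` exactly.

    Membership patterns are emitted region by region (only-A, only-B,
    only-C, AB, AC, BC, ABC); abundances for present cells are drawn
    uniformly in [1, 99].
    """
    rng = np.random.default_rng(seed)
    patterns = [
        (True, False, False), (False, True, False), (False, False, True),
        (True, True, False), (True, False, True), (False, True, True),
        (True, True, True),
    ]
    otus: list[OTU] = []
    k = 0
    for pattern, count in zip(patterns, spec.as_tuple()):
        for _ in range(count):
            k += 1
            counts = {
                site: int(rng.integers(1, 100))
                for site, present in zip(site_ids, pattern) if present
            }
            otus.append(OTU(f"OTU{k}", "", counts))
    return OTUTable(otus, list(site_ids))


def write_fastq(reads: list[Read], path: str | Path) -> None:
    """Phred+33 FASTQ."""
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")


def write_truth_tsv(truth: list[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tsite_id\ttaxon_id\n")
        for rid, site, taxon in truth:
            fh.write(f"{rid}\t{site}\t{taxon}\n")
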