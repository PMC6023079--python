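"""MEGAN-like lowest-common-ancestor classification of OTUs from BLAST
tabular hits.

Each OTU's hit list is reduced in three stages:

1. **Threshold filtering** — keep at most ``max_hits`` hits (by bit
   score; ties broken by lower E-value, then subject id), then drop hits
   failing any absolute threshold (E-value, percent identity, bit score)
   or scoring below ``bitscore_fraction`` of the best *threshold-passing*
   hit. All absolute thresholds are inclusive.
2. **Uninformative-hit resolution** — if at least one retained hit names
   an informative taxon, hits to "uncultured"/"unclassified"-style
   subjects are dropped; if every hit is uninformative, all are kept and
   the result is flagged ``uncultured_only``.
3. **Majority LCA** — hits are tallied per subject taxon; the least
   frequent taxon is removed (ties: lexicographically last name first)
   as long as the survivors still account for >= ``majority_fraction``
   of the original retained-hit count; the assignment is the LCA of the
   surviving taxa. This guards the LCA against a few aberrant outlier
   hits dragging the assignment to an uninformatively high rank.

Default thresholds: E-value <= 1e-15, identity >= 95.5%, bit score
>= 200, bit-score band 99% of best, <= 100 hits, 95% majority.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .taxonomy import (
    CANONICAL_RANKS,
    TaxonomyTree,
    is_uninformative,
)

__all__ = [
    "HitRecord",
    "LcaParams",
    "ClassificationResult",
    "read_hit_table",
    "filter_hits",
    "resolve_uninformative",
    "majority_lca",
    "classify_otu",
    "classify_all",
    "write_classification_tsv",
    "write_run_manifest",
]

#: Ranks reported in a classification rank path (species is omitted:
#: 16S fragments do not resolve species reliably).
REPORT_RANKS: tuple[str, ...] = CANONICAL_RANKS[:6]  # domain .. genus


@dataclass(frozen=True)
class HitRecord:
    """One BLAST tabular (outfmt 6) alignment row, plus subject taxon."""

    query_id: str
    subject_id: str
    percent_identity: float  # 0-100
    alignment_length: int
    bit_score: float
    e_value: float
    subject_taxon_id: str = ""
    subject_name: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError("percent_identity outside [0, 100]")
        if self.bit_score < 0 or self.e_value < 0:
            raise ValueError("negative bit score or E-value")

    @property
    def taxon_key(self) -> str:
        """Identity used for tallying: taxon id when present, else name."""
        return self.subject_taxon_id or self.subject_name


@dataclass(frozen=True)
class LcaParams:
    max_hits: int = 100
    max_evalue: float = 1e-15
    min_identity: float = 95.5  # percent
    min_bitscore: float = 200.0
    bitscore_fraction: float = 0.99  # band relative to best passing hit
    majority_fraction: float = 0.95
    skip_uninformative: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.bitscore_fraction <= 1:
            raise ValueError("bitscore_fraction must be in (0, 1]")
        if not 0 < self.majority_fraction <= 1:
            raise ValueError("majority_fraction must be in (0, 1]")


@dataclass
class ClassificationResult:
    query_id: str
    assigned_node_id: str | None
    rank_path: dict[str, str]  # rank -> name / "unclassified" / "uncultured"
    n_hits_considered: int
    status: str  # "classified" | "uncultured_only" | "no_hits_passed"


_OUTFMT6_COLS = [
    "query_id", "subject_id", "percent_identity", "alignment_length",
    "mismatches", "gap_opens", "q_start", "q_end", "s_start", "s_end",
    "e_value", "bit_score",
]


def read_hit_table(path: str | Path) -> list[HitRecord]:
    """Parse BLAST tabular output (12 standard columns, plus optional
    ``subject_taxon_id`` and ``subject_name``). ``#`` lines are ignored."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    ncols = df.shape[1]
    if ncols < 12:
        raise ValueError(f"hit table has {ncols} columns; expected >= 12")
    names = list(_OUTFMT6_COLS)
    if ncols >= 13:
        names.append("subject_taxon_id")
    if ncols >= 14:
        names.append("subject_name")
    df.columns = names + [f"extra{i}" for i in range(ncols - len(names))]
    hits = []
    for row in df.itertuples(index=False):
        hits.append(
            HitRecord(
                query_id=row.query_id,
                subject_id=row.subject_id,
                percent_identity=float(row.percent_identity),
                alignment_length=int(row.alignment_length),
                bit_score=float(row.bit_score),
                e_value=float(row.e_value),
                subject_taxon_id=str(getattr(row, "subject_taxon_id", "") or ""),
                subject_name=str(getattr(row, "subject_name", "") or ""),
            )
        )
    return hits


def filter_hits(hits: list[HitRecord], params: LcaParams = LcaParams()) -> list[HitRecord]:
    """Apply the hit-count cap, absolute thresholds and bit-score band.

    The cap is applied first (top ``max_hits`` by bit score, ties by
    lower E-value then subject id); the 99% band is relative to the best
    bit score **among capped hits passing the absolute thresholds**, so a
    high-scoring hit that itself fails e.g. the identity threshold cannot
    suppress everything below it.
    """
    if not hits:
        return []
    if len({h.query_id for h in hits}) > 1:
        raise ValueError("filter_hits got hits for more than one query")
    capped = sorted(hits, key=lambda h: (-h.bit_score, h.e_value, h.subject_id))
    capped = capped[: params.max_hits]
    passing = [
        h for h in capped
        if h.e_value <= params.max_evalue
        and h.percent_identity >= params.min_identity
        and h.bit_score >= params.min_bitscore
    ]
    if not passing:
        return []
    best = max(h.bit_score for h in passing)
    band = params.bitscore_fraction * best
    return [h for h in passing if h.bit_score >= band]


def resolve_uninformative(
    hits: list[HitRecord], params: LcaParams = LcaParams()
) -> tuple[list[HitRecord], bool]:
    """Drop uncultured/unclassified-named hits when informative ones exist.

    Returns ``(hits_for_lca, uncultured_only)``. When every hit is
    uninformative they are all kept and the flag is True; the caller
    reports the result under the "uncultured" category.
    """
    if not params.skip_uninformative or not hits:
        return hits, False
    informative = [h for h in hits if not is_uninformative(h.subject_name)]
    if informative:
        return informative, False
    return hits, True


def majority_lca(
    hits: list[HitRecord],
    tree: TaxonomyTree,
    majority_fraction: float = 0.95,
) -> str:
    """LCA of the most frequent subject taxa covering >= the majority
    fraction of the retained hits.

    Taxa are tallied by :attr:`HitRecord.taxon_key`; the least frequent
    taxon is removed iteratively (ties: lexicographically last name
    removed first) while the remaining taxa still account for >=
    ``majority_fraction`` of the ORIGINAL hit count. Returns the node id
    of the LCA of the survivors.
    """
    if not hits:
        raise ValueError("majority_lca of an empty hit set")
    tally: dict[str, int] = {}
    names: dict[str, str] = {}
    for h in hits:
        tally[h.taxon_key] = tally.get(h.taxon_key, 0) + 1
        names.setdefault(h.taxon_key, h.subject_name or h.taxon_key)
    total = len(hits)
    remaining = dict(tally)
    while len(remaining) > 1:
        # candidate for removal: lowest count, ties -> lexicographically
        # last name (then last key, for full determinism)
        victim = min(
            remaining,
            key=lambda k: (remaining[k], _neg_lex(names[k]), _neg_lex(k)),
        )
        if (sum(remaining.values()) - remaining[victim]) / total >= majority_fraction:
            del remaining[victim]
        else:
            break
    node_ids = [_resolve_taxon(tree, key) for key in remaining]
    return tree.lca(node_ids).node_id


class _neg_lex(str):
    """Sort key wrapper inverting lexicographic order."""

    def __lt__(self, other) -> bool:  # type: ignore[override]
        return str.__gt__(self, other)


def _resolve_taxon(tree: TaxonomyTree, key: str) -> str:
    if key in tree:
        return key
    ids = tree.find_by_name(key)
    if not ids:
        raise KeyError(f"taxon {key!r} not found in taxonomy")
    return ids[0]


def _build_rank_path(tree: TaxonomyTree, node_id: str, deeper_label: str) -> dict[str, str]:
    known = tree.rank_path(node_id)
    return {rank: known.get(rank, deeper_label) for rank in REPORT_RANKS}


def classify_otu(
    hits: list[HitRecord],
    tree: TaxonomyTree,
    params: LcaParams = LcaParams(),
    query_id: str | None = None,
) -> ClassificationResult:
    """Full per-OTU classification: filter -> resolve -> majority LCA.

    Canonical ranks deeper than the assigned node are labelled
    ``"unclassified"`` for ordinary assignments and ``"uncultured"`` when
    only uninformative hits survived filtering.
    """
    qid = query_id if query_id is not None else (hits[0].query_id if hits else "")
    retained = filter_hits(hits, params) if hits else []
    if not retained:
        return ClassificationResult(
            query_id=qid,
            assigned_node_id=None,
            rank_path={r: "unclassified" for r in REPORT_RANKS},
            n_hits_considered=0,
            status="no_hits_passed",
        )
    for_lca, uncultured_only = resolve_uninformative(retained, params)
    node_id = majority_lca(for_lca, tree, params.majority_fraction)
    deeper = "uncultured" if uncultured_only else "unclassified"
    return ClassificationResult(
        query_id=qid,
        assigned_node_id=node_id,
        rank_path=_build_rank_path(tree, node_id, deeper),
        n_hits_considered=len(for_lca),
        status="uncultured_only" if uncultured_only else "classified",
    )


def classify_all(
    hits: list[HitRecord],
    tree: TaxonomyTree,
    params: LcaParams = LcaParams(),
    query_ids: list[str] | None = None,
) -> dict[str, ClassificationResult]:
    """Classify every query in a hit table.

    ``query_ids`` may list queries expected in the output; queries with
    no hits in the table are reported as ``no_hits_passed``.
    """
    by_query: dict[str, list[HitRecord]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    all_ids = list(by_query)
    if query_ids is not None:
        all_ids = list(query_ids) + [q for q in all_ids if q not in set(query_ids)]
    return {
        qid: classify_otu(by_query.get(qid, []), tree, params, query_id=qid)
        for qid in all_ids
    }


def write_classification_tsv(
    results: dict[str, ClassificationResult], path: str | Path
) -> None:
    """Per-OTU classification table: query, status, one column per rank."""
    with open(path, "w") as fh:
        fh.write("query_id\tstatus\t" + "\t".join(REPORT_RANKS) + "\n")
        for qid, res in results.items():
            cells = [res.rank_path.get(r, "unclassified") for r in REPORT_RANKS]
            fh.write(f"{qid}\t{res.status}\t" + "\t".join(cells) + "\n")


def write_run_manifest(params: LcaParams, path: str | Path) -> None:
    """Echo the classification parameters alongside the outputs so a
    run can be reproduced from its artifacts."""
    with open(path, "w") as fh:
        fh.write("parameter\tvalue\n")
        for key, value in vars(params).items():
            fh.write(f"{key}\t{value}\n")
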