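"""Rank-level abundance profiles and most-abundant-OTU reports.

A rank profile aggregates an OTU x site count table by the taxon each
OTU was assigned at a canonical rank. OTUs whose classification stops
above the requested rank contribute to the ``unclassified`` pseudo-taxon
row; OTUs classified only through uncultured database entries go to
``uncultured``. These two categories stay separate at every rank.

Percentages are relative to each site's classified read total; the
"average %" column is the unweighted mean of the per-site percentages
(not the pooled-sequence fraction — verified against the per-site /
average arithmetic of published genus tables). Taxa below the pooling
threshold in every site can be pooled into an ``other`` row; the
uncultured/unclassified pseudo-rows are never pooled.
"""

from __future__ import annotations

import pandas as pd

from .classify import ClassificationResult
from .cluster import OTUTable

__all__ = ["rank_profile", "top_otus"]

PSEUDO_TAXA = ("uncultured", "unclassified")


def _taxon_at_rank(res: ClassificationResult, rank: str) -> str:
    name = res.rank_path.get(rank, "unclassified")
    low = name.lower()
    for pseudo in PSEUDO_TAXA:
        if pseudo in low:
            return pseudo
    return name


def rank_profile(
    otu_table: OTUTable,
    classifications: dict[str, ClassificationResult],
    rank: str,
    pool_below: float | None = None,
) -> pd.DataFrame:
    """Per-taxon abundance table at one canonical rank.

    Columns: per-site sequence counts (``<site>_seq``), per-site percent
    (``<site>_pct``), per-site OTU counts (``<site>_otus``), plus
    ``total_seq``, ``avg_pct`` (unweighted mean of per-site percents) and
    ``distinct_otus`` (each OTU counted once across sites). Rows are
    sorted by total sequences descending. With ``pool_below`` set (in
    percent), taxa under the threshold in *every* site are pooled as
    ``other``.
    """
    counts = otu_table.counts
    missing = [oid for oid in counts.index if oid not in classifications]
    if missing:
        raise ValueError(f"OTUs without classification: {missing[:5]}")
    sites = list(counts.columns)
    taxa = pd.Series(
        {oid: _taxon_at_rank(classifications[oid], rank) for oid in counts.index}
    )
    seq = counts.groupby(taxa).sum()
    site_totals = counts.sum(axis=0)
    pct = 100 * seq / site_totals
    otus_per_site = (counts > 0).groupby(taxa).sum()
    distinct = (counts.sum(axis=1) > 0).groupby(taxa).sum()

    prof = pd.DataFrame(index=seq.index)
    for s in sites:
        prof[f"{s}_seq"] = seq[s]
        prof[f"{s}_pct"] = pct[s]
        prof[f"{s}_otus"] = otus_per_site[s]
    prof["total_seq"] = seq.sum(axis=1)
    prof["avg_pct"] = pct.mean(axis=1)
    prof["distinct_otus"] = distinct

    if pool_below is not None:
        pool_mask = (pct < pool_below).all(axis=1) & ~prof.index.isin(PSEUDO_TAXA)
        if pool_mask.any():
            pooled = prof.loc[pool_mask].sum()
            prof = prof.loc[~pool_mask]
            prof.loc["other"] = pooled
    prof = prof.sort_values("total_seq", ascending=False)
    prof.index.name = rank
    return prof


def top_otus(
    otu_table: OTUTable,
    classifications: dict[str, ClassificationResult],
    n: int,
    ranks: tuple[str, ...] = ("class", "family", "genus"),
) -> pd.DataFrame:
    """The ``n`` most abundant OTUs with per-site and average percents.

    Rows are ranked by total reads (ties by OTU id); per-site percent is
    relative to the site total over *all* OTUs; ``avg_pct`` is the
    unweighted mean of the per-site percents; ``cum_coverage`` is the
    cumulative fraction of all reads captured down to each row. Taxon
    columns echo the classification at the requested ranks.
    """
    counts = otu_table.counts
    if n > len(counts):
        raise ValueError(f"n={n} exceeds the {len(counts)} OTUs in the table")
    sites = list(counts.columns)
    totals = counts.sum(axis=1)
    order = totals.sort_values(ascending=False, kind="stable").index[:n]
    site_totals = counts.sum(axis=0)
    grand_total = int(site_totals.sum())

    rep = pd.DataFrame(index=order)
    for s in sites:
        rep[f"{s}_pct"] = 100 * counts.loc[order, s] / site_totals[s]
    rep["avg_pct"] = rep[[f"{s}_pct" for s in sites]].mean(axis=1)
    rep["total_seq"] = totals[order]
    rep["cum_coverage"] = totals[order].cumsum() / grand_total
    for rank in ranks:
        rep[rank] = [
            classifications[oid].rank_path.get(rank, "unclassified") if oid in classifications else "unclassified"
            for oid in order
        ]
    rep.index.name = "otu_id"
    return rep
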