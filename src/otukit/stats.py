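"""Alpha-diversity estimators, rarefaction, and shared-OTU (Venn) analysis.

Diversity follows the finite-sample (mothur) convention:

    D   = sum n_i (n_i - 1) / (N (N - 1))      (Simpson index)
    1/D = inverse Simpson, an effective OTU count
    sobs = number of OTUs with n_i > 0          (observed richness)
    evenness = (1/D) / sobs

The Simpson index D is the probability that two reads drawn without
replacement belong to the same OTU. On very small inputs the finite-
sample inverse Simpson can exceed sobs; the report carries a flag rather
than clamping.

Shared-OTU analysis partitions the union of three sites' OTUs into the
seven regions of a 3-set Venn diagram, and reports pairwise shared
percentages with the *sum-of-richness* denominator:
percent = 100 * |A and B| / (|A| + |B|).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "DiversityReport",
    "SharedReport",
    "VennSpec",
    "rarefy",
    "diversity",
    "rarefaction_curve",
    "venn_regions",
    "pairwise_shared",
    "all_pairwise_shared",
    "write_diversity_tsv",
    "write_venn_tsv",
    "write_shared_tsv",
]


@dataclass(frozen=True)
class VennSpec:
    """Region sizes of a 3-set partition (A, B, C in site order)."""

    only_a: int
    only_b: int
    only_c: int
    ab_only: int
    ac_only: int
    bc_only: int
    abc: int

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.as_tuple()):
            raise ValueError("Venn region counts must be nonnegative")

    def as_tuple(self) -> tuple[int, ...]:
        return (self.only_a, self.only_b, self.only_c,
                self.ab_only, self.ac_only, self.bc_only, self.abc)

    @property
    def union(self) -> int:
        return sum(self.as_tuple())

    def site_richness(self) -> tuple[int, int, int]:
        a = self.only_a + self.ab_only + self.ac_only + self.abc
        b = self.only_b + self.ab_only + self.bc_only + self.abc
        c = self.only_c + self.ac_only + self.bc_only + self.abc
        return a, b, c


@dataclass
class DiversityReport:
    site_id: str
    sobs: int
    simpson_d: float
    inv_simpson: float
    evenness: float
    evenness_exceeds_one: bool = False


@dataclass
class SharedReport:
    pair: tuple[str, str]
    shared: int
    denominator: int  # sum of the two sites' richness
    percent: float  # 1 dp


def _as_counts(counts) -> np.ndarray:
    arr = np.asarray(counts, dtype=np.int64)
    if arr.ndim != 1:
        raise ValueError("counts must be one-dimensional")
    if (arr < 0).any():
        raise ValueError("counts must be nonnegative")
    return arr


def rarefy(counts, depth: int, seed: int | None = None) -> np.ndarray:
    """Subsample a count vector to ``depth`` reads without replacement.

    Multivariate hypergeometric draw; deterministic for a fixed seed.
    """
    arr = _as_counts(counts)
    total = int(arr.sum())
    if depth > total:
        raise ValueError(f"depth {depth} exceeds site total {total}")
    rng = np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(arr, depth)


def diversity(counts, site_id: str = "") -> DiversityReport:
    """Finite-sample Simpson diversity report for one site."""
    arr = _as_counts(counts)
    n_total = int(arr.sum())
    if n_total < 2:
        raise ValueError("diversity requires at least two reads")
    sobs = int((arr > 0).sum())
    simpson_d = float((arr * (arr - 1)).sum() / (n_total * (n_total - 1)))
    inv = float("inf") if simpson_d == 0 else 1.0 / simpson_d
    evenness = inv / sobs
    return DiversityReport(
        site_id=site_id,
        sobs=sobs,
        simpson_d=simpson_d,
        inv_simpson=inv,
        evenness=evenness,
        evenness_exceeds_one=evenness > 1.0,
    )


def rarefaction_curve(
    counts,
    depths,
    mode: str = "analytic",
    n_resamples: int = 1000,
    seed: int | None = None,
) -> np.ndarray:
    """Expected observed richness at each subsampling depth.

    Analytic mode uses the exact hypergeometric expectation

        E[sobs at d] = sum_i (1 - C(N - n_i, d) / C(N, d))

    evaluated in log space; resample mode averages sobs over seeded
    hypergeometric draws. The curve is non-decreasing in depth.
    """
    arr = _as_counts(counts)
    total = int(arr.sum())
    depths = np.atleast_1d(np.asarray(depths, dtype=np.int64))
    if (depths < 0).any() or (depths > total).any():
        raise ValueError("depths must lie in [0, total reads]")
    nz = arr[arr > 0]
    if mode == "analytic":
        out = np.empty(len(depths), dtype=float)
        for j, d in enumerate(depths):
            # log C(N - n_i, d) - log C(N, d), with C(m, d) = 0 when m < d
            m = total - nz
            logp = np.full(len(nz), -np.inf)
            ok = m >= d
            if d == 0:
                logp[:] = 0.0
            elif ok.any():
                mm = m[ok].astype(float)
                logp[ok] = (
                    gammaln(mm + 1) - gammaln(d + 1) - gammaln(mm - d + 1)
                    - (gammaln(total + 1) - gammaln(d + 1) - gammaln(total - d + 1))
                )
            out[j] = float(np.sum(1.0 - np.exp(logp)))
        return out
    if mode == "resample":
        rng = np.random.default_rng(seed)
        out = np.empty(len(depths), dtype=float)
        for j, d in enumerate(depths):
            draws = rng.multivariate_hypergeometric(arr, int(d), size=n_resamples)
            out[j] = float((draws > 0).sum(axis=1).mean())
        return out
    raise ValueError(f"unknown mode {mode!r}")


def venn_regions(presence: pd.DataFrame) -> tuple[VennSpec, dict]:
    """Partition three sites' OTU sets into the 7 Venn regions.

    ``presence`` is a boolean (or count) DataFrame, rows = OTUs,
    exactly three site columns in (A, B, C) order. Returns the region
    spec and a totals dict with per-site richness, the union size, and
    the narrative percentages (integer-rounded): triple-shared %,
    single-site unique %, and shared-by->=2-sites %.
    """
    if presence.shape[1] != 3:
        raise ValueError("venn_regions requires exactly 3 site columns")
    pres = presence.astype(bool)
    pres = pres[pres.any(axis=1)]
    a, b, c = (pres.iloc[:, i].to_numpy() for i in range(3))
    spec = VennSpec(
        only_a=int((a & ~b & ~c).sum()),
        only_b=int((~a & b & ~c).sum()),
        only_c=int((~a & ~b & c).sum()),
        ab_only=int((a & b & ~c).sum()),
        ac_only=int((a & ~b & c).sum()),
        bc_only=int((~a & b & c).sum()),
        abc=int((a & b & c).sum()),
    )
    union = spec.union
    richness = dict(zip(presence.columns, spec.site_richness()))
    unique = spec.only_a + spec.only_b + spec.only_c
    multi = spec.ab_only + spec.ac_only + spec.bc_only + spec.abc
    totals = {
        "richness": richness,
        "union": union,
        "triple_shared": spec.abc,
        "triple_shared_pct": round(100 * spec.abc / union) if union else 0,
        "unique": unique,
        "unique_pct": round(100 * unique / union) if union else 0,
        "multi_site_pct": round(100 * multi / union) if union else 0,
    }
    return spec, totals


def pairwise_shared(presence: pd.DataFrame, site_a: str, site_b: str) -> SharedReport:
    """Shared OTUs between two sites over the sum of their richness."""
    for s in (site_a, site_b):
        if s not in presence.columns:
            raise ValueError(f"unknown site {s!r}")
    pres = presence.astype(bool)
    a = pres[site_a].to_numpy()
    b = pres[site_b].to_numpy()
    shared = int((a & b).sum())
    denom = int(a.sum() + b.sum())
    pct = round(100 * shared / denom, 1) if denom else 0.0
    return SharedReport((site_a, site_b), shared, denom, pct)


def all_pairwise_shared(presence: pd.DataFrame) -> tuple[list[SharedReport], float, float]:
    """Shared-OTU reports for the three site pairs, plus mean +/- SD of
    the (unrounded) percentages."""
    sites = list(presence.columns)
    if len(sites) != 3:
        raise ValueError("expected exactly 3 sites")
    pairs = [(sites[0], sites[1]), (sites[0], sites[2]), (sites[2], sites[1])]
    reports = [pairwise_shared(presence, a, b) for a, b in pairs]
    pcts = np.array([100 * r.shared / r.denominator for r in reports])
    return reports, float(pcts.mean()), float(pcts.std(ddof=1))


def write_diversity_tsv(reports: list[DiversityReport], path) -> None:
    with open(path, "w") as fh:
        fh.write("site_id\tsobs\tsimpson_d\tinv_simpson\tevenness\tflag\n")
        for r in reports:
            flag = "evenness>1" if r.evenness_exceeds_one else ""
            fh.write(
                f"{r.site_id}\t{r.sobs}\t{r.simpson_d:.6g}\t"
                f"{r.inv_simpson:.6g}\t{r.evenness:.6g}\t{flag}\n"
            )


def write_venn_tsv(spec: VennSpec, totals: dict, path) -> None:
    regions = ["only_a", "only_b", "only_c", "ab_only", "ac_only",
               "bc_only", "abc"]
    with open(path, "w") as fh:
        fh.write("region\tcount\n")
        for name, count in zip(regions, spec.as_tuple()):
            fh.write(f"{name}\t{count}\n")
        fh.write(f"union\t{totals['union']}\n")
        fh.write(f"triple_shared_pct\t{totals['triple_shared_pct']}\n")
        fh.write(f"unique_pct\t{totals['unique_pct']}\n")


def write_shared_tsv(reports: list[SharedReport], path) -> None:
    with open(path, "w") as fh:
        fh.write("site_a\tsite_b\tshared\tdenominator\tpercent\n")
        for r in reports:
            fh.write(
                f"{r.pair[0]}\t{r.pair[1]}\t{r.shared}\t"
                f"{r.denominator}\t{r.percent}\n"
            )
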