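"""Independent brute-force oracles used across the test suite.

These deliberately avoid the library's own code paths (no edlib, no
tree LCA helper, no greedy clusterer) so that each check is a genuine
second route to the same answer.
"""

from __future__ import annotations

import numpy as np


def nw_edit_distance(a: str, b: str) -> int:
    """Textbook Needleman-Wunsch / Levenshtein DP, unit costs."""
    la, lb = len(a), len(b)
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        ai = a[i - 1]
        for j in range(1, lb + 1):
            cur[j] = min(
                prev[j - 1] + (ai != b[j - 1]),
                prev[j] + 1,
                cur[j - 1] + 1,
            )
        prev = cur
    return prev[lb]


def root_path_lca(paths: list[list[str]]) -> str:
    """LCA as the deepest shared element of root-to-node paths."""
    common = paths[0]
    for p in paths[1:]:
        keep = 0
        for x, y in zip(common, p):
            if x != y:
                break
            keep += 1
        common = common[:keep]
    return common[-1]


def greedy_cluster_membership(
    sequences: list[str], identity_fn, threshold: float
) -> list[int]:
    """Single-pass greedy clustering re-simulation.

    ``sequences`` must already be in presentation order. Returns, per
    sequence, the index of its cluster founder in that order.
    """
    founders: list[int] = []
    assignment: list[int] = []
    for i, seq in enumerate(sequences):
        placed = None
        for f in founders:
            if identity_fn(seq, sequences[f]) >= threshold:
                placed = f
                break
        if placed is None:
            founders.append(i)
            placed = i
        assignment.append(placed)
    return assignment


def brute_filter_hits(hits, max_hits, max_evalue, min_identity, min_bitscore,
                      bitscore_fraction):
    """Independent application of the four hit-filtering rules."""
    capped = sorted(hits, key=lambda h: (-h.bit_score, h.e_value, h.subject_id))
    capped = capped[:max_hits]
    absolute = [
        h for h in capped
        if h.e_value <= max_evalue
        and h.percent_identity >= min_identity
        and h.bit_score >= min_bitscore
    ]
    if not absolute:
        return []
    best = max(h.bit_score for h in absolute)
    return [h for h in absolute if h.bit_score >= bitscore_fraction * best]


def greedy_majority_taxa(hits, majority_fraction):
    """Independent greedy outlier removal over the taxon tally.

    Removes the least frequent taxon (ties: lexicographically last
    subject name, then last key) while the survivors keep covering
    >= majority_fraction of the original hit count; returns the set of
    surviving taxon keys.
    """
    keys = [h.subject_taxon_id or h.subject_name for h in hits]
    names = {}
    for h, k in zip(hits, keys):
        names.setdefault(k, h.subject_name or k)
    total = len(keys)
    tally = {k: keys.count(k) for k in set(keys)}
    while len(tally) > 1:
        ordered = sorted(
            tally,
            key=lambda k: (tally[k],
                           [-ord(c) for c in names[k]],
                           [-ord(c) for c in k]),
        )
        victim = ordered[0]
        if (sum(tally.values()) - tally[victim]) / total >= majority_fraction:
            del tally[victim]
        else:
            break
    return set(tally)


def simpson_by_pair_enumeration(counts) -> float:
    """P(two reads drawn without replacement share an OTU), enumerated
    over every ordered pair of individual reads."""
    labels = []
    for i, n in enumerate(counts):
        labels.extend([i] * int(n))
    n_total = len(labels)
    same = 0
    for i in range(n_total):
        for j in range(n_total):
            if i != j and labels[i] == labels[j]:
                same += 1
    return same / (n_total * (n_total - 1))


def min_mismatch_window(primer: str, seq: str, iupac: dict[str, str]):
    """Sliding-window minimal-mismatch primer placement (earliest wins)."""
    best = (-1, len(primer) + 1)
    for i in range(len(seq) - len(primer) + 1):
        mm = sum(
            seq[i + k] not in iupac.get(p, p) for k, p in enumerate(primer)
        )
        if mm < best[1]:
            best = (i, mm)
    return best
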