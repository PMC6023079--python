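"""Reference taxonomy: a rooted tree of named, ranked taxa.

The tree backs every taxonomic operation in the pipeline: lowest-common-
ancestor (LCA) queries during hit-based classification, and rank-level
aggregation when building class/order/family/genus abundance profiles.

Two on-disk dialects are read:

* ``lineage_strings`` — a text file where each line is either a
  semicolon-delimited lineage (``Bacteria;Actinobacteria;...;Rhodococcus``)
  or ``<sequence_id> <TAB> <lineage>`` (SILVA-style two-column TSV).
  Ranks are assigned positionally: domain, phylum, class, order, family,
  genus, species.
* ``nodes_names`` — the NCBI taxdump layout: ``nodes.dmp`` and ``names.dmp``
  with ``<TAB>|<TAB>`` field separators.

Names that carry no usable taxon (``uncultured``, ``unclassified`` ...)
are detected by :func:`is_uninformative`; the classifier uses this to skip
environmental database entries when informative hits are available.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "CANONICAL_RANKS",
    "DEFAULT_UNINFORMATIVE_MARKERS",
    "TaxonomyError",
    "TaxonomyNode",
    "TaxonomyTree",
    "load_taxonomy",
    "is_uninformative",
]

#: Canonical ranks from shallowest to deepest. ``no_rank`` nodes may
#: interleave anywhere and are skipped when reporting at canonical ranks.
CANONICAL_RANKS: tuple[str, ...] = (
    "domain",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

_RANK_DEPTH = {r: i for i, r in enumerate(CANONICAL_RANKS)}

DEFAULT_UNINFORMATIVE_MARKERS: tuple[str, ...] = (
    "uncultured",
    "unclassified",
    "unidentified",
    "environmental sample",
    "metagenome",
)


class TaxonomyError(ValueError):
    """Structural or lookup error in a taxonomy source or tree."""


@dataclass(frozen=True)
class TaxonomyNode:
    node_id: str
    name: str
    rank: str  # one of CANONICAL_RANKS, "root" or "no_rank"
    parent_id: str | None  # None only for the root


class TaxonomyTree:
    """Rooted taxonomy with ancestor and LCA queries.

    Nodes are indexed by id and (non-uniquely) by name; name collisions
    across lineages are resolved by full-path identity, never by name,
    because genus homonyms exist across families.
    """

    def __init__(self) -> None:
        self._nodes: dict[str, TaxonomyNode] = {}
        self._children: dict[str, list[str]] = {}
        self._by_name: dict[str, list[str]] = {}
        self.root_id = "root"
        self._add_node(TaxonomyNode("root", "root", "root", None))

    # -- construction -------------------------------------------------

    def _add_node(self, node: TaxonomyNode) -> None:
        if node.node_id in self._nodes:
            raise TaxonomyError(f"duplicate node id {node.node_id!r}")
        self._nodes[node.node_id] = node
        self._children.setdefault(node.node_id, [])
        if node.parent_id is not None:
            self._children.setdefault(node.parent_id, []).append(node.node_id)
        self._by_name.setdefault(node.name, []).append(node.node_id)

    def add_lineage(self, names: Sequence[str], ranks: Sequence[str] | None = None) -> str:
        """Insert a root-anchored path of names, merging shared prefixes.

        Returns the id of the deepest node. ``ranks`` defaults to the
        canonical order, positionally.
        """
        if ranks is None:
            ranks = CANONICAL_RANKS[: len(names)]
        if len(ranks) != len(names):
            raise TaxonomyError("ranks and names length mismatch")
        parent = self.root_id
        for name, rank in zip(names, ranks):
            node_id = f"{parent}|{name}" if parent != "root" else name
            if node_id not in self._nodes:
                if rank not in _RANK_DEPTH and rank != "no_rank":
                    raise TaxonomyError(f"unknown rank label {rank!r}")
                self._add_node(TaxonomyNode(node_id, name, rank, parent))
            parent = node_id
        return parent

    # -- lookups ------------------------------------------------------

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    def node(self, node_id: str) -> TaxonomyNode:
        try:
            return self._nodes[node_id]
        except KeyError:
            raise TaxonomyError(f"unknown node id {node_id!r}") from None

    def nodes(self) -> Iterable[TaxonomyNode]:
        return self._nodes.values()

    def children(self, node_id: str) -> list[str]:
        return list(self._children.get(node_id, []))

    def find_by_name(self, name: str) -> list[str]:
        """All node ids bearing ``name`` (homonyms possible)."""
        return list(self._by_name.get(name, []))

    def path_to_root(self, node_id: str) -> list[str]:
        """Node ids from ``node_id`` up to and including the root."""
        path = []
        cur: str | None = node_id
        while cur is not None:
            node = self.node(cur)
            path.append(cur)
            cur = node.parent_id
        return path

    def is_ancestor(self, ancestor_id: str, node_id: str) -> bool:
        """True iff ``ancestor_id`` lies on ``node_id``'s root path (or equals it)."""
        return ancestor_id in self.path_to_root(node_id)

    def lca(self, node_ids: Iterable[str]) -> TaxonomyNode:
        """Deepest node that is an ancestor-or-equal of every input node."""
        ids = list(node_ids)
        if not ids:
            raise TaxonomyError("lca of an empty node set")
        common: list[str] | None = None
        for nid in ids:
            path = self.path_to_root(nid)[::-1]  # root -> node
            if common is None:
                common = path
            else:
                keep = 0
                for a, b in zip(common, path):
                    if a != b:
                        break
                    keep += 1
                common = common[:keep]
        assert common  # root is always shared
        return self.node(common[-1])

    # -- rank reporting -----------------------------------------------

    def rank_path(self, node_id: str) -> dict[str, str]:
        """Names at each canonical rank along the root path.

        ``no_rank`` nodes are transparently skipped; ranks not present on
        the path are absent from the result.
        """
        out: dict[str, str] = {}
        for nid in self.path_to_root(node_id):
            node = self.node(nid)
            if node.rank in _RANK_DEPTH:
                out[node.rank] = node.name
        return out

    def canonical_rank(self, node_id: str) -> str | None:
        """Deepest canonical rank at-or-above ``node_id`` (None if only root)."""
        for nid in self.path_to_root(node_id):
            node = self.node(nid)
            if node.rank in _RANK_DEPTH:
                return node.rank
        return None

    def ancestor_at_rank(self, node_id: str, rank: str) -> TaxonomyNode | None:
        """The node's ancestor-or-self at the given canonical rank, if any."""
        for nid in self.path_to_root(node_id):
            node = self.node(nid)
            if node.rank == rank:
                return node
        return None

    # -- serialization ------------------------------------------------

    def write_lineages(self) -> list[str]:
        """Normalized semicolon lineages, one per leaf, sorted."""
        out = []
        for nid, node in self._nodes.items():
            if nid == self.root_id or self._children.get(nid):
                continue
            names = [
                self.node(p).name
                for p in self.path_to_root(nid)[::-1]
                if p != self.root_id
            ]
            out.append(";".join(names))
        return sorted(out)

    def validate(self) -> None:
        """Check structural invariants; raise TaxonomyError on violation."""
        for nid, node in self._nodes.items():
            seen = set()
            cur: str | None = nid
            while cur is not None:
                if cur in seen:
                    raise TaxonomyError(f"cycle detected at node {cur!r}")
                seen.add(cur)
                if cur not in self._nodes:
                    raise TaxonomyError(f"orphan node: parent {cur!r} missing")
                cur = self._nodes[cur].parent_id
            if self.root_id not in seen:
                raise TaxonomyError(f"node {nid!r} not reachable from root")
            # ranks must deepen along the path (no_rank interleaves freely)
            depth = -1
            for pid in self.path_to_root(nid)[::-1]:
                r = self._nodes[pid].rank
                if r in _RANK_DEPTH:
                    d = _RANK_DEPTH[r]
                    if d <= depth:
                        raise TaxonomyError(
                            f"rank order violation at node {pid!r} (rank {r})"
                        )
                    depth = d


def is_uninformative(
    name: str, markers: Sequence[str] = DEFAULT_UNINFORMATIVE_MARKERS
) -> bool:
    """True iff ``name`` contains any marker, case-insensitively.

    Flags database entries like ``uncultured bacterium`` or
    ``Unclassified Pseudonocardiaceae`` that carry no usable taxon name
    at lower ranks. The marker list is configurable.
    """
    low = name.lower()
    return any(m in low for m in markers)


def _parse_lineage_line(line: str) -> list[str]:
    if "\t" in line:
        line = line.split("\t", 1)[1]
    return [part.strip() for part in line.split(";") if part.strip()]


def _load_lineage_strings(path: Path) -> TaxonomyTree:
    tree = TaxonomyTree()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            names = _parse_lineage_line(line)
            if not names:
                raise TaxonomyError(f"line {lineno}: empty lineage")
            if len(names) > len(CANONICAL_RANKS):
                raise TaxonomyError(
                    f"line {lineno}: lineage deeper than {len(CANONICAL_RANKS)} ranks"
                )
            tree.add_lineage(names)
    tree.validate()
    return tree


_TAXDUMP_RANKS = {
    "superkingdom": "domain",  # NCBI dumps use superkingdom for domain
    "domain": "domain",
    "phylum": "phylum",
    "class": "class",
    "order": "order",
    "family": "family",
    "genus": "genus",
    "species": "species",
    "no rank": "no_rank",
    "no_rank": "no_rank",
}


def _load_nodes_names(nodes_path: Path, names_path: Path) -> TaxonomyTree:
    names: dict[str, str] = {}
    with open(names_path) as fh:
        for raw in fh:
            fields = [f.strip() for f in raw.rstrip("\n").rstrip("|").split("\t|\t")]
            if len(fields) < 2:
                continue
            taxid, name = fields[0], fields[1]
            name_class = fields[3].rstrip("\t|").strip() if len(fields) > 3 else ""
            if name_class in ("scientific name", "") and taxid not in names:
                names[taxid] = name

    tree = TaxonomyTree()
    rows: list[tuple[str, str, str]] = []
    with open(nodes_path) as fh:
        for lineno, raw in enumerate(fh, 1):
            fields = [f.strip() for f in raw.rstrip("\n").rstrip("|").split("\t|\t")]
            if len(fields) < 3:
                raise TaxonomyError(f"nodes line {lineno}: too few fields")
            taxid, parent, rank = fields[0], fields[1], fields[2]
            if rank not in _TAXDUMP_RANKS:
                raise TaxonomyError(f"nodes line {lineno}: unknown rank label {rank!r}")
            rows.append((taxid, parent, _TAXDUMP_RANKS[rank]))

    # the taxdump convention: the root row has taxid == parent
    root_rows = [r for r in rows if r[0] == r[1]]
    if len(root_rows) != 1:
        raise TaxonomyError(f"expected exactly one root row, found {len(root_rows)}")
    root_taxid = root_rows[0][0]

    id_map = {root_taxid: tree.root_id}
    pending = [r for r in rows if r[0] != root_taxid]
    while pending:
        progressed = False
        rest = []
        for taxid, parent, rank in pending:
            if parent in id_map:
                node = TaxonomyNode(taxid, names.get(taxid, taxid), rank, id_map[parent])
                tree._add_node(node)
                id_map[taxid] = taxid
                progressed = True
            else:
                rest.append((taxid, parent, rank))
        if not progressed:
            bad = ", ".join(r[0] for r in rest[:5])
            raise TaxonomyError(f"orphan or cyclic nodes (taxids: {bad})")
        pending = rest
    tree.validate()
    return tree


def load_taxonomy(
    source: str | Path | tuple[str | Path, str | Path],
    dialect: str = "lineage_strings",
) -> TaxonomyTree:
    """Load a taxonomy reference into a :class:`TaxonomyTree`.

    Parameters
    ----------
    source
        For ``lineage_strings``: a path to the lineage file. For
        ``nodes_names``: a ``(nodes_path, names_path)`` pair.
    dialect
        ``"lineage_strings"`` or ``"nodes_names"``.
    """
    if dialect == "lineage_strings":
        return _load_lineage_strings(Path(source))  # type: ignore[arg-type]
    if dialect == "nodes_names":
        nodes_path, names_path = source  # type: ignore[misc]
        return _load_nodes_names(Path(nodes_path), Path(names_path))
    raise TaxonomyError(f"unknown dialect {dialect!r}")
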