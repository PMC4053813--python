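"""Taxonomic tree: parent links, ranks, LCA and rank-ancestor queries.

The tree follows NCBI taxonomy conventions: every node has a parent taxon
ID, a free-form rank string and an optional scientific name; the root is
the unique node that is its own parent.  The seven named ranks (species,
genus, family, order, class, phylum, kingdom) are recognized for
rank-level queries, but nodes may lack any given rank among their
ancestors — rank queries then return ``None``.

LCA queries walk both ancestor paths to the root and take the deepest
shared node; taxonomies are shallow (depth ~10-40) so no preprocessing is
warranted.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Optional

__all__ = ["TaxonomyTree", "load_taxonomy", "SEVEN_RANKS"]

#: canonical rank order, most specific first
SEVEN_RANKS = ("species", "genus", "family", "order", "class", "phylum", "kingdom")

MAX_TAXID = 2**32 - 1  # taxon IDs must fit the 4-byte record payload


class TaxonomyTree:
    """Rooted taxonomy with LCA, rank-ancestor and clade-membership queries."""

    def __init__(self, nodes: dict[int, tuple[int, str, str]]):
        """``nodes`` maps taxid -> (parent taxid, rank, scientific name)."""
        self._parent: dict[int, int] = {}
        self._rank: dict[int, str] = {}
        self._name: dict[int, str] = {}
        root = None
        for taxid, (parent, rank, name) in nodes.items():
            if not 1 <= taxid <= MAX_TAXID:
                raise ValueError(f"taxid {taxid} outside the 4-byte range [1, {MAX_TAXID}]")
            self._parent[taxid] = parent
            self._rank[taxid] = rank
            self._name[taxid] = name
            if parent == taxid:
                if root is not None:
                    raise ValueError(f"multiple roots: {root} and {taxid}")
                root = taxid
        if root is None:
            raise ValueError("no root node (a node that is its own parent)")
        self.root_id = root
        for taxid, parent in self._parent.items():
            if parent not in self._parent:
                raise ValueError(f"node {taxid} references missing parent {parent}")
        self._depth: dict[int, int] = {root: 0}
        self._compute_depths()

    def _compute_depths(self) -> None:
        for taxid in self._parent:
            path = []
            t = taxid
            while t not in self._depth:
                path.append(t)
                t = self._parent[t]
                if t in path:
                    raise ValueError(f"cycle in taxonomy at taxid {t}")
            d = self._depth[t]
            for node in reversed(path):
                d += 1
                self._depth[node] = d

    # -- basic accessors ----------------------------------------------------

    def __contains__(self, taxid: int) -> bool:
        return taxid in self._parent

    def __len__(self) -> int:
        return len(self._parent)

    def __iter__(self):
        return iter(self._parent)

    def parent(self, taxid: int) -> int:
        self._require(taxid)
        return self._parent[taxid]

    def rank(self, taxid: int) -> str:
        self._require(taxid)
        return self._rank[taxid]

    def name(self, taxid: int) -> str:
        self._require(taxid)
        return self._name[taxid]

    def depth(self, taxid: int) -> int:
        self._require(taxid)
        return self._depth[taxid]

    def _require(self, taxid: int) -> None:
        if taxid not in self._parent:
            raise KeyError(f"unknown taxid {taxid}")

    def ancestors(self, taxid: int) -> list[int]:
        """Path from ``taxid`` (inclusive) up to the root (inclusive)."""
        self._require(taxid)
        path = [taxid]
        while path[-1] != self.root_id:
            path.append(self._parent[path[-1]])
        return path

    # -- queries ------------------------------------------------------------

    def lca(self, a: int, b: int) -> int:
        """Lowest common ancestor of two taxa."""
        self._require(a)
        self._require(b)
        while a != b:
            if self._depth[a] >= self._depth[b]:
                a = self._parent[a]
            else:
                b = self._parent[b]
        return a

    def lca_many(self, taxa: Iterable[int]) -> int:
        """LCA of a non-empty collection of taxa (fold of pairwise LCA)."""
        it = iter(taxa)
        try:
            acc = next(it)
        except StopIteration:
            raise ValueError("lca of an empty taxon set") from None
        self._require(acc)
        for t in it:
            acc = self.lca(acc, t)
        return acc

    def ancestor_at_rank(self, taxid: int, rank: str) -> Optional[int]:
        """The ancestor-or-self of ``taxid`` at ``rank``, or None if absent."""
        self._require(taxid)
        t = taxid
        while True:
            if self._rank[t] == rank:
                return t
            if t == self.root_id:
                return None
            t = self._parent[t]

    def is_in_clade(self, taxid: int, clade_root: int) -> bool:
        """True iff ``clade_root`` is an ancestor-or-self of ``taxid``."""
        self._require(taxid)
        self._require(clade_root)
        t = taxid
        while True:
            if t == clade_root:
                return True
            if t == self.root_id:
                return False
            t = self._parent[t]

    def children_map(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {t: [] for t in self._parent}
        for t, p in self._parent.items():
            if t != p:
                out[p].append(t)
        return out


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _parse_dmp_line(line: str) -> list[str]:
    # NCBI dump records: fields separated by "\t|\t", terminated "\t|"
    line = line.rstrip("\n")
    if line.endswith("\t|"):
        line = line[: -len("\t|")]
    return line.split("\t|\t")


def load_taxonomy(
    nodes_path, names_path=None, dialect: str = "ncbi-dmp"
) -> TaxonomyTree:
    """Load a taxonomy from NCBI-style dump files or a simple TSV.

    ``ncbi-dmp``: nodes.dmp with pipe-delimited fields (taxid, parent,
    rank, ...) and an optional names.dmp from which scientific names are
    taken.  ``tsv``: four tab-separated columns taxid, parent, rank, name.
    Missing names yield empty strings.  Structural defects (cycles,
    dangling parents, zero or multiple roots) raise with the offending
    taxid.
    """
    nodes: dict[int, tuple[int, str, str]] = {}
    if dialect == "ncbi-dmp":
        with _open_text(nodes_path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                fields = _parse_dmp_line(line)
                if len(fields) < 3:
                    raise ValueError(f"malformed nodes.dmp line: {line!r}")
                taxid, parent, rank = int(fields[0]), int(fields[1]), fields[2]
                nodes[taxid] = (parent, rank, "")
        if names_path is not None:
            names: dict[int, str] = {}
            with _open_text(names_path) as fh:
                for line in fh:
                    if not line.strip():
                        continue
                    fields = _parse_dmp_line(line)
                    if len(fields) < 4:
                        continue
                    taxid, name, name_class = int(fields[0]), fields[1], fields[3]
                    if name_class == "scientific name" or taxid not in names:
                        names[taxid] = name
            nodes = {
                t: (p, r, names.get(t, "")) for t, (p, r, _) in nodes.items()
            }
    elif dialect == "tsv":
        with _open_text(nodes_path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 3:
                    raise ValueError(f"line {lineno}: expected >=3 TSV columns")
                name = fields[3] if len(fields) > 3 else ""
                nodes[int(fields[0])] = (int(fields[1]), fields[2], name)
    else:
        raise ValueError(f"unknown taxonomy dialect {dialect!r}")
    return TaxonomyTree(nodes)
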