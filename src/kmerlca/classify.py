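"""Read classification by root-to-leaf path scoring over k-mer hit taxa.

Every k-mer window of a read is queried against the database; the taxa
returned (each the LCA of the genomes containing that k-mer), together
with all their ancestors, form a pruned subtree of the taxonomy — the
*classification tree*.  Each node is weighted by the number of k-mer
windows whose stored LCA is exactly that taxon.  Every root-to-leaf path
is scored by the sum of weights along it; the read is labelled with the
leaf of the maximum-scoring path, or with the LCA of the tied leaves when
several paths tie.  Reads with no database hits stay unclassified.

Treating each k-mer as an independent piece of evidence and resolving
conflicts through path scores lets a small minority of stray hits (from
conserved or contaminating sequence) be outvoted by the dominant lineage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import codec
from .db import KrakenDB, QueryCursor
from .taxonomy import TaxonomyTree

__all__ = [
    "HIT_AMBIGUOUS",
    "ClassificationResult",
    "classify",
    "classify_quick",
    "classify_pair",
    "hit_list_runs",
    "PAIR_JOINT",
]

#: marker used in hit lists for windows containing non-ACGT characters
HIT_AMBIGUOUS = -1

#: spacer joining mates of a pair; its windows are ambiguous by construction
PAIR_JOINT = "NNNNN"


@dataclass
class ClassificationResult:
    """Outcome for one read: label, per-position hits, winning path score."""

    status: str  # "classified" | "unclassified"
    label: int  # taxon ID; 0 when unclassified
    hit_list: list[int]  # per window: taxid hit, 0 miss, HIT_AMBIGUOUS
    path_score: int = 0
    read_id: str = ""

    @property
    def classified(self) -> bool:
        return self.status == "classified"

    @property
    def n_hits(self) -> int:
        return sum(1 for h in self.hit_list if h > 0)


def _query_hits(
    db: KrakenDB,
    tree: TaxonomyTree,
    read: str,
    exclusion: Optional[int],
    stop_at_first: bool = False,
) -> list[int]:
    """Per-window query outcomes, cursor carried across positions.

    Hits whose stored LCA lies inside the exclusion clade are masked to
    misses (0).  With ``stop_at_first`` the scan ends at the first
    surviving hit (quick mode) and the list covers only the windows seen.
    """
    codes, buckets, valid = codec.sequence_minimizers(read.upper(), db.k, db.params)
    cursor = QueryCursor()
    hits: list[int] = []
    for i in range(codes.shape[0]):
        if not valid[i]:
            hits.append(HIT_AMBIGUOUS)
            continue
        taxon = db.query(int(codes[i]), cursor)
        if taxon is not None and exclusion is not None and tree.is_in_clade(taxon, exclusion):
            taxon = None
        hits.append(0 if taxon is None else taxon)
        if stop_at_first and hits[-1] > 0:
            break
    return hits


def _score_tree(hits: list[int], tree: TaxonomyTree) -> tuple[int, int]:
    """(label, path score) from hit weights via RTL path enumeration.

    Returns (0, 0) when there are no hits.
    """
    weights: dict[int, int] = {}
    for h in hits:
        if h > 0:
            weights[h] = weights.get(h, 0) + 1
    if not weights:
        return 0, 0
    # pruned tree: hit taxa plus their ancestors (weight 0 unless hit)
    nodes: set[int] = set()
    for t in weights:
        nodes.update(tree.ancestors(t))
    has_child = {t: False for t in nodes}
    for t in nodes:
        p = tree.parent(t)
        if t != tree.root_id:
            has_child[p] = True
    # cumulative root-to-node scores, walking each leaf's ancestor path
    leaves = [t for t in nodes if not has_child[t]]
    path_cache: dict[int, int] = {}

    def path_score(t: int) -> int:
        if t in path_cache:
            return path_cache[t]
        w = weights.get(t, 0)
        s = w if t == tree.root_id else w + path_score(tree.parent(t))
        path_cache[t] = s
        return s

    best = max(path_score(leaf) for leaf in leaves)
    winners = [leaf for leaf in leaves if path_score(leaf) == best]
    label = winners[0] if len(winners) == 1 else tree.lca_many(winners)
    return label, best


def classify(
    db: KrakenDB,
    tree: TaxonomyTree,
    read: str,
    exclusion: Optional[int] = None,
    read_id: str = "",
) -> ClassificationResult:
    """Classify a read by maximum root-to-leaf path score.

    ``exclusion`` masks database hits falling inside the given clade, as
    used by clade-exclusion experiments that emulate novel organisms.
    """
    if exclusion is not None and exclusion not in tree:
        raise KeyError(f"exclusion taxon {exclusion} not in taxonomy")
    hits = _query_hits(db, tree, read, exclusion)
    label, score = _score_tree(hits, tree)
    if label == 0:
        return ClassificationResult("unclassified", 0, hits, 0, read_id)
    return ClassificationResult("classified", label, hits, score, read_id)


def classify_quick(
    db: KrakenDB,
    tree: TaxonomyTree,
    read: str,
    exclusion: Optional[int] = None,
    read_id: str = "",
) -> ClassificationResult:
    """Quick mode: label with the stored LCA of the first database hit.

    Skips the path-scoring machinery entirely; ambiguous windows are
    skipped, masked hits do not stop the scan.
    """
    if exclusion is not None and exclusion not in tree:
        raise KeyError(f"exclusion taxon {exclusion} not in taxonomy")
    hits = _query_hits(db, tree, read, exclusion, stop_at_first=True)
    for h in hits:
        if h > 0:
            return ClassificationResult("classified", h, hits, 1, read_id)
    return ClassificationResult("unclassified", 0, hits, 0, read_id)


def classify_pair(
    db: KrakenDB,
    tree: TaxonomyTree,
    mate1: str,
    mate2: str,
    quick: bool = False,
    exclusion: Optional[int] = None,
    read_id: str = "",
) -> ClassificationResult:
    """Classify a read pair as one unit, mates joined by ``NNNNN``.

    Windows spanning the joint contain N and are ambiguous, so the spacer
    contributes nothing; the pair is effectively scored on the union of
    both mates' k-mers.
    """
    if not mate1 or not mate2:
        raise ValueError("both mates must be non-empty")
    joined = mate1 + PAIR_JOINT + mate2
    fn = classify_quick if quick else classify
    return fn(db, tree, joined, exclusion=exclusion, read_id=read_id)


def hit_list_runs(hits: list[int]) -> str:
    """Run-length encode a hit list as space-separated ``taxid:count`` tokens.

    Misses appear as ``0:count`` and ambiguous windows as ``A:count``.
    """
    if not hits:
        return ""
    tokens: list[str] = []
    prev, count = hits[0], 0
    for h in hits + [None]:  # sentinel flushes the last run
        if h == prev:
            count += 1
        else:
            key = "A" if prev == HIT_AMBIGUOUS else str(prev)
            tokens.append(f"{key}:{count}")
            prev, count = h, 1
    return " ".join(tokens)
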