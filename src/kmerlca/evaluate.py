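"""Accuracy metrics for taxonomic classification and clade-exclusion runs.

Rank-level accuracy uses five tallies per measured rank:

* A — reads with a truth taxon at the rank that were classified correctly
  at (or below) that rank;
* B — reads with any truth taxon at the rank (the sensitivity denominator,
  including unclassified reads);
* C — reads labelled at or below the *correct* taxon at the rank;
* D — reads labelled at or below the rank (right or wrong);
* E — reads labelled *above* the rank but off the correct lineage.

Sensitivity = A/B and precision = C/(D+E).  A label above the measured
rank on the correct lineage (e.g. the right family when measuring at
genus, or the root) affects neither C, D nor E: a selective classifier is
not penalized for backing off to a correct coarser label.

Clade exclusion masks database hits from a read's clade of origin before
classification, emulating the arrival of a novel organism, and scores the
result at a higher rank.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .classify import ClassificationResult, classify
from .db import KrakenDB, GenomeLibrary
from .taxonomy import TaxonomyTree, SEVEN_RANKS

__all__ = [
    "RankTally",
    "AccuracyReport",
    "score_rank",
    "clade_exclusion_run",
    "taxonomic_profile",
]


@dataclass
class RankTally:
    """A/B/C/D/E tallies for one measured rank."""

    rank: str
    a: int = 0
    b: int = 0
    c: int = 0
    d: int = 0
    e: int = 0

    @property
    def sensitivity(self) -> Optional[float]:
        return self.a / self.b if self.b else None

    @property
    def precision(self) -> Optional[float]:
        return self.c / (self.d + self.e) if (self.d + self.e) else None


@dataclass
class AccuracyReport:
    """Per-rank tallies keyed by rank name."""

    tallies: dict[str, RankTally] = field(default_factory=dict)

    def to_rows(self) -> list[tuple]:
        rows = []
        for rank in SEVEN_RANKS:
            if rank in self.tallies:
                t = self.tallies[rank]
                rows.append(
                    (rank, t.a, t.b, t.c, t.d, t.e, t.sensitivity, t.precision)
                )
        return rows


def score_rank(
    results: Iterable[ClassificationResult],
    truth: dict[str, int],
    tree: TaxonomyTree,
    rank: str,
) -> RankTally:
    """Tally rank-level accuracy of classification results against truth.

    Reads whose origin taxon has no ancestor at the measured rank are
    excluded entirely.  Unclassified reads count only toward B.
    """
    if rank not in SEVEN_RANKS:
        raise ValueError(f"rank must be one of {SEVEN_RANKS}, got {rank!r}")
    tally = RankTally(rank)
    for res in results:
        if res.read_id not in truth:
            raise KeyError(f"read {res.read_id!r} missing from truth set")
        origin = truth[res.read_id]
        truth_at_rank = tree.ancestor_at_rank(origin, rank)
        if truth_at_rank is None:
            continue  # origin lacks this rank: not part of the experiment
        tally.b += 1
        if not res.classified:
            continue
        label_at_rank = tree.ancestor_at_rank(res.label, rank)
        if label_at_rank is not None:
            # labelled at or below the measured rank
            tally.d += 1
            if label_at_rank == truth_at_rank:
                tally.a += 1
                tally.c += 1
        else:
            # labelled above the rank: harmless if on the correct lineage
            if not tree.is_in_clade(truth_at_rank, res.label):
                tally.e += 1
    return tally


_RANK_ORDER = {r: i for i, r in enumerate(SEVEN_RANKS)}  # 0 = most specific


def eligible_for_exclusion(
    origin: int,
    tree: TaxonomyTree,
    represented: set[int],
    measured_rank: str,
    excluded_rank: str,
) -> Optional[int]:
    """Excluded-rank ancestor of ``origin`` if the read is usable, else None.

    A read is used only when its origin has taxa at both ranks and at
    least two *other* excluded-rank taxa represented in the database share
    the origin's measured-rank ancestor — otherwise no classifier could
    possibly recover the measured-rank taxon once the clade is masked.
    """
    excl = tree.ancestor_at_rank(origin, excluded_rank)
    meas = tree.ancestor_at_rank(origin, measured_rank)
    if excl is None or meas is None:
        return None
    siblings = {
        t
        for t in represented
        if tree.rank(t) == excluded_rank
        and t != excl
        and tree.is_in_clade(t, meas)
    }
    if len(siblings) < 2:
        return None
    return excl


def clade_exclusion_run(
    db: KrakenDB,
    tree: TaxonomyTree,
    reads: Iterable[tuple[str, str]],
    truth: dict[str, int],
    library: GenomeLibrary,
    measured_rank: str,
    excluded_rank: str,
) -> RankTally:
    """Classify reads with their clade of origin masked; score at a rank.

    ``measured_rank`` must be strictly above ``excluded_rank``.  Each
    eligible read is classified with hits at or below its excluded-rank
    ancestor masked out, then scored at the measured rank.  Ineligible
    reads are skipped; with no eligible reads the tally has B = 0 and
    undefined (None) sensitivity.
    """
    for r in (measured_rank, excluded_rank):
        if r not in SEVEN_RANKS:
            raise ValueError(f"unknown rank {r!r}")
    if _RANK_ORDER[measured_rank] <= _RANK_ORDER[excluded_rank]:
        raise ValueError(
            f"measured rank {measured_rank!r} must be above excluded rank {excluded_rank!r}"
        )
    represented = library.represented_taxa(tree)
    results = []
    used_truth = {}
    for read_id, seq in reads:
        if read_id not in truth:
            raise KeyError(f"read {read_id!r} missing from truth set")
        origin = truth[read_id]
        excl = eligible_for_exclusion(
            origin, tree, represented, measured_rank, excluded_rank
        )
        if excl is None:
            continue
        results.append(classify(db, tree, seq, exclusion=excl, read_id=read_id))
        used_truth[read_id] = origin
    return score_rank(results, used_truth, tree, measured_rank)


def taxonomic_profile(
    results: Iterable[ClassificationResult], tree: TaxonomyTree
) -> tuple[dict[int, int], dict[int, int], int]:
    """Per-taxon read counts with cumulative lineage rollup.

    Returns ``(direct, rollup, unclassified)`` where ``direct[t]`` counts
    reads labelled exactly ``t`` and ``rollup[t]`` additionally includes
    reads labelled at any descendant of ``t``.
    """
    direct: dict[int, int] = {}
    rollup: dict[int, int] = {}
    unclassified = 0
    for res in results:
        if not res.classified:
            unclassified += 1
            continue
        direct[res.label] = direct.get(res.label, 0) + 1
        for anc in tree.ancestors(res.label):
            rollup[anc] = rollup.get(anc, 0) + 1
    return direct, rollup, unclassified
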