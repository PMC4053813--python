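"""Minimizer-bucketed k-mer → LCA database: build, query, shrink, serialize.

Each record pairs a canonical k-mer code (8 bytes) with the taxonomy LCA of
every library genome containing that k-mer (4 bytes) — 12 bytes per k-mer.
Records are sorted by (scrambled minimizer value, k-mer code); an offset
array of 4^M + 1 indices maps each minimizer bucket to its half-open record
range, so a query is a binary search inside a single small bucket.  The
scrambled value orders buckets only; within a bucket records are ordered by
their plain canonical codes.

Queries carry a cursor remembering the previous bucket range: overlapping
k-mers from one read usually share a minimizer, so most lookups re-search
the previous range and skip recomputing the minimizer.  The cursor is a
pure work-saving device — answers never depend on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import struct

import numpy as np

from . import codec
from .codec import MinimizerParams
from .taxonomy import TaxonomyTree

__all__ = [
    "GenomeLibrary",
    "ContaminationFilter",
    "KrakenDB",
    "QueryCursor",
    "enumerate_distinct_kmers",
    "build",
    "shrink",
    "save",
    "load",
]

_MAGIC = b"KLDB"
_VERSION = 1
_RECORD_DTYPE = np.dtype([("code", "<u8"), ("taxon", "<u4")])  # 12 bytes


@dataclass
class GenomeLibrary:
    """Reference sequences plus their sequence-ID → taxon-ID mapping."""

    sequences: list[tuple[str, str]]
    taxon_map: dict[str, int]
    draft_ids: set[str] = field(default_factory=set)

    def validate(self, tree: TaxonomyTree) -> None:
        for seqid, _ in self.sequences:
            if seqid not in self.taxon_map:
                raise ValueError(f"sequence {seqid!r} has no taxon mapping")
            taxid = self.taxon_map[seqid]
            if taxid not in tree:
                raise ValueError(
                    f"sequence {seqid!r} maps to taxon {taxid} absent from the taxonomy"
                )

    def represented_taxa(self, tree: TaxonomyTree) -> set[int]:
        """Taxa of library sequences plus all their ancestors."""
        out: set[int] = set()
        for seqid, _ in self.sequences:
            out.update(tree.ancestors(self.taxon_map[seqid]))
        return out


@dataclass
class ContaminationFilter:
    """Adapter k-mer removal and draft-contig edge trimming.

    K-mers occurring in any adapter sequence are removed from the database
    outright.  For sequences flagged as draft contigs, the first and last
    ``draft_edge_trim`` k-mer windows contribute no occurrences (the k-mer
    survives if it also occurs in an untrimmed region).
    """

    adapters: list[str] = field(default_factory=list)
    draft_edge_trim: int = 20

    def adapter_codes(self, k: int) -> np.ndarray:
        chunks = []
        for adapter in self.adapters:
            codes, valid = codec.sequence_codes(adapter, k)
            chunks.append(codes[valid])
        if not chunks:
            return np.empty(0, dtype=np.uint64)
        return np.unique(np.concatenate(chunks))


class QueryCursor:
    """Mutable per-read lookup state: previous bucket range and minimizer."""

    __slots__ = ("lo", "hi", "bucket")

    def __init__(self):
        self.lo = 0
        self.hi = 0
        self.bucket = -1


@dataclass
class KrakenDB:
    """Sorted (k-mer, LCA) record array with a minimizer offset index."""

    k: int
    params: MinimizerParams
    records: np.ndarray  # structured array, _RECORD_DTYPE
    offsets: np.ndarray  # uint64, length 4^M + 1

    def __post_init__(self):
        self.records = np.asarray(self.records, dtype=_RECORD_DTYPE)
        self.offsets = np.asarray(self.offsets, dtype=np.uint64)

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, KrakenDB)
            and self.k == other.k
            and self.params == other.params
            and np.array_equal(self.records, other.records)
            and np.array_equal(self.offsets, other.offsets)
        )

    def query(self, kmer_code: int, cursor: QueryCursor | None = None) -> int | None:
        """Stored LCA for a canonical k-mer code, or None if absent.

        Three steps: (1) binary-search the cursor's previous bucket range;
        (2) on a miss, recompute the minimizer — if it equals the previous
        one the miss is definitive; (3) otherwise fetch the new range from
        the offset index and search it.
        """
        codes = self.records["code"]
        code = np.uint64(kmer_code)
        if cursor is not None and cursor.hi > cursor.lo:
            i = cursor.lo + int(np.searchsorted(codes[cursor.lo : cursor.hi], code))
            if i < cursor.hi and codes[i] == code:
                return int(self.records["taxon"][i])
        bucket = codec.minimizer_bucket(int(code), self.k, self.params)
        if cursor is not None and bucket == cursor.bucket:
            return None
        lo = int(self.offsets[bucket])
        hi = int(self.offsets[bucket + 1])
        if cursor is not None:
            cursor.lo, cursor.hi, cursor.bucket = lo, hi, bucket
        i = lo + int(np.searchsorted(codes[lo:hi], code))
        if i < hi and codes[i] == code:
            return int(self.records["taxon"][i])
        return None

    def query_many(self, kmer_codes: np.ndarray, buckets: np.ndarray) -> np.ndarray:
        """Vectorized lookup given precomputed bucket indices; 0 = absent."""
        kmer_codes = np.asarray(kmer_codes, dtype=np.uint64)
        lo = self.offsets[buckets]
        hi = self.offsets[np.asarray(buckets) + 1]
        out = np.zeros(len(kmer_codes), dtype=np.uint32)
        codes = self.records["code"]
        taxa = self.records["taxon"]
        for j in range(len(kmer_codes)):
            i = int(lo[j]) + int(
                np.searchsorted(codes[int(lo[j]) : int(hi[j])], kmer_codes[j])
            )
            if i < int(hi[j]) and codes[i] == kmer_codes[j]:
                out[j] = taxa[i]
        return out


def _library_kmer_occurrences(
    library: GenomeLibrary,
    k: int,
    params: MinimizerParams,
    filters: ContaminationFilter | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(codes, buckets, taxa) for every retained k-mer occurrence."""
    if not library.sequences:
        raise ValueError("cannot build a database from an empty genome library")
    code_chunks, bucket_chunks, taxon_chunks = [], [], []
    trim = filters.draft_edge_trim if filters else 0
    for seqid, seq in library.sequences:
        taxid = library.taxon_map[seqid]
        codes, buckets, valid = codec.sequence_minimizers(seq, k, params)
        keep = valid.copy()
        if filters and seqid in library.draft_ids and keep.size:
            keep[:trim] = False
            if trim:
                keep[-trim:] = False
        code_chunks.append(codes[keep])
        bucket_chunks.append(buckets[keep])
        taxon_chunks.append(np.full(int(keep.sum()), taxid, dtype=np.uint32))
    codes = np.concatenate(code_chunks)
    buckets = np.concatenate(bucket_chunks)
    taxa = np.concatenate(taxon_chunks)
    if filters is not None:
        bad = filters.adapter_codes(k)
        if bad.size:
            mask = ~np.isin(codes, bad)
            codes, buckets, taxa = codes[mask], buckets[mask], taxa[mask]
    return codes, buckets, taxa


def enumerate_distinct_kmers(library: GenomeLibrary, k: int) -> set[int]:
    """Distinct canonical k-mer codes over all ACGT windows of the library."""
    if not library.sequences:
        raise ValueError("empty genome library")
    if not 1 <= k <= 31:
        raise ValueError(f"k must be in [1, 31], got {k}")
    chunks = []
    for _, seq in library.sequences:
        codes, valid = codec.sequence_codes(seq, k)
        chunks.append(codes[valid])
    return set(int(c) for c in np.unique(np.concatenate(chunks))) if chunks else set()


def build(
    library: GenomeLibrary,
    tree: TaxonomyTree,
    k: int = 31,
    params: MinimizerParams | None = None,
    filters: ContaminationFilter | None = None,
) -> KrakenDB:
    """Build the k-mer → LCA database for a genome library.

    Every distinct canonical k-mer is stored with the taxonomy LCA of all
    taxa whose sequences contain it; the result is independent of the
    order in which sequences are processed.
    """
    if params is None:
        params = MinimizerParams()
    if not 1 <= params.m <= k <= 31:
        raise ValueError(f"need 1 <= M ({params.m}) <= k ({k}) <= 31")
    library.validate(tree)
    codes, buckets, taxa = _library_kmer_occurrences(library, k, params, filters)
    if codes.size == 0:
        raise ValueError("no k-mers survive filtering; database would be empty")

    # dedupe (code, taxon) pairs, then fold LCA per k-mer group
    pair_order = np.lexsort((taxa, codes))
    codes, buckets, taxa = codes[pair_order], buckets[pair_order], taxa[pair_order]
    first = np.ones(len(codes), dtype=bool)
    first[1:] = (codes[1:] != codes[:-1]) | (taxa[1:] != taxa[:-1])
    codes, buckets, taxa = codes[first], buckets[first], taxa[first]

    uniq_starts = np.ones(len(codes), dtype=bool)
    uniq_starts[1:] = codes[1:] != codes[:-1]
    starts = np.flatnonzero(uniq_starts)
    ends = np.append(starts[1:], len(codes))
    out_codes = codes[starts]
    out_buckets = buckets[starts]
    out_taxa = taxa[starts].copy()
    for idx in np.flatnonzero(ends - starts > 1):
        out_taxa[idx] = tree.lca_many(int(t) for t in taxa[starts[idx] : ends[idx]])

    order = np.lexsort((out_codes, out_buckets))
    records = np.empty(len(out_codes), dtype=_RECORD_DTYPE)
    records["code"] = out_codes[order]
    records["taxon"] = out_taxa[order]
    offsets = np.zeros(params.n_buckets + 1, dtype=np.uint64)
    counts = np.bincount(out_buckets[order].astype(np.int64), minlength=params.n_buckets)
    offsets[1:] = np.cumsum(counts, dtype=np.uint64)
    return KrakenDB(k=k, params=params, records=records, offsets=offsets)


def shrink(db: KrakenDB, factor: int = 19) -> KrakenDB:
    """Reduced database: keep the last record of each block of ``factor``.

    The global sorted record array is partitioned into consecutive blocks
    of ``factor`` records; the first ``factor - 1`` of each complete block
    are dropped and a trailing partial block is dropped entirely.  The
    default factor 19 mirrors the ~19x reduction used to fit a reduced
    database into 4 GB of RAM.
    """
    if factor < 2:
        raise ValueError(f"shrink factor must be >= 2, got {factor}")
    if len(db) == 0:
        raise ValueError("cannot shrink an empty database")
    n_blocks = len(db) // factor
    if n_blocks == 0:
        raise ValueError(
            f"database with {len(db)} records has no complete block of {factor}; "
            "result would be empty"
        )
    keep = np.arange(1, n_blocks + 1) * factor - 1
    records = db.records[keep]
    # rebuild offsets: old bucket of each kept record via searchsorted
    old_idx = keep.astype(np.uint64)
    buckets = np.searchsorted(db.offsets, old_idx, side="right") - 1
    offsets = np.zeros(db.params.n_buckets + 1, dtype=np.uint64)
    counts = np.bincount(buckets.astype(np.int64), minlength=db.params.n_buckets)
    offsets[1:] = np.cumsum(counts, dtype=np.uint64)
    return KrakenDB(k=db.k, params=db.params, records=records.copy(), offsets=offsets)


_HEADER = struct.Struct("<4sBBBBIQ")  # magic, version, k, M, pad, scramble, count


def save(db: KrakenDB, path) -> None:
    """Serialize to the little-endian on-disk format (bit-exact round trip)."""
    with open(path, "wb") as fh:
        fh.write(
            _HEADER.pack(
                _MAGIC, _VERSION, db.k, db.params.m, 0, db.params.scramble, len(db)
            )
        )
        fh.write(db.records.tobytes())
        fh.write(db.offsets.astype("<u8").tobytes())


def load(path) -> KrakenDB:
    """Load a database written by :func:`save`."""
    path = Path(path)
    with open(path, "rb") as fh:
        head = fh.read(_HEADER.size)
        if len(head) < _HEADER.size:
            raise ValueError(f"{path}: truncated header")
        magic, version, k, m, _pad, scramble, count = _HEADER.unpack(head)
        if magic != _MAGIC:
            raise ValueError(f"{path}: bad magic {magic!r}")
        if version != _VERSION:
            raise ValueError(f"{path}: unsupported version {version}")
        params = MinimizerParams(m=m, scramble=scramble)
        rec_bytes = fh.read(count * _RECORD_DTYPE.itemsize)
        if len(rec_bytes) < count * _RECORD_DTYPE.itemsize:
            raise ValueError(f"{path}: truncated record section")
        records = np.frombuffer(rec_bytes, dtype=_RECORD_DTYPE).copy()
        n_off = params.n_buckets + 1
        off_bytes = fh.read(n_off * 8)
        if len(off_bytes) < n_off * 8:
            raise ValueError(f"{path}: truncated offset section")
        offsets = np.frombuffer(off_bytes, dtype="<u8").copy()
    return KrakenDB(k=k, params=params, records=records, offsets=offsets)
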